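"""Weighted lowest-common-ancestor (LCA) taxonomy reports.

Each retained host-phage match casts a vote: for a phage, the vote is
the host's taxid weighted by the match confidence (-log10 of the
combined score, clipped to [1, 20]); symmetrically for a spacer, the
vote is the phage's taxid.  The weighted LCA of a vote set is the
*lowest* tree node whose subtree carries at least a configurable
fraction (default 0.5) of the total vote weight.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

DEFAULT_SUPPORT = 0.5
WEIGHT_CLIP = (1.0, 20.0)

_EPS = 1e-9


class Taxonomy:
    """Parent-pointer taxonomy tree with rank and name per node."""

    def __init__(self, nodes: dict):
        # nodes: taxid -> (parent, rank, name); root points to itself
        self.nodes = nodes
        roots = [t for t, (p, _, _) in nodes.items() if p == t]
        if len(roots) != 1:
            raise ValueError(f"taxonomy must have exactly one root, found {roots}")
        self.root = roots[0]
        self._depth: dict[int, int] = {}

    def __contains__(self, taxid: int) -> bool:
        return taxid in self.nodes

    def parent(self, taxid: int) -> int:
        return self.nodes[taxid][0]

    def rank(self, taxid: int) -> str:
        return self.nodes[taxid][1]

    def name(self, taxid: int) -> str:
        return self.nodes[taxid][2]

    def lineage(self, taxid: int) -> list[int]:
        """Path from the node up to (and including) the root."""
        path = [taxid]
        while path[-1] != self.root:
            path.append(self.parent(path[-1]))
        return path

    def depth(self, taxid: int) -> int:
        if taxid not in self._depth:
            self._depth[taxid] = len(self.lineage(taxid)) - 1
        return self._depth[taxid]

    @classmethod
    def from_tsv(cls, path) -> "Taxonomy":
        """4-column TSV: taxid, parent taxid, rank, name."""
        nodes = {}
        for ln in Path(path).read_text().splitlines():
            ln = ln.strip()
            if not ln or ln.startswith("#"):
                continue
            taxid, parent, rank, name = ln.split("\t")[:4]
            nodes[int(taxid)] = (int(parent), rank, name)
        return cls(nodes)

    @classmethod
    def from_taxdump(cls, directory) -> "Taxonomy":
        """NCBI-taxdump-style nodes.dmp / names.dmp (pipe-delimited)."""
        directory = Path(directory)
        nodes = {}
        for ln in (directory / "nodes.dmp").read_text().splitlines():
            fields = [f.strip() for f in ln.split("|")]
            if len(fields) < 3:
                continue
            nodes[int(fields[0])] = [int(fields[1]), fields[2], ""]
        for ln in (directory / "names.dmp").read_text().splitlines():
            fields = [f.strip() for f in ln.split("|")]
            if len(fields) >= 4 and fields[3] == "scientific name":
                taxid = int(fields[0])
                if taxid in nodes:
                    nodes[taxid][2] = fields[1]
        return cls({t: tuple(v) for t, v in nodes.items()})


@dataclass
class LcaAssignment:
    subject_accession: str
    lca_taxid: int
    lca_rank: str
    lca_name: str
    support: float
    n_votes: int


def weighted_lca(
    votes: list[tuple[int, float]],
    taxonomy: Taxonomy,
    support_threshold: float = DEFAULT_SUPPORT,
    subject: str = "",
) -> LcaAssignment | None:
    """Lowest node whose subtree weight is >= threshold * total weight.

    Ties (possible only at threshold = 0.5 on a tree) are broken by
    greater depth, then smaller taxid.  Returns None for empty votes.
    """
    if not votes:
        return None
    for taxid, w in votes:
        if taxid not in taxonomy:
            raise KeyError(f"taxid {taxid} not in taxonomy")
        if w <= 0:
            raise ValueError("vote weights must be positive")
    total = sum(w for _, w in votes)
    acc: dict[int, float] = {}
    nvotes: dict[int, int] = {}
    for taxid, w in votes:
        for node in taxonomy.lineage(taxid):
            acc[node] = acc.get(node, 0.0) + w
            nvotes[node] = nvotes.get(node, 0) + 1
    # strict majority: a node qualifies when its subtree weight exceeds
    # threshold * total (so equal-weight siblings resolve to their
    # parent); if nothing exceeds it (e.g. threshold 1.0), fall back to
    # nodes reaching it exactly
    cutoff = support_threshold * total
    candidates = [t for t, w in acc.items() if w > cutoff + _EPS]
    if not candidates:
        candidates = [t for t, w in acc.items() if w >= cutoff - _EPS]
    best = max(candidates, key=lambda t: (taxonomy.depth(t), -t))
    return LcaAssignment(
        subject_accession=subject,
        lca_taxid=best,
        lca_rank=taxonomy.rank(best),
        lca_name=taxonomy.name(best),
        support=acc[best] / total,
        n_votes=nvotes[best],
    )


def match_weight(s_comb: float) -> float:
    """Vote weight of a retained match: clipped -log10(s_comb)."""
    if s_comb <= 0:
        return WEIGHT_CLIP[1]
    lo, hi = WEIGHT_CLIP
    return min(hi, max(lo, -math.log10(s_comb)))


def build_reports(
    matches,
    labels,
    support_threshold: float = DEFAULT_SUPPORT,
    uniform_weights: bool = False,
) -> tuple[list[LcaAssignment], list[LcaAssignment]]:
    """Host LCA per phage and phage LCA per spacer, from retained matches.

    ``labels`` is a TaxLabelTable whose mapping must cover the voting
    side (host genome ids for the phage report, phage accessions for the
    spacer report); voters without a label are skipped with a warning.
    """
    tax = labels.taxonomy
    phage_votes: dict[str, list[tuple[int, float]]] = {}
    spacer_votes: dict[str, list[tuple[int, float]]] = {}
    for m in matches:
        if not m.retained:
            continue
        w = 1.0 if uniform_weights else match_weight(m.s_comb)
        host_tax = labels.mapping.get(m.query_set_id)
        phage_tax = labels.mapping.get(m.target_set_id)
        if host_tax is not None:
            phage_votes.setdefault(m.target_set_id, []).append((host_tax, w))
        else:
            logger.warning("no taxonomic label for host %s; vote skipped", m.query_set_id)
        if phage_tax is not None:
            for bh in m.best_hits:
                spacer_votes.setdefault(bh.spacer_accession, []).append((phage_tax, w))
        else:
            logger.warning("no taxonomic label for phage %s; vote skipped", m.target_set_id)

    host_report = [
        a
        for phage, votes in sorted(phage_votes.items())
        if (a := weighted_lca(votes, tax, support_threshold, subject=phage))
    ]
    spacer_report = [
        a
        for spacer, votes in sorted(spacer_votes.items())
        if (a := weighted_lca(votes, tax, support_threshold, subject=spacer))
    ]
    return host_report, spacer_report
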