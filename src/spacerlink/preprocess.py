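"""Six-frame extraction and translation of putative coding fragments.

Both CRISPR spacers and phage genomes are scanned in all six reading
frames.  Every maximal stop-free run of codons covering at least
``min_nt`` nucleotides (default 27, i.e. 9 aa) becomes one fragment; no
start codon is required, because spacers are arbitrary sub-gene
fragments.  The translated fragments from one prokaryote's spacers form
a query set Q; the fragments from one phage genome form a target set T.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio.Data import CodonTable

logger = logging.getLogger(__name__)

MIN_FRAGMENT_NT = 27

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


@lru_cache(maxsize=None)
def codon_map(table_id: int = 11) -> dict:
    """Codon -> amino acid for an NCBI translation table; stops map to '*'.

    Codons containing ambiguity codes are not in the map; they translate
    to 'X' and never terminate a coding run.
    """
    table = CodonTable.unambiguous_dna_by_id[table_id]
    mapping = dict(table.forward_table)
    for stop in table.stop_codons:
        mapping[stop] = "*"
    return mapping


@dataclass(frozen=True)
class OrfFragment:
    """One translated stop-free codon run from a spacer or genome.

    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the
    *forward* strand of the parent sequence regardless of ``strand``.
    """

    parent_accession: str
    parent_kind: str  # "spacer" | "genome"
    frame: int  # 0..2, offset in the strand-oriented sequence
    strand: str  # "+" | "-"
    nt_start: int
    nt_end: int
    aa_sequence: str
    nt_sequence: str

    def __post_init__(self):
        length = self.nt_end - self.nt_start
        if length < MIN_FRAGMENT_NT or length % 3:
            raise ValueError("fragment must span >= 27 nt in whole codons")
        if "*" in self.aa_sequence:
            raise ValueError("fragment contains a stop codon")
        if len(self.aa_sequence) * 3 != length:
            raise ValueError("aa/nt length mismatch")


def extract_fragments(
    sequence: str,
    accession: str,
    kind: str = "genome",
    min_nt: int = MIN_FRAGMENT_NT,
    table: int = 11,
) -> list[OrfFragment]:
    """All maximal stop-free codon runs of >= min_nt nt, in six frames.

    Returns an empty list (not an error) for sequences shorter than
    ``min_nt``.  Ambiguous codons translate to 'X' and do not split runs.
    """
    cmap = codon_map(table)
    length = len(sequence)
    out: list[OrfFragment] = []
    for strand in ("+", "-"):
        oriented = sequence if strand == "+" else revcomp(sequence)
        for frame in range(3):
            n_codons = (length - frame) // 3
            run_start = 0  # codon index where current stop-free run began
            aa_run: list[str] = []
            for ci in range(n_codons + 1):
                if ci < n_codons:
                    codon = oriented[frame + 3 * ci : frame + 3 * ci + 3]
                    aa = cmap.get(codon, "X")
                else:
                    aa = "*"  # sentinel: flush at end of frame
                if aa == "*":
                    if 3 * len(aa_run) >= min_nt:
                        o_start = frame + 3 * run_start
                        o_end = frame + 3 * ci
                        if strand == "+":
                            nt_start, nt_end = o_start, o_end
                        else:
                            nt_start, nt_end = length - o_end, length - o_start
                        out.append(
                            OrfFragment(
                                parent_accession=accession,
                                parent_kind=kind,
                                frame=frame,
                                strand=strand,
                                nt_start=nt_start,
                                nt_end=nt_end,
                                aa_sequence="".join(aa_run),
                                nt_sequence=oriented[o_start:o_end],
                            )
                        )
                    run_start = ci + 1
                    aa_run = []
                else:
                    aa_run.append(aa)
    return out


@dataclass
class FragmentSet:
    """Fragments from one side of the comparison (query or target)."""

    set_id: str
    fragments: list[OrfFragment] = field(default_factory=list)

    @property
    def n_fragments(self) -> int:
        return len(self.fragments)


class QuerySet(FragmentSet):
    """All translated spacer fragments from one prokaryotic genome."""


class TargetSet(FragmentSet):
    """All translated fragments from one phage (or null) genome."""


def build_sets(
    spacers_by_genome: dict,
    genomes: list,
    min_nt: int = MIN_FRAGMENT_NT,
    query_table: int = 11,
    target_table: int = 11,
) -> tuple[list[QuerySet], list[TargetSet]]:
    """Build one QuerySet per prokaryote and one TargetSet per genome.

    Raises ``ValueError`` if *every* query set is empty ("no translatable
    spacers"); individual empty query sets only log a warning.
    """
    queries: list[QuerySet] = []
    for genome_id, spacers in spacers_by_genome.items():
        frags: list[OrfFragment] = []
        for sp in spacers:
            frags.extend(
                extract_fragments(sp.sequence, sp.accession, "spacer", min_nt, query_table)
            )
        if not frags:
            logger.warning("no translatable spacers for genome %s", genome_id)
        queries.append(QuerySet(set_id=genome_id, fragments=frags))
    if queries and all(q.n_fragments == 0 for q in queries):
        raise ValueError("no translatable spacers in any query genome")

    targets = [
        TargetSet(
            set_id=g.accession,
            fragments=extract_fragments(g.sequence, g.accession, "genome", min_nt, target_table),
        )
        for g in genomes
    ]
    return queries, targets
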