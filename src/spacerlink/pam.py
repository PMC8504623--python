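"""Protospacer-adjacent motif (PAM) detection.

Some CRISPR-Cas systems require a short (2-6 nt) conserved motif
flanking the protospacer to license cleavage.  After a match is
accepted, the 10 nt upstream and downstream of the protospacer are
scanned (clipped at genome ends) against a small catalog of well-known
IUPAC motifs, on the protospacer strand and its reverse complement.
Reported motifs are annotations only; they never affect scoring, and
the raw flanks are always reported so users can re-analyze.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

from .preprocess import revcomp

FLANK_LEN = 10

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class PamMotif:
    name: str
    pattern: str  # IUPAC nucleotide pattern
    side: str  # "5prime" | "3prime"

    def __post_init__(self):
        if self.side not in ("5prime", "3prime"):
            raise ValueError(f"motif {self.name}: side must be 5prime or 3prime")
        bad = set(self.pattern) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC characters {bad}")


@dataclass
class PamResult:
    upstream_flank: str  # 5' of the protospacer, protospacer orientation
    downstream_flank: str  # 3' of the protospacer
    matched_motif_fwd: str = "-"
    matched_motif_rev: str = "-"
    motif_side: str = "none"  # side of the forward-strand match
    motif_side_rev: str = "none"


def default_catalog() -> list[PamMotif]:
    """Bundled catalog of well-known PAMs (user-editable TSV)."""
    text = resources.files("spacerlink").joinpath("data/pam_catalog.tsv").read_text()
    return parse_catalog(text.splitlines())


def parse_catalog(lines) -> list[PamMotif]:
    motifs = []
    for ln in lines:
        ln = ln.strip()
        if not ln or ln.startswith("#"):
            continue
        name, side = ln.split("\t")[:2]
        motifs.append(PamMotif(name=name, pattern=name, side=side))
    return motifs


def load_catalog(path) -> list[PamMotif]:
    return parse_catalog(Path(path).read_text().splitlines())


def iupac_find(flank: str, pattern: str) -> bool:
    """True if the IUPAC pattern occurs at any offset of the flank."""
    k = len(pattern)
    for i in range(len(flank) - k + 1):
        if all(flank[i + j] in IUPAC[pattern[j]] for j in range(k)):
            return True
    return False


def _first_match(up: str, down: str, catalog) -> tuple[str, str]:
    """First catalog motif matching in its annotated flank; catalog order wins."""
    for motif in catalog:
        flank = up if motif.side == "5prime" else down
        if iupac_find(flank, motif.pattern):
            return motif.name, motif.side
    return "-", "none"


def scan_pam(genome, proto_start: int, proto_end: int, strand: str, catalog=None) -> PamResult:
    """Scan the 10-nt flanks of a protospacer for a possible PAM.

    Coordinates are 0-based half-open on the genome forward strand;
    ``strand`` is the protospacer strand.  Flanks are reported in
    protospacer orientation (upstream = 5').  The forward scan uses that
    orientation; the reverse scan tests the reverse-complement
    protospacer (flanks swapped and complemented).
    """
    if catalog is None:
        catalog = default_catalog()
    if not (0 <= proto_start < proto_end <= len(genome.sequence)):
        raise ValueError("protospacer coordinates outside genome")
    G = genome.sequence
    left = G[max(0, proto_start - FLANK_LEN) : proto_start]
    right = G[proto_end : proto_end + FLANK_LEN]
    if strand == "+":
        up, down = left, right
    else:
        up, down = revcomp(right), revcomp(left)

    fwd_name, fwd_side = _first_match(up, down, catalog)
    rev_name, rev_side = _first_match(revcomp(down), revcomp(up), catalog)
    return PamResult(
        upstream_flank=up,
        downstream_flank=down,
        matched_motif_fwd=fwd_name,
        matched_motif_rev=rev_name,
        motif_side=fwd_side,
        motif_side_rev=rev_side,
    )


def format_pam(name: str, side: str) -> str:
    """Report-column form: side-prefixed motif name, or '-'."""
    if name == "-" or side == "none":
        return "-"
    return ("5'" if side == "5prime" else "3'") + name
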