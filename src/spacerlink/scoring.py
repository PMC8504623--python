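"""Scoring parameters for the protein-level spacer search.

The search compares very short translated spacer fragments (9-14 aa)
against phage protein fragments, so the substitution matrix must be tuned
for short evolutionary distances.  The default is the PAM40 log-odds
matrix with an affine gap cost of 16 to open and 2 to extend, and a
spaced k-mer pattern ``10111011`` (six informative positions) for the
prefilter.  Per-hit significance uses a Karlin-Altschul/Gumbel tail whose
(lambda, K) parameters are calibrated once by simulation and shipped as
package data (see ``spacerlink.calibrate``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources

import numpy as np

#: Alphabet of the bundled protein matrices (order matters: row/col index).
AA_ALPHABET: tuple[str, ...] = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L", "M", "N",
    "P", "Q", "R", "S", "T", "V", "W", "Y", "B", "Z", "X", "*",
)

_AA_INDEX = {a: i for i, a in enumerate(AA_ALPHABET)}
_X_INDEX = _AA_INDEX["X"]

#: The 20 standard residues, used for random-sequence simulation.
STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"

DEFAULT_KMER_PATTERN = "10111011"
DEFAULT_GAP_OPEN = 16
DEFAULT_GAP_EXTEND = 2


def encode_protein(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 matrix indices (unknown -> X)."""
    return np.array([_AA_INDEX.get(c, _X_INDEX) for c in seq], dtype=np.int8)


def load_default_matrix() -> np.ndarray:
    """Load the PAM40 substitution matrix (24x24 int, symmetric)."""
    import biotite.sequence as bseq
    import biotite.sequence.align as balign

    alph = bseq.ProteinSequence.alphabet
    mat = balign.SubstitutionMatrix(alph, alph, "PAM40")
    order = [alph.encode(a) for a in AA_ALPHABET]
    arr = mat.score_matrix()[np.ix_(order, order)]
    return np.ascontiguousarray(arr, dtype=np.int32)


def load_matrix_file(path) -> np.ndarray:
    """Parse an NCBI-format substitution matrix text file.

    Rows/columns are reordered to :data:`AA_ALPHABET`; letters absent from
    the file fall back to the X column of the file (or 0 if X is absent).
    """
    with open(path) as fh:
        lines = [ln.rstrip() for ln in fh if ln.strip() and not ln.lstrip().startswith("#")]
    header = lines[0].split()
    rows: dict[str, dict[str, int]] = {}
    for ln in lines[1:]:
        parts = ln.split()
        rows[parts[0]] = {h: int(round(float(v))) for h, v in zip(header, parts[1:])}

    def score(a: str, b: str) -> int:
        ra = rows.get(a) or rows.get("X") or {}
        return ra.get(b, ra.get("X", 0))

    n = len(AA_ALPHABET)
    arr = np.zeros((n, n), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            arr[i, j] = score(a, b)
    if not np.array_equal(arr, arr.T):
        raise ValueError(f"substitution matrix in {path} is not symmetric")
    return arr


def load_gumbel_params() -> dict:
    """Load the shipped Gumbel (lambda, K) calibration."""
    text = resources.files("spacerlink").joinpath("data/gumbel_params.json").read_text()
    return json.loads(text)


@dataclass
class ScoringScheme:
    """All parameters governing prefilter, alignment and per-hit P-values."""

    matrix: np.ndarray = field(default_factory=load_default_matrix)
    gap_open: int = DEFAULT_GAP_OPEN
    gap_extend: int = DEFAULT_GAP_EXTEND
    kmer_pattern: str = DEFAULT_KMER_PATTERN
    gumbel_lambda: float = 0.0
    gumbel_K: float = 0.0
    matrix_name: str = "PAM40"

    def __post_init__(self):
        if self.gumbel_lambda <= 0.0 or self.gumbel_K <= 0.0:
            if self.matrix_name == "PAM40":
                params = load_gumbel_params()
                self.gumbel_lambda = params["lambda"]
                self.gumbel_K = params["K"]
            else:
                raise ValueError(
                    "gumbel_lambda and gumbel_K must be calibrated (>0) "
                    "for a non-default matrix"
                )
        self.validate()

    def validate(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (len(AA_ALPHABET), len(AA_ALPHABET)):
            raise ValueError("matrix must be 24x24 over the protein alphabet")
        if not np.array_equal(m, m.T):
            raise ValueError("substitution matrix must be symmetric")
        if not (self.gap_open >= self.gap_extend >= 1):
            raise ValueError("require gap_open >= gap_extend >= 1")
        p = self.kmer_pattern
        if not p or p[0] != "1" or p[-1] != "1" or set(p) - {"0", "1"}:
            raise ValueError("kmer_pattern must be a 0/1 string starting and ending with 1")
        if self.gumbel_lambda <= 0 or self.gumbel_K <= 0:
            raise ValueError("gumbel_lambda and gumbel_K must be positive")

    @classmethod
    def from_file(cls, path, gumbel_lambda: float, gumbel_K: float, **kw) -> "ScoringScheme":
        """Scheme with a user-supplied NCBI-format matrix (e.g. VTML40)."""
        return cls(
            matrix=load_matrix_file(path),
            gumbel_lambda=gumbel_lambda,
            gumbel_K=gumbel_K,
            matrix_name=str(path),
            **kw,
        )

    @property
    def pattern_offsets(self) -> tuple[int, ...]:
        """Offsets of the informative ('1') positions in the spaced pattern."""
        return tuple(i for i, c in enumerate(self.kmer_pattern) if c == "1")
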