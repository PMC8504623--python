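"""Stage 1: protein-level search of spacer fragments against phage fragments.

A pair of fragments becomes a candidate when it shares at least one
identical *spaced* 6-mer: the '1' positions of the 8-residue pattern
``10111011`` select the six compared residues, so any exact ungapped
8-residue match is guaranteed to seed a candidate.  Candidates are
aligned with affine-gap Smith-Waterman; each protein hit is then
re-aligned at the nucleotide level over the genome window implied by the
protein alignment, and near-perfect nucleotide hits (<= 2 mismatches at
>= 95% spacer coverage) are prioritized by flooring their P-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

from . import _sw
from .preprocess import OrfFragment, QuerySet, TargetSet, revcomp
from .scoring import ScoringScheme, encode_protein

#: P-value assigned to near-perfect nucleotide hits so that they
#: dominate any protein-only hit in the downstream combination.
NEAR_PERFECT_P_FLOOR = 1e-10

#: near-perfect criteria (the classic strict nucleotide-match filter)
NEAR_PERFECT_MAX_MISMATCHES = 2
NEAR_PERFECT_MIN_COVERAGE = 0.95

_P_MIN = 1e-300  # keep P-values strictly positive


@dataclass
class ProteinHit:
    """One aligned query-target fragment pair, optionally nt-enriched."""

    query_fragment: OrfFragment
    target_fragment: OrfFragment
    aln_score: int
    q_aln_start: int
    q_aln_end: int
    t_aln_start: int
    t_aln_end: int
    p_hit: float
    # nucleotide re-alignment results
    nt_identity: float = 0.0
    nt_mismatches: int = -1
    near_perfect: bool = False
    # spacer/protospacer coordinates on the forward strands of their parents
    spacer_start: int = 0
    spacer_end: int = 0
    proto_start: int = 0
    proto_end: int = 0
    proto_strand: str = "+"
    aln_spacer_seq: Optional[str] = None
    aln_target_seq: Optional[str] = None
    pam_fwd: Optional[str] = None
    pam_rev: Optional[str] = None


def spaced_kmers(aa_sequence: str, pattern_offsets: tuple[int, ...], span: int) -> set:
    """All spaced k-mers of a fragment (set of strings)."""
    n = len(aa_sequence)
    return {
        "".join(aa_sequence[i + o] for o in pattern_offsets)
        for i in range(n - span + 1)
    }


def build_target_index(T: TargetSet, scheme: ScoringScheme) -> dict:
    """Spaced 6-mer -> target fragment indices, built once per target set."""
    offsets = scheme.pattern_offsets
    span = len(scheme.kmer_pattern)
    index: dict[str, list[int]] = {}
    for tj, tf in enumerate(T.fragments):
        for kmer in spaced_kmers(tf.aa_sequence, offsets, span):
            index.setdefault(kmer, []).append(tj)
    return index


def prefilter(
    Q: QuerySet,
    T: TargetSet,
    scheme: ScoringScheme,
    index: dict | None = None,
    query_kmers: list[set] | None = None,
) -> list[tuple[int, int]]:
    """Candidate (query-fragment, target-fragment) index pairs.

    A pair is a candidate iff the two fragments share at least one
    identical spaced 6-mer.  ``index`` and ``query_kmers`` allow reuse
    of precomputed k-mer structures across many set pairs.
    """
    offsets = scheme.pattern_offsets
    span = len(scheme.kmer_pattern)
    if index is None:
        index = build_target_index(T, scheme)
    if query_kmers is None:
        query_kmers = [
            spaced_kmers(qf.aa_sequence, offsets, span) for qf in Q.fragments
        ]
    out: list[tuple[int, int]] = []
    for qi, kmers in enumerate(query_kmers):
        hits: set[int] = set()
        for kmer in kmers:
            hits.update(index.get(kmer, ()))
        out.extend((qi, tj) for tj in sorted(hits))
    return out


def align_protein(q: OrfFragment, t: OrfFragment, scheme: ScoringScheme):
    """Optimal affine-gap local alignment of two fragments.

    Returns ``(score, q_start, q_end, t_start, t_end)`` (aa coordinates,
    0-based half-open, fragment-local).  Ties are broken toward the
    smallest query start, then the smallest target start.
    """
    return _sw.sw_align(
        encode_protein(q.aa_sequence),
        encode_protein(t.aa_sequence),
        scheme.matrix,
        scheme.gap_open,
        scheme.gap_extend,
    )


def hit_pvalue(score: int, m: int, n: int, scheme: ScoringScheme) -> float:
    """Karlin-Altschul/Gumbel tail P-value of a local alignment score.

    ``p = 1 - exp(-K m n exp(-lambda * score))``, clamped to
    ``[1e-300, 1]``; m and n are the fragment lengths in residues.
    """
    lam, K = scheme.gumbel_lambda, scheme.gumbel_K
    if lam <= 0 or K <= 0:
        raise ValueError("Gumbel parameters must be positive")
    log_e = math.log(K) + math.log(m) + math.log(n) - lam * score
    if log_e > 700.0:
        return 1.0
    p = -math.expm1(-math.exp(log_e))
    return min(1.0, max(_P_MIN, p))


def _oriented_offset(frag: OrfFragment, parent_len: int) -> int:
    """Start of the fragment in its strand-oriented parent sequence."""
    if frag.strand == "+":
        return frag.nt_start
    return parent_len - frag.nt_end


def realign_nucleotide(hit: ProteinHit, spacer, genome) -> ProteinHit:
    """Ungapped nucleotide comparison of the full spacer against the
    genome window implied by the protein alignment.

    The window is extended from the aligned codons to cover the whole
    spacer, strand-aware, and clipped at genome ends (coverage is then
    computed on the clipped part).  Sets ``nt_identity``,
    ``nt_mismatches``, ``near_perfect`` and the protospacer coordinates;
    near-perfect hits get ``p_hit`` floored at 1e-10.
    """
    qf, tf = hit.query_fragment, hit.target_fragment
    S, G = spacer.sequence, genome.sequence
    L, N = len(S), len(G)

    s_or = S if qf.strand == "+" else revcomp(S)
    g_or = G if tf.strand == "+" else revcomp(G)
    a0 = _oriented_offset(qf, L) + 3 * hit.q_aln_start
    b0 = _oriented_offset(tf, N) + 3 * hit.t_aln_start
    g0 = b0 - a0  # g_or index aligned to s_or index 0

    c0 = max(0, -g0)
    c1 = min(L, N - g0)
    covered = max(0, c1 - c0)
    matches = 0
    for i in range(c0, c1):
        if s_or[i] == g_or[g0 + i]:
            matches += 1
    mismatches = covered - matches
    coverage = covered / L if L else 0.0
    identity = matches / covered if covered else 0.0
    near_perfect = (
        mismatches <= NEAR_PERFECT_MAX_MISMATCHES
        and coverage >= NEAR_PERFECT_MIN_COVERAGE
        and covered > 0
    )

    # protospacer window (clipped) on the genome forward strand
    w0, w1 = g0 + c0, g0 + c1
    if tf.strand == "+":
        proto_start, proto_end = w0, w1
    else:
        proto_start, proto_end = N - w1, N - w0
    proto_strand = "+" if qf.strand == tf.strand else "-"
    if qf.strand == "+":
        sp_start, sp_end = c0, c1
    else:
        sp_start, sp_end = L - c1, L - c0

    p_hit = min(hit.p_hit, NEAR_PERFECT_P_FLOOR) if near_perfect else hit.p_hit
    return replace(
        hit,
        nt_identity=identity,
        nt_mismatches=mismatches,
        near_perfect=near_perfect,
        p_hit=p_hit,
        spacer_start=sp_start,
        spacer_end=sp_end,
        proto_start=proto_start,
        proto_end=proto_end,
        proto_strand=proto_strand,
        aln_spacer_seq=s_or[c0:c1],
        aln_target_seq=g_or[w0:w1],
    )


def search_pair(
    Q: QuerySet,
    T: TargetSet,
    scheme: ScoringScheme,
    spacers_by_accession: dict,
    genome,
    min_score: int = 1,
    index: dict | None = None,
    query_kmers: list[set] | None = None,
) -> list[ProteinHit]:
    """All protein hits between one query set and one target set.

    One hit (the optimal local alignment) is kept per candidate fragment
    pair; every hit is nucleotide re-aligned.
    """
    hits: list[ProteinHit] = []
    for qi, tj in prefilter(Q, T, scheme, index=index, query_kmers=query_kmers):
        qf, tf = Q.fragments[qi], T.fragments[tj]
        score, qs, qe, ts, te = align_protein(qf, tf, scheme)
        if score < min_score:
            continue
        p = hit_pvalue(score, len(qf.aa_sequence), len(tf.aa_sequence), scheme)
        hit = ProteinHit(
            query_fragment=qf,
            target_fragment=tf,
            aln_score=score,
            q_aln_start=qs,
            q_aln_end=qe,
            t_aln_start=ts,
            t_aln_end=te,
            p_hit=p,
        )
        spacer = spacers_by_accession[qf.parent_accession]
        hits.append(realign_nucleotide(hit, spacer, genome))
    return hits
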