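"""Stages 2-4: per-spacer best-hit P-values, evidence combination, FDR.

For one spacer against one phage fragment set T, the best-hit P-value is
the order-1 statistic of the per-fragment P-values under independence:
``p_bh = 1 - (1 - p_min)^n_T``.  Evidence from multiple spacers hitting
the same phage is combined with a truncated-product score: p-values at
or below a threshold tau (default 0.1) enter a product ``tau *
prod(p_i/tau)``; with no p-value below tau the smallest p-value is used,
so a single weak hit still yields a score.  Smaller s_comb means
stronger evidence.  Significance is calibrated empirically against a
null database of character-reversed genomes, and matches are retained
below an estimated false discovery rate (default 0.05).
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field

from .search import ProteinHit

DEFAULT_TAU = 0.1
DEFAULT_FDR = 0.05

_S_MIN = 1e-300


@dataclass
class BestHit:
    """Best hit of one spacer against one target set."""

    spacer_accession: str
    target_set_id: str
    p_bh: float
    hit: ProteinHit


@dataclass
class PairMatch:
    """One candidate host-phage relationship (query set vs target set)."""

    query_set_id: str
    target_set_id: str
    best_hits: list[BestHit] = field(default_factory=list)
    s_comb: float = 1.0
    empirical_p: float = 1.0
    fdr: float = 1.0
    retained: bool = False


def min_order_pvalue(p_min: float, n: int) -> float:
    """P-value of the minimum of n independent uniform p-values:
    ``1 - (1 - p_min)^n``, computed in log space for small p_min."""
    if n <= 0:
        raise ValueError("n must be positive")
    if p_min <= 0.0:
        return 0.0
    if p_min >= 1.0:
        return 1.0
    return min(1.0, -math.expm1(n * math.log1p(-p_min)))


def best_hit_pvalue(hits: list[ProteinHit], n_T: int, target_set_id: str) -> BestHit:
    """P-value of the best of ``n_T`` fragment comparisons (minimum
    order statistic over the target set's fragments)."""
    if not hits:
        raise ValueError("no hits to summarize")
    if n_T <= 0:
        raise ValueError("target set has no fragments")
    best = min(hits, key=lambda h: h.p_hit)
    return BestHit(
        spacer_accession=best.query_fragment.parent_accession,
        target_set_id=target_set_id,
        p_bh=min_order_pvalue(best.p_hit, n_T),
        hit=best,
    )


def combine_truncated_product(p_values: list[float], tau: float = DEFAULT_TAU) -> float:
    """Truncated-product combination of best-hit P-values.

    Only p-values <= tau contribute: ``s_comb = tau * prod(p/tau)``.
    With no p-value below tau, returns ``min(p_values)``.  Clamped to
    ``[1e-300, 1]`` so scores stay positive.
    """
    if not p_values:
        raise ValueError("empty p-value list")
    if not 0.0 < tau <= 1.0:
        raise ValueError("tau must be in (0, 1]")
    selected = [p for p in p_values if p <= tau]
    if not selected:
        return max(_S_MIN, min(p_values))
    log_s = math.log(tau) + sum(
        math.log(max(p, _S_MIN)) - math.log(tau) for p in selected
    )
    return max(_S_MIN, math.exp(max(log_s, math.log(_S_MIN))))


def empirical_pvalue(s: float, null_scores: list[float], n_null_pairs: int) -> float:
    """Fraction of null comparisons scoring at least as well, with
    add-one smoothing: ``(1 + #{null <= s}) / (1 + n_null_pairs)``.

    ``n_null_pairs`` counts all evaluated query-set/null-target-set
    pairs, including those that produced no hits.
    """
    if n_null_pairs <= 0:
        raise ValueError("null database produced no comparisons")
    k = bisect.bisect_right(null_scores, s)
    return (1 + k) / (1 + n_null_pairs)


def estimate_fdr(
    matches: list[PairMatch],
    null_scores: list[float],
    size_ratio: float,
    threshold: float = DEFAULT_FDR,
) -> list[PairMatch]:
    """Annotate matches with a monotone FDR estimate and a retained flag.

    At the cutoff set by the k-th best (smallest) real score c,
    ``FDR_raw(k) = min(1, size_ratio * #{null <= c} / k)``; the estimate
    is then monotonized from the weakest cutoff downward (running
    minimum, q-value convention).  ``size_ratio`` rescales for a null
    database of different size (real targets / null targets).  Returns
    the matches sorted by ascending s_comb.
    """
    nulls = sorted(null_scores)
    order = sorted(matches, key=lambda m: m.s_comb)
    raw = []
    for k, m in enumerate(order, start=1):
        n_le = bisect.bisect_right(nulls, m.s_comb)
        raw.append(min(1.0, size_ratio * n_le / k))
    running = 1.0
    for i in range(len(order) - 1, -1, -1):
        running = min(running, raw[i])
        order[i].fdr = running
        order[i].retained = running < threshold
    return order


def summarize_pair(
    hits_by_spacer: dict,
    n_T: int,
    query_set_id: str,
    target_set_id: str,
    tau: float = DEFAULT_TAU,
) -> PairMatch:
    """Build a PairMatch from per-spacer hit lists against one target set."""
    best_hits = [
        best_hit_pvalue(hits, n_T, target_set_id) for hits in hits_by_spacer.values()
    ]
    best_hits.sort(key=lambda b: b.p_bh)
    s_comb = combine_truncated_product([b.p_bh for b in best_hits], tau=tau)
    return PairMatch(
        query_set_id=query_set_id,
        target_set_id=target_set_id,
        best_hits=best_hits,
        s_comb=s_comb,
    )
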