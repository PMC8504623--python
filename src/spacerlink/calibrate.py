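"""Gumbel (lambda, K) calibration for per-hit alignment P-values.

Local alignment scores of unrelated sequences follow a Gumbel law:
``P(S >= s) = 1 - exp(-K m n exp(-lambda s))`` where m, n are the
sequence lengths.  The parameters are fitted once, by aligning random
fragment pairs drawn from the operating regime of this tool (9-14 aa
translated spacer fragments against 50-300 aa phage fragments) and
maximizing a tail-censored likelihood: scores below a censoring
threshold contribute only through the CDF, so the fit is governed by
the tail that the P-values actually use.  The fitted values are shipped
as package data together with the seed and regime that produced them
(see ``scripts/calibrate_gumbel.py``).
"""

from __future__ import annotations

import numpy as np
from scipy import optimize

from ._sw import batch_scores
from .scoring import STANDARD_AA, ScoringScheme, encode_protein

QUERY_LEN_RANGE = (9, 14)
TARGET_LEN_RANGE = (50, 300)


def random_fragment_scores(
    n_pairs: int,
    scheme: ScoringScheme,
    seed: int,
    qlen_range: tuple[int, int] = QUERY_LEN_RANGE,
    tlen_range: tuple[int, int] = TARGET_LEN_RANGE,
) -> tuple[np.ndarray, np.ndarray]:
    """Align random i.i.d. fragment pairs; returns (scores, m*n)."""
    rng = np.random.default_rng(seed)
    aa = encode_protein(STANDARD_AA)
    q_lens = rng.integers(qlen_range[0], qlen_range[1] + 1, size=n_pairs)
    t_lens = rng.integers(tlen_range[0], tlen_range[1] + 1, size=n_pairs)
    qs = aa[rng.integers(0, len(aa), size=(n_pairs, qlen_range[1]))]
    ts = aa[rng.integers(0, len(aa), size=(n_pairs, tlen_range[1]))]
    scores = batch_scores(
        np.ascontiguousarray(qs),
        q_lens.astype(np.int64),
        np.ascontiguousarray(ts),
        t_lens.astype(np.int64),
        scheme.matrix,
        scheme.gap_open,
        scheme.gap_extend,
    )
    return scores.astype(np.float64), (q_lens * t_lens).astype(np.float64)


def fit_gumbel_tail(
    scores: np.ndarray,
    mn: np.ndarray,
    censor_quantile: float = 0.9,
) -> tuple[float, float]:
    """Tail-censored maximum-likelihood Gumbel fit; returns (lambda, K).

    For score s_i with length product mn_i, the model CDF is
    ``F(s) = exp(-K mn_i e^{-lambda s})``.  Scores at or below the
    censoring threshold u contribute log F(u); exceedances contribute
    the log density.  A continuity correction of 0.5 is applied to the
    integer scores.
    """
    s = scores + 0.5
    u = float(np.quantile(s, censor_quantile))
    below = s <= u
    s_tail = s[~below]
    mn_tail = mn[~below]
    mn_below = mn[below]
    if s_tail.size < 100:
        raise ValueError("too few tail scores to fit")

    def nll(params):
        lam, logk = params
        if lam <= 0:
            return 1e12
        k = np.exp(logk)
        ll_below = -(k * mn_below * np.exp(-lam * u)).sum()
        z = k * mn_tail * np.exp(-lam * s_tail)
        ll_tail = (np.log(lam) + np.log(z) - z).sum()
        return -(ll_below + ll_tail)

    # initial lambda from the tail slope of the pooled survival curve
    res = optimize.minimize(
        nll, x0=np.array([0.3, np.log(0.1)]), method="Nelder-Mead",
        options={"xatol": 1e-6, "fatol": 1e-6, "maxiter": 5000},
    )
    lam, logk = res.x
    return float(lam), float(np.exp(logk))


def calibrate(
    n_pairs: int = 100_000,
    seed: int = 20240801,
    scheme: ScoringScheme | None = None,
) -> dict:
    """Full calibration run; returns the parameter record to ship."""
    if scheme is None:
        scheme = ScoringScheme(gumbel_lambda=1.0, gumbel_K=1.0)  # placeholders
    scores, mn = random_fragment_scores(n_pairs, scheme, seed)
    lam, K = fit_gumbel_tail(scores, mn)
    return {
        "lambda": lam,
        "K": K,
        "n_pairs": n_pairs,
        "seed": seed,
        "query_len_range": list(QUERY_LEN_RANGE),
        "target_len_range": list(TARGET_LEN_RANGE),
        "matrix": scheme.matrix_name,
        "gap_open": scheme.gap_open,
        "gap_extend": scheme.gap_extend,
    }
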