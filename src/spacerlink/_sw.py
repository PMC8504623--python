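"""Numba kernels for affine-gap Smith-Waterman on encoded protein arrays.

A gap of length g costs gap_open + (g - 1) * gap_extend.  Sequences are
int8 arrays of matrix indices (see ``scoring.encode_protein``).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG_INF = -(10**9)


@njit(cache=True)
def sw_score(a, b, matrix, gap_open, gap_extend):
    """Best local alignment score (score only, linear memory)."""
    n = b.shape[0]
    H = np.zeros(n + 1, dtype=np.int64)
    E = np.full(n + 1, NEG_INF, dtype=np.int64)
    best = 0
    for i in range(a.shape[0]):
        diag = 0  # H[i-1][j-1]
        F = NEG_INF
        for j in range(1, n + 1):
            E[j] = max(H[j] - gap_open, E[j] - gap_extend)
            F = max(H[j - 1] - gap_open, F - gap_extend)
            h = diag + matrix[a[i], b[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_matrix(a, b, matrix, gap_open, gap_extend):
    """Full H matrix of local alignment plus (best, last argmax i, j).

    Scanning keeps ties with ``>=`` so the returned cell is the last
    row-major maximum (largest i, then largest j).
    """
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full(n + 1, NEG_INF, dtype=np.int64)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        F = NEG_INF
        for j in range(1, n + 1):
            E[j] = max(H[i - 1, j] - gap_open, E[j] - gap_extend)
            F = max(H[i, j - 1] - gap_open, F - gap_extend)
            h = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            if E[j] > h:
                h = E[j]
            if F > h:
                h = F
            if h < 0:
                h = 0
            H[i, j] = h
            if h >= best and h > 0:
                best = h
                bi = i
                bj = j
    return H, best, bi, bj


@njit(cache=True)
def _sw_extent_from(a, b, matrix, gap_open, gap_extend):
    """Best alignment forced to start at (a[0], b[0]); first-maximum end.

    Returns (score, end_i, end_j) with ends exclusive; local alignments
    never end in a gap, so ends always follow a substitution.
    """
    m, n = a.shape[0], b.shape[0]
    H = np.full((m + 1, n + 1), NEG_INF, dtype=np.int64)
    E = np.full(n + 1, NEG_INF, dtype=np.int64)
    best = NEG_INF
    bi = 1
    bj = 1
    for i in range(1, m + 1):
        F = NEG_INF
        for j in range(1, n + 1):
            e = max(H[i - 1, j] - gap_open, E[j] - gap_extend)
            E[j] = e
            F = max(H[i, j - 1] - gap_open, F - gap_extend)
            if i == 1 and j == 1:
                h = matrix[a[0], b[0]]
            else:
                h = NEG_INF
                if H[i - 1, j - 1] > NEG_INF:
                    h = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if F > h:
                h = F
            H[i, j] = h
            # endpoint must be a substitution cell; strict > keeps first max
            sub = NEG_INF
            if i == 1 and j == 1:
                sub = matrix[a[0], b[0]]
            elif H[i - 1, j - 1] > NEG_INF:
                sub = H[i - 1, j - 1] + matrix[a[i - 1], b[j - 1]]
            if sub > best:
                best = sub
                bi = i
                bj = j
    return best, bi, bj


def sw_align(a: np.ndarray, b: np.ndarray, matrix: np.ndarray, gap_open: int, gap_extend: int):
    """Optimal local alignment with deterministic tie-breaking.

    Returns ``(score, q_start, q_end, t_start, t_end)`` with 0-based
    half-open coordinates.  Among co-optimal alignments the one with the
    smallest ``q_start`` is chosen, then the smallest ``t_start``.
    Implemented by aligning the reversed sequences (the last row-major
    maximum there corresponds to the smallest forward start) and then
    re-aligning forward from that fixed start to locate the end.
    """
    m, n = len(a), len(b)
    ar = np.ascontiguousarray(a[::-1])
    br = np.ascontiguousarray(b[::-1])
    _, best, bi, bj = _sw_matrix(ar, br, matrix, gap_open, gap_extend)
    if best <= 0:
        return 0, 0, 0, 0, 0
    q_start = m - bi
    t_start = n - bj
    score, ei, ej = _sw_extent_from(
        np.ascontiguousarray(a[q_start:]),
        np.ascontiguousarray(b[t_start:]),
        matrix,
        gap_open,
        gap_extend,
    )
    return int(score), q_start, q_start + int(ei), t_start, t_start + int(ej)


@njit(cache=True)
def batch_scores(qs, q_lens, ts, t_lens, matrix, gap_open, gap_extend):
    """Scores for padded batches of query/target arrays (calibration)."""
    k = q_lens.shape[0]
    out = np.empty(k, dtype=np.int64)
    for i in range(k):
        out[i] = sw_score(qs[i, : q_lens[i]], ts[i, : t_lens[i]], matrix, gap_open, gap_extend)
    return out
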