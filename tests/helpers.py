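"""Independent oracles used across the test suite.

Each oracle re-derives the checked quantity by brute force (full DP
tables, exhaustive enumeration) and stays independent of the package
code paths it validates.
"""

from __future__ import annotations

import numpy as np

from spacerlink.scoring import STANDARD_AA
from spacerlink.taxonomy import Taxonomy

NEG = float("-inf")


def gotoh_local_score(a, b, matrix, gap_open, gap_extend) -> int:
    """Quadratic-space affine-gap local alignment DP (score only)."""
    m, n = len(a), len(b)
    H = [[0] * (n + 1) for _ in range(m + 1)]
    E = [[NEG] * (n + 1) for _ in range(m + 1)]
    F = [[NEG] * (n + 1) for _ in range(m + 1)]
    best = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i][j] = max(H[i - 1][j] - gap_open, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open, F[i][j - 1] - gap_extend)
            H[i][j] = max(
                0, H[i - 1][j - 1] + matrix[a[i - 1], b[j - 1]], E[i][j], F[i][j]
            )
            best = max(best, H[i][j])
    return int(best)


def spaced_kmer_list(seq: str, offsets, span: int) -> set:
    return {
        tuple(seq[i + o] for o in offsets) for i in range(len(seq) - span + 1)
    }


def share_spaced_kmer(q: str, t: str, offsets, span: int) -> bool:
    """Exhaustive check over all window pairs."""
    for i in range(len(q) - span + 1):
        for j in range(len(t) - span + 1):
            if all(q[i + o] == t[j + o] for o in offsets):
                return True
    return False


def random_protein(rng, n: int) -> str:
    return "".join(STANDARD_AA[i] for i in rng.integers(0, 20, size=n))


def random_taxonomy(rng, max_nodes: int = 50) -> Taxonomy:
    """Random rooted tree with taxids 1..n (1 is the root)."""
    n = int(rng.integers(2, max_nodes + 1))
    nodes = {1: (1, "no rank", "root")}
    for t in range(2, n + 1):
        parent = int(rng.integers(1, t))
        nodes[t] = (parent, "clade", f"node{t}")
    return Taxonomy(nodes)


def lca_oracle(votes, tax: Taxonomy, threshold: float):
    """Exhaustive weighted-LCA: test every node, pick the lowest whose
    subtree weight strictly exceeds threshold * total (fallback: reaches
    it); ties broken by depth then smaller taxid."""
    total = sum(w for _, w in votes)
    weights = {}
    for node in tax.nodes:
        w = sum(wt for t, wt in votes if node in tax.lineage(t))
        if w > 0:
            weights[node] = w
    strict = [t for t, w in weights.items() if w > threshold * total + 1e-9]
    pool = strict or [t for t, w in weights.items() if w >= threshold * total - 1e-9]
    best = max(pool, key=lambda t: (tax.depth(t), -t))
    return best, weights[best] / total
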