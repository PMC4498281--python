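"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: exact integer enumeration for the
hypergeometric tail, the textbook pooled two-sample t test, an explicit
Pearson formula, adjacency-row-sum degrees and union-find components.
None of it shares code with the package.
"""

from __future__ import annotations

from math import comb

import numpy as np
from scipy import stats


def exact_hypergeom_tails(N: int, K: int, n: int) -> np.ndarray:
    """P(X >= k) for k = 0..min(K, n), by exact integer summation.

    Terms C(K, i) * C(N-K, n-i) are accumulated as Python ints and divided
    by C(N, n) only at the end, so every tail is exact to float rounding.
    """
    hi = min(K, n)
    lo = max(0, n - (N - K))
    terms = {i: comb(K, i) * comb(N - K, n - i) for i in range(lo, hi + 1)}
    denom = comb(N, n)
    tails = np.empty(hi + 1)
    running = 0
    for k in range(hi, lo - 1, -1):
        running += terms[k]
        tails[k] = running / denom
    tails[:lo] = 1.0
    return tails


def pooled_t_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Classic equal-variance two-sample t test (two-sided)."""
    return float(stats.ttest_ind(a, b, equal_var=True).pvalue)


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Direct sum formula for Pearson's r."""
    dx = x - x.mean()
    dy = y - y.mean()
    return float((dx * dy).sum() / np.sqrt((dx**2).sum() * (dy**2).sum()))


def adjacency_from_r(r: np.ndarray, threshold: float, mode: str = "positive") -> np.ndarray:
    crit = np.abs(r) if mode == "absolute" else r
    adj = crit > threshold
    np.fill_diagonal(adj, False)
    return adj


def union_find_components(nodes: list[str], edges: list[tuple[str, str]]) -> list[set[str]]:
    parent = {n: n for n in nodes}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for u, v in edges:
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    groups: dict[str, set[str]] = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return list(groups.values())
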