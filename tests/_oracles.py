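"""Independent brute-force oracles used only by the test suite.

Every oracle follows the printed formula or an exhaustive enumeration and
deliberately shares no code with the production paths it checks.
"""
from __future__ import annotations

import itertools
from functools import lru_cache
from math import comb

import numpy as np


def naive_levenshtein(a: str, b: str) -> int:
    """Plain memoized recursion on the textbook recurrence."""

    @lru_cache(maxsize=None)
    def d(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            d(i - 1, j) + 1,
            d(i, j - 1) + 1,
            d(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return d(len(a), len(b))


def brute_rhi(items, relation) -> float:
    """Unordered similar pairs over C(m, 2) by explicit double loop."""
    m = len(items)
    hits = sum(
        1
        for i in range(m)
        for j in range(i + 1, m)
        if relation(items[i], items[j])
    )
    return hits / comb(m, 2)


def brute_rsi(xs, ys, relation) -> float:
    """The printed RSI formula by explicit loops (self sums incl. diagonal)."""
    m, n = len(xs), len(ys)
    cross = sum(1 for a in xs for b in ys if relation(a, b)) / (n * m)
    sx = sum(1 for a in xs for b in xs if relation(a, b)) / (m * m)
    sy = sum(1 for a in ys for b in ys if relation(a, b)) / (n * n)
    return 2 * cross / (sx + sy)


def brute_rhi_weighted(items, relation) -> float:
    """Expanded-multiset oracle: each clonotype becomes CN labelled reads;
    the fraction of unordered read pairs from *distinct* clonotypes that are
    similar."""
    reads = [i for i, c in enumerate(items) for _ in range(c.copy_number)]
    num = 0
    den = 0
    for a, b in itertools.combinations(reads, 2):
        if a == b:
            continue
        den += 1
        if relation(items[a], items[b]):
            num += 1
    return num / den


def morisita_horn(x: np.ndarray, y: np.ndarray) -> float:
    """Textbook Morisita-Horn on two aligned count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    p, q = x / x.sum(), y / y.sum()
    return 2 * float(p @ q) / (float(p @ p) + float(q @ q))


def sorensen(sa: set, sb: set) -> float:
    return 2 * len(sa & sb) / (len(sa) + len(sb))


def holm_by_hand(pvals) -> list[float]:
    """Step-down Holm with running maximum, capped at 1."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, min(1.0, (n - rank) * pvals[i]))
        adj[i] = running
    return adj


def fisher_by_enumeration(table) -> float:
    """Two-sided Fisher p by enumerating all 2x2 tables with fixed margins."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(aa: int) -> float:
        bb, cc = r1 - aa, c1 - aa
        dd = r2 - cc
        if min(bb, cc, dd) < 0:
            return 0.0
        return comb(r1, aa) * comb(r2, cc) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(0, min(r1, c1) + 1) if prob(k) <= p_obs * (1 + 1e-12))


def exhaustive_kmedoids_cost(d: np.ndarray, k: int = 2) -> float:
    """Optimal k-medoid cost by exhaustive search over medoid subsets."""
    n = d.shape[0]
    best = np.inf
    for medoids in itertools.combinations(range(n), k):
        cost = d[:, medoids].min(axis=1).sum()
        best = min(best, cost)
    return float(best)


def mann_whitney_exact_two_sided(a, b) -> float:
    """Exact two-sided Mann-Whitney p by full enumeration of group splits.

    Only feasible for small samples without ties; p = fraction of splits with
    a U statistic at least as extreme (min(U, nm - U) <= observed min).
    """
    a, b = list(a), list(b)
    pooled = a + b
    n, m = len(a), len(b)
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_of(group):
        rest = [x for x in pooled if x not in group]
        return sum(1 for x in group for y in rest if x > y)

    u_obs = u_of(a)
    stat_obs = min(u_obs, n * m - u_obs)
    hits = 0
    total = 0
    for combo in itertools.combinations(pooled, n):
        u = u_of(list(combo))
        if min(u, n * m - u) <= stat_obs:
            hits += 1
        total += 1
    return hits / total
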