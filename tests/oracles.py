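"""Independent brute-force reference implementations used only by the tests.

Every oracle here is written from the mathematical definition, sharing no
code with the package: exhaustive DTW path enumeration, naive O(n^3)
agglomerative linkage, direct-loop validity indices, normal-equations OLS,
and full-enumeration hypergeometric exact inference.
"""

import math
from functools import lru_cache

import numpy as np


# ---------------------------------------------------------------- DTW ------

@lru_cache(maxsize=None)
def dtw_paths(n, m):
    """Every monotone path from (0,0) to (n-1,m-1) with steps (1,0),(0,1),(1,1)."""
    if n == 1 and m == 1:
        return [[(0, 0)]]
    paths = []
    if n > 1:
        paths += [p + [(n - 1, m - 1)] for p in dtw_paths(n - 1, m)]
    if m > 1:
        paths += [p + [(n - 1, m - 1)] for p in dtw_paths(n, m - 1)]
    if n > 1 and m > 1:
        paths += [p + [(n - 1, m - 1)] for p in dtw_paths(n - 1, m - 1)]
    return paths


def dtw_bruteforce(x, y, open_end):
    """Minimal cumulative squared-Euclidean cost by exhaustive enumeration."""
    x, y = np.atleast_2d(x), np.atleast_2d(y)
    n, m = len(x), len(y)
    cost = np.array([[np.sum((xi - yj) ** 2) for yj in y] for xi in x])
    if open_end:
        ends = {(i, m - 1) for i in range(n)} | {(n - 1, j) for j in range(m)}
    else:
        ends = {(n - 1, m - 1)}
    best = math.inf
    for ei, ej in ends:
        for path in dtw_paths(ei + 1, ej + 1):
            best = min(best, sum(cost[i, j] for i, j in path))
    return best


# ---------------------------------------------------- hierarchical linkage -

def naive_linkage_cut(d, k, linkage):
    """Flat k-partition from naive agglomerative clustering of matrix d.

    Clusters are merged greedily by the linkage distance recomputed from the
    original pairwise matrix at every step. Returns a label array (arbitrary
    label values) once k clusters remain.
    """
    n = len(d)
    clusters = [[i] for i in range(n)]
    agg = {"complete": max, "single": min,
           "average": lambda v: sum(v) / len(v)}[linkage]
    while len(clusters) > k:
        best, pair = math.inf, None
        for a in range(len(clusters)):
            for b in range(a + 1, len(clusters)):
                dist = agg([d[i][j] for i in clusters[a] for j in clusters[b]])
                if dist < best:
                    best, pair = dist, (a, b)
        a, b = pair
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    labels = np.empty(n, dtype=int)
    for lab, members in enumerate(clusters):
        labels[list(members)] = lab
    return labels


# ------------------------------------------------------- validity indices --

def connectivity_bruteforce(d, labels, neighbors):
    """Direct-loop connectivity with (distance, index) neighbour ordering."""
    n = len(d)
    c = 0.0
    for i in range(n):
        ranked = sorted((j for j in range(n) if j != i),
                        key=lambda j: (d[i][j], j))
        for pos, j in enumerate(ranked[:neighbors], start=1):
            if labels[j] != labels[i]:
                c += 1.0 / pos
    return c


def dunn_bruteforce(d, labels):
    """min inter-cluster point distance / max within-cluster diameter."""
    groups = sorted(set(labels))
    diam = 0.0
    for g in groups:
        idx = [i for i, l in enumerate(labels) if l == g]
        for a in idx:
            for b in idx:
                diam = max(diam, d[a][b])
    inter = math.inf
    for gi, g in enumerate(groups):
        for h in groups[gi + 1:]:
            for a in (i for i, l in enumerate(labels) if l == g):
                for b in (i for i, l in enumerate(labels) if l == h):
                    inter = min(inter, d[a][b])
    return inter / diam


# ------------------------------------------------------------------- OLS ---

def ols_normal_equations(X, y):
    """(intercept, coef) via the normal equations (A'A) beta = A'y."""
    A = np.column_stack([np.ones(len(y)), X])
    beta = np.linalg.solve(A.T @ A, A.T @ y)
    return beta[0], beta[1:]


# ------------------------------------------------- exact 2x2 inference -----

def hypergeom_pmf(x, row1, col1, total):
    """P(cell a = x) under fixed margins (noncentral parameter 1)."""
    return (math.comb(col1, x) * math.comb(total - col1, row1 - x)
            / math.comb(total, row1))


def fisher_p_bruteforce(a, b, c, d):
    """Two-sided Fisher p: sum of table probabilities <= observed's."""
    row1, col1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    p_obs = hypergeom_pmf(a, row1, col1, total)
    return sum(p for x in range(lo, hi + 1)
               if (p := hypergeom_pmf(x, row1, col1, total)) <= p_obs * (1 + 1e-9))


def cmle_or_bruteforce(a, b, c, d):
    """Conditional MLE odds ratio by solving the score equation numerically.

    E_psi[A] = a where A follows the noncentral hypergeometric distribution
    with the table's margins; bisection on log(psi). Returns inf/0 when the
    observed count sits on the support boundary.
    """
    row1, col1, total = a + b, a + c, a + b + c + d
    lo, hi = max(0, row1 + col1 - total), min(row1, col1)
    if a == hi:
        return math.inf
    if a == lo:
        return 0.0
    support = list(range(lo, hi + 1))
    w0 = [hypergeom_pmf(x, row1, col1, total) for x in support]

    def mean(logpsi):
        w = [wx * math.exp(x * logpsi) for wx, x in zip(w0, support)]
        s = sum(w)
        return sum(x * wx for x, wx in zip(support, w)) / s

    left, right = -50.0, 50.0
    for _ in range(200):
        mid = 0.5 * (left + right)
        if mean(mid) < a:
            left = mid
        else:
            right = mid
    return math.exp(0.5 * (left + right))
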