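"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from textbook definitions with plain loops and
exact arithmetic, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def pearson_loop(x, y) -> float:
    """Textbook Pearson correlation with explicit sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(sum((a - mx) ** 2 for a in x)) * math.sqrt(sum((b - my) ** 2 for b in y))
    return num / den


def bh_survivors(pvals, q) -> set:
    """Benjamini-Hochberg step-up: indices of rejected hypotheses."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    kmax = 0
    for rank, i in enumerate(order, start=1):
        if pvals[i] <= q * rank / m:
            kmax = rank
    return set(order[:kmax])


def walk_product_loop(A, B) -> np.ndarray:
    """Triple-loop walk accumulation sum_k A[i,k] B[k,j], diagonal zeroed."""
    n = len(A)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            acc = 0.0
            for k in range(n):
                acc += A[i][k] * B[k][j]
            out[i, j] = acc
    return out


def walk_count(A, length: int) -> np.ndarray:
    """Number (or weight-sum) of walks of a given length via repeated loops."""
    M = np.asarray(A, dtype=float)
    out = M.copy()
    for _ in range(length - 1):
        nxt = np.zeros_like(out)
        n = out.shape[0]
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    nxt[i, j] += out[i, k] * M[k, j]
        out = nxt
    return out


def ols_t_normal_equations(X, y):
    """OLS via explicit normal equations; returns (beta, t) for every coefficient."""
    X = np.asarray(X, float)
    y = np.asarray(y, float)
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    df = X.shape[0] - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    t = beta / np.sqrt(np.diag(cov))
    return beta, t


def hypergeom_upper_tail(k, K, n, N) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n), exact rational arithmetic."""
    total = Fraction(0)
    for x in range(k, min(n, K) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))
    return float(total)


def bfs_closeness(adj: dict, node, n_total: int) -> float:
    """Hop-count closeness with Wasserman-Faust component scaling."""
    dist = {node: 0}
    frontier = [node]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj.get(u, ()):
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    m = len(dist)
    if m < 2:
        return 0.0
    s = sum(dist.values())
    return ((m - 1) / s) * ((m - 1) / (n_total - 1))


def grouped_mean(values, labels) -> dict:
    """Loop-and-average per label, skipping label 0."""
    sums, counts = {}, {}
    for v, g in zip(values, labels):
        if g == 0:
            continue
        sums[g] = sums.get(g, 0.0) + v
        counts[g] = counts.get(g, 0) + 1
    return {g: sums[g] / counts[g] for g in sums}
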