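"""Brute-force reference implementations used as independent oracles.

Everything here is deliberately naive — explicit all-pairs BFS with
geodesic counting, dense eigendecomposition, loop-based sums — and shares
no code with the production paths it is used to check.
"""

from __future__ import annotations

from collections import deque

import numpy as np


def bfs_geodesics(C: np.ndarray, source: int) -> tuple[np.ndarray, np.ndarray]:
    """Shortest-path distances and geodesic counts from one node."""
    n = len(C)
    dist = np.full(n, np.inf)
    count = np.zeros(n)
    dist[source] = 0
    count[source] = 1
    q = deque([source])
    while q:
        u = q.popleft()
        for w in np.flatnonzero(C[u]):
            if np.isinf(dist[w]):
                dist[w] = dist[u] + 1
                q.append(w)
            if dist[w] == dist[u] + 1:
                count[w] += count[u]
    return dist, count


def betweenness_bruteforce(C: np.ndarray) -> np.ndarray:
    """Freeman betweenness by enumerating every unordered pair."""
    C = np.asarray(C)
    n = len(C)
    dist = np.empty((n, n))
    count = np.empty((n, n))
    for s in range(n):
        dist[s], count[s] = bfs_geodesics(C, s)
    b = np.zeros(n)
    for i in range(n):
        for j in range(n):
            for k in range(j + 1, n):
                if i in (j, k) or np.isinf(dist[j, k]):
                    continue
                if dist[j, i] + dist[i, k] == dist[j, k]:
                    b[i] += count[j, i] * count[i, k] / count[j, k]
    return b


def closeness_bruteforce(C: np.ndarray) -> np.ndarray:
    """Wasserman-Faust closeness: within-component, scaled by (n_c-1)/(N-1)."""
    C = np.asarray(C)
    n = len(C)
    cl = np.zeros(n)
    for i in range(n):
        dist, _ = bfs_geodesics(C, i)
        reach = np.isfinite(dist) & (np.arange(n) != i)
        n_c = reach.sum() + 1
        if n_c > 1:
            cl[i] = (n_c - 1) / dist[reach].sum() * (n_c - 1) / (n - 1)
    return cl


def degree_bruteforce(C: np.ndarray) -> np.ndarray:
    return np.asarray(C).sum(axis=1)


def eigenvector_bruteforce(C: np.ndarray) -> tuple[float, np.ndarray]:
    """Largest adjacency eigenvalue and a matching unit eigenvector (dense)."""
    C = np.asarray(C, dtype=float)
    vals, vecs = np.linalg.eigh(C)
    v = vecs[:, -1]
    if v.sum() < 0:
        v = -v
    return float(vals[-1]), v


def entropy_bruteforce(b: np.ndarray) -> float:
    """Shannon entropy (bits) of a nonnegative vector normalized to sum 1."""
    b = np.asarray(b, dtype=float)
    total = b.sum()
    if total == 0:
        return 0.0
    h = 0.0
    for x in b / total:
        if x > 0:
            h -= x * np.log2(x)
    return h


def expected_deaths_loop(R, n) -> float:
    """Plain-loop weighted sum, the oracle for the vectorized version."""
    total = 0.0
    for r_i, n_i in zip(R, n):
        total += r_i * n_i
    return total


def pearson_on_ranks(a, b) -> float:
    """Spearman correlation as Pearson on average ranks, computed by hand."""

    def ranks(x):
        x = np.asarray(x, dtype=float)
        order = np.argsort(x, kind="stable")
        r = np.empty(len(x))
        i = 0
        while i < len(x):
            j = i
            while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
                j += 1
            r[order[i : j + 1]] = (i + j) / 2 + 1
            i = j + 1
        return r

    ra, rb = ranks(a), ranks(b)
    ra -= ra.mean()
    rb -= rb.mean()
    return float((ra @ rb) / np.sqrt((ra @ ra) * (rb @ rb)))
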