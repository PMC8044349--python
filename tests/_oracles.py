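"""Independent brute-force oracles used by the test suite.

Everything here is computed by a different route than the library: distances
and shortest-path counts via adjacency-matrix powers, clustering via triple
enumeration, betweenness via the sigma-product identity on matrix-power
counts, AUC via all-pairs comparison, BH via the literal step-up recursion.
"""

from __future__ import annotations

import itertools

import numpy as np


def distances_by_matrix_powers(a: np.ndarray) -> np.ndarray:
    """d[i, j] = smallest k with (A^k)[i, j] > 0 (inf if never, 0 on diag)."""
    n = a.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    power = np.eye(n)
    for k in range(1, n):
        power = power @ a
        newly = (power > 0) & np.isinf(d)
        d[newly] = k
    return d


def path_counts_by_matrix_powers(a: np.ndarray) -> np.ndarray:
    """sigma[i, j] = number of shortest paths between i and j."""
    n = a.shape[0]
    d = distances_by_matrix_powers(a)
    sigma = np.zeros((n, n))
    power = np.eye(n)
    for k in range(0, n):
        mask = d == k
        sigma[mask] = power[mask]
        power = power @ a
    return sigma


def lp_oracle(a: np.ndarray) -> float:
    d = distances_by_matrix_powers(a)
    n = a.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        return float("inf")
    return float(d[finite].mean())


def eg_oracle(a: np.ndarray) -> float:
    d = distances_by_matrix_powers(a)
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def eloc_oracle(a: np.ndarray) -> float:
    n = a.shape[0]
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size >= 2:
            total += eg_oracle(a[np.ix_(nb, nb)])
    return total / n


def cp_oracle(a: np.ndarray) -> float:
    """Clustering by exhaustive triple enumeration."""
    n = a.shape[0]
    cs = []
    for i in range(n):
        nb = np.flatnonzero(a[i])
        k = nb.size
        if k < 2:
            cs.append(0.0)
            continue
        tri = sum(1 for u, v in itertools.combinations(nb, 2) if a[u, v])
        cs.append(2.0 * tri / (k * (k - 1)))
    return float(np.mean(cs))


def bc_oracle(a: np.ndarray) -> np.ndarray:
    """Betweenness via sigma_st(v) = sigma_sv * sigma_vt when v lies on a
    shortest s-t path (d(s,v) + d(v,t) = d(s,t))."""
    n = a.shape[0]
    d = distances_by_matrix_powers(a)
    sigma = path_counts_by_matrix_powers(a)
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        if not np.isfinite(d[s, t]) or sigma[s, t] == 0:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            if d[s, v] + d[v, t] == d[s, t]:
                bc[v] += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return bc


def auc_all_pairs(pos: np.ndarray, neg: np.ndarray) -> float:
    """AUC by exhaustive pair comparison, ties counted 1/2."""
    total = 0.0
    for x in pos:
        for y in neg:
            if x > y:
                total += 1.0
            elif x == y:
                total += 0.5
    return total / (len(pos) * len(neg))


def bh_oracle(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up by the literal definition."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        val = min(prev, p[idx] * m / rank_from_top)
        adj[idx] = val
        prev = val
    return adj


def pooled_t(x: np.ndarray, y: np.ndarray) -> float:
    """Classical pooled two-sample t statistic (x minus y)."""
    nx, ny = len(x), len(y)
    sp2 = ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    return float((np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1 / nx + 1 / ny)))


def components_by_union_find(
    edges: list[tuple[int, int]]
) -> list[set[tuple[int, int]]]:
    """Connected edge components via a plain union-find, largest first."""
    parent: dict[int, int] = {}

    def find(u):
        while parent[u] != u:
            u = parent[u]
        return u

    for i, j in edges:
        parent.setdefault(i, i)
        parent.setdefault(j, j)
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri
    groups: dict[int, set[tuple[int, int]]] = {}
    for i, j in edges:
        groups.setdefault(find(i), set()).add((i, j))
    return sorted(groups.values(), key=len, reverse=True)


def random_graph(rng: np.random.Generator, n: int, p: float) -> np.ndarray:
    """Symmetric zero-diagonal Bernoulli adjacency."""
    a = (rng.random((n, n)) < p).astype(np.int8)
    a = np.triu(a, k=1)
    return a + a.T
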