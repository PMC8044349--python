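"""Global and nodal graph metrics on binary connectomes.

Implements the small-world battery used in structural-connectome studies:
characteristic path length Lp, global efficiency Eg, local efficiency Eloc,
clustering coefficient Cp, per-node betweenness centrality BC, and the
normalized ratios gamma = Cp / <Cp_null>, lambda = Lp / <Lp_null>,
sigma = gamma / lambda against an ensemble of degree-preserving rewired
random networks (default 100 nulls, Maslov-Sneppen double-edge swaps).

All metrics are computed on the *binary* adjacency (the edge rule that
defines the network is binary). Disconnected graphs are handled by the
reachable-pairs convention: Lp and BC average over reachable pairs only and
results carry a ``connected=False`` flag; Eg treats 1/infinity as 0
natively.

Betweenness is reported unnormalized (raw sums of shortest-path fractions),
the magnitude scale on which nodal hub values for a 90-node connectome land
in the hundreds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components, shortest_path

__all__ = [
    "GlobalMetrics",
    "NodalMetrics",
    "NullEnsemble",
    "shortest_paths",
    "characteristic_path_length",
    "is_connected",
    "global_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness_centrality",
    "degree_preserving_rewire",
    "small_world",
]


@dataclass(frozen=True)
class GlobalMetrics:
    """Global metric set of one binary connectome.

    ``lam`` is the path-length ratio usually written lambda (reserved word in
    Python). ``sigma == gamma / lam`` holds exactly by construction. gamma,
    lam, sigma are NaN when computed without a null ensemble.
    """

    lp: float
    eg: float
    eloc: float
    cp: float
    gamma: float
    lam: float
    sigma: float
    n_null: int
    connected: bool


@dataclass(frozen=True)
class NodalMetrics:
    """Per-node betweenness centrality (unnormalized)."""

    bc: np.ndarray


@dataclass
class NullEnsemble:
    """Degree-preserving rewired nulls with their Cp and Lp."""

    matrices: list[np.ndarray]
    cp: np.ndarray
    lp: np.ndarray


def _validate_adjacency(adjacency: np.ndarray) -> np.ndarray:
    a = np.asarray(adjacency)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    vals = np.unique(a)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError("adjacency must be binary (0/1)")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diagonal(a) != 0):
        raise ValueError("adjacency must have a zero diagonal")
    return a.astype(np.int8)


def shortest_paths(adjacency: np.ndarray) -> np.ndarray:
    """All-pairs hop-count distances; unreachable pairs are infinite."""
    a = _validate_adjacency(adjacency)
    if a.shape[0] == 0:
        return np.zeros((0, 0))
    return shortest_path(csr_matrix(a), method="D", unweighted=True, directed=False)


def is_connected(adjacency: np.ndarray) -> bool:
    a = _validate_adjacency(adjacency)
    if a.shape[0] <= 1:
        return True
    n_comp, _ = connected_components(csr_matrix(a), directed=False)
    return n_comp == 1


def characteristic_path_length(adjacency: np.ndarray) -> float:
    """Mean hop distance over reachable ordered pairs i != j.

    Returns inf when no pair is reachable (edgeless graph). For
    disconnected graphs unreachable pairs are excluded (see module docs);
    use :func:`is_connected` / the GlobalMetrics flag to detect that case.
    """
    d = shortest_paths(adjacency)
    n = d.shape[0]
    if n < 2:
        raise ValueError("characteristic path length needs >= 2 nodes")
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    if not finite.any():
        return float("inf")
    return float(d[finite].mean())


def global_efficiency(adjacency: np.ndarray) -> float:
    """Mean inverse hop distance over ordered pairs i != j (1/inf = 0)."""
    d = shortest_paths(adjacency)
    n = d.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs >= 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return float(inv[off].mean())


def local_efficiency(adjacency: np.ndarray) -> float:
    """Mean over nodes of the global efficiency of the neighbor subgraph
    (0 for nodes with < 2 neighbors)."""
    a = _validate_adjacency(adjacency)
    n = a.shape[0]
    if n < 2:
        raise ValueError("local efficiency needs >= 2 nodes")
    effs = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(a[i])
        if nb.size < 2:
            continue
        effs[i] = global_efficiency(a[np.ix_(nb, nb)])
    return float(effs.mean())


def clustering_coefficient(adjacency: np.ndarray) -> float:
    """Mean over nodes of 2*T_i / (k_i (k_i - 1)), 0 when k_i < 2."""
    a = _validate_adjacency(adjacency).astype(float)
    n = a.shape[0]
    if n == 0:
        return 0.0
    k = a.sum(axis=1)
    closed_walks = np.diagonal(a @ a @ a)  # 2 * triangles per node
    denom = k * (k - 1)
    c = np.zeros(n)
    mask = denom > 0
    c[mask] = closed_walks[mask] / denom[mask]
    return float(c.mean())


def betweenness_centrality(adjacency: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness: bc[v] = sum over unordered pairs s != t != v
    of sigma_st(v) / sigma_st (Brandes' algorithm)."""
    a = _validate_adjacency(adjacency)
    g = nx.from_numpy_array(a)
    bc = nx.betweenness_centrality(g, normalized=False)
    return np.array([bc[i] for i in range(a.shape[0])])


def degree_preserving_rewire(
    adjacency: np.ndarray,
    n_swaps: int | None = None,
    rng: np.random.Generator | None = None,
    require_connected: bool | None = None,
    max_restarts: int = 20,
) -> np.ndarray:
    """Randomize a binary graph by double-edge swaps, preserving every degree.

    ``n_swaps`` swap *attempts* are made (default 10x the edge count);
    attempts creating self-loops or multi-edges are rejected, so the degree
    sequence is invariant by construction. When the input is connected (or
    ``require_connected=True``) the whole rewire is redrawn until the result
    is connected, up to ``max_restarts`` times. Graphs admitting no valid
    swap (e.g. a triangle) come back unchanged with a warning.
    """
    a = _validate_adjacency(adjacency)
    rng = np.random.default_rng() if rng is None else rng
    edges0 = [tuple(e) for e in np.argwhere(np.triu(a, k=1))]
    m = len(edges0)
    if m < 2:
        warnings.warn("fewer than 2 edges; nothing to rewire", stacklevel=2)
        return a.copy()
    if n_swaps is None:
        n_swaps = 10 * m
    if n_swaps < 1:
        raise ValueError("n_swaps must be >= 1")
    if require_connected is None:
        require_connected = is_connected(a)

    for _ in range(max_restarts):
        edges = list(edges0)
        eset = set(edges)
        pair_idx = rng.integers(0, m, size=(n_swaps, 2))
        flips = rng.random(n_swaps) < 0.5
        accepted = 0
        for (i, j), flip in zip(pair_idx.tolist(), flips.tolist()):
            if i == j:
                continue
            a1, b1 = edges[i]
            c1, d1 = edges[j]
            if flip:
                c1, d1 = d1, c1
            # propose (a1,b1),(c1,d1) -> (a1,d1),(c1,b1)
            if a1 == d1 or c1 == b1:
                continue
            e1 = (a1, d1) if a1 < d1 else (d1, a1)
            e2 = (c1, b1) if c1 < b1 else (b1, c1)
            if e1 in eset or e2 in eset:
                continue
            eset.discard(edges[i])
            eset.discard(edges[j])
            edges[i] = e1
            edges[j] = e2
            eset.add(e1)
            eset.add(e2)
            accepted += 1
        out = np.zeros_like(a)
        if edges:
            arr = np.array(edges)
            out[arr[:, 0], arr[:, 1]] = 1
            out[arr[:, 1], arr[:, 0]] = 1
        if accepted == 0:
            warnings.warn(
                "no valid double-edge swap exists; returning input unchanged",
                stacklevel=2,
            )
            return a.copy()
        if not require_connected or is_connected(out):
            return out
    raise RuntimeError(
        f"rewired graph stayed disconnected after {max_restarts} restarts"
    )


def _cp_lp(a: np.ndarray) -> tuple[float, float]:
    return clustering_coefficient(a), characteristic_path_length(a)


def small_world(
    adjacency: np.ndarray,
    n_null: int = 100,
    rng: np.random.Generator | None = None,
    n_swaps: int | None = None,
    return_ensemble: bool = False,
) -> GlobalMetrics | tuple[GlobalMetrics, NullEnsemble]:
    """Small-world battery with degree-preserving random-network normalization.

    gamma = Cp / mean(Cp over ``n_null`` rewired networks), lambda likewise
    for Lp, sigma = gamma / lambda (exact identity). Disconnected inputs are
    processed under the reachable-pairs convention with ``connected=False``
    and nulls rewired without the connectivity constraint.
    """
    a = _validate_adjacency(adjacency)
    if a.shape[0] < 4:
        raise ValueError("small-world analysis needs >= 4 nodes")
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    connected = is_connected(a)
    cp_real, lp_real = _cp_lp(a)
    eg = global_efficiency(a)
    eloc = local_efficiency(a)

    mats: list[np.ndarray] = []
    cps = np.empty(n_null)
    lps = np.empty(n_null)
    for k in range(n_null):
        null = degree_preserving_rewire(
            a, n_swaps=n_swaps, rng=rng, require_connected=connected
        )
        cps[k], lps[k] = _cp_lp(null)
        if return_ensemble:
            mats.append(null)

    mean_cp = float(cps.mean())
    mean_lp = float(lps.mean())
    gamma = cp_real / mean_cp if mean_cp > 0 else float("nan")
    lam = lp_real / mean_lp if mean_lp > 0 else float("nan")
    sigma = gamma / lam
    gm = GlobalMetrics(
        lp=lp_real,
        eg=eg,
        eloc=eloc,
        cp=cp_real,
        gamma=gamma,
        lam=lam,
        sigma=sigma,
        n_null=n_null,
        connected=connected,
    )
    if return_ensemble:
        return gm, NullEnsemble(matrices=mats, cp=cps, lp=lps)
    return gm
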