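"""Graph metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest

from strucnet.metrics import (
    betweenness_centrality,
    characteristic_path_length,
    clustering_coefficient,
    degree_preserving_rewire,
    global_efficiency,
    is_connected,
    local_efficiency,
    shortest_paths,
    small_world,
)

from _oracles import (
    bc_oracle,
    cp_oracle,
    distances_by_matrix_powers,
    eg_oracle,
    eloc_oracle,
    lp_oracle,
    random_graph,
)


def path3():
    a = np.zeros((3, 3), dtype=int)
    a[0, 1] = a[1, 0] = a[1, 2] = a[2, 1] = 1
    return a


def complete(n):
    return (np.ones((n, n)) - np.eye(n)).astype(int)


def star(leaves):
    a = np.zeros((leaves + 1, leaves + 1), dtype=int)
    a[0, 1:] = 1
    a[1:, 0] = 1
    return a


def test_shortest_paths_small_cases():
    d = shortest_paths(path3())
    assert d[0, 2] == 2 and d[0, 1] == 1 and d[0, 0] == 0
    assert np.all(shortest_paths(complete(4))[~np.eye(4, dtype=bool)] == 1)
    two_k2 = np.zeros((4, 4), dtype=int)
    two_k2[0, 1] = two_k2[1, 0] = two_k2[2, 3] = two_k2[3, 2] = 1
    d = shortest_paths(two_k2)
    assert np.isinf(d[0, 2])


def test_shortest_paths_rejects_nonbinary():
    with pytest.raises(ValueError, match="binary"):
        shortest_paths(np.array([[0, 2], [2, 0]]))


def test_characteristic_path_length_conventions():
    assert characteristic_path_length(complete(4)) == 1.0
    assert characteristic_path_length(path3()) == pytest.approx(4 / 3)
    two_k2 = np.zeros((4, 4), dtype=int)
    two_k2[0, 1] = two_k2[1, 0] = two_k2[2, 3] = two_k2[3, 2] = 1
    # unreachable pairs excluded; the disconnection is flagged separately
    assert characteristic_path_length(two_k2) == 1.0
    assert not is_connected(two_k2)
    assert characteristic_path_length(np.zeros((3, 3), dtype=int)) == np.inf


def test_efficiency_and_clustering_closed_forms():
    assert global_efficiency(complete(5)) == 1.0
    assert global_efficiency(path3()) == pytest.approx(5 / 6)
    assert global_efficiency(np.zeros((4, 4), dtype=int)) == 0.0
    assert local_efficiency(complete(4)) == 1.0
    assert local_efficiency(star(4)) == 0.0
    assert clustering_coefficient(complete(4)) == 1.0
    assert clustering_coefficient(star(4)) == 0.0


def test_betweenness_closed_forms():
    assert np.array_equal(betweenness_centrality(path3()), [0.0, 1.0, 0.0])
    bc = betweenness_centrality(star(4))
    assert bc[0] == 6.0  # C(4,2) leaf pairs all route through the hub
    assert np.all(bc[1:] == 0)


def test_all_metrics_match_bruteforce_oracles(rng):
    for _ in range(40):
        n = int(rng.integers(4, 9))
        a = random_graph(rng, n, float(rng.uniform(0.2, 0.8)))
        assert np.array_equal(shortest_paths(a), distances_by_matrix_powers(a))
        assert characteristic_path_length(a) == pytest.approx(lp_oracle(a))
        assert global_efficiency(a) == pytest.approx(eg_oracle(a))
        assert local_efficiency(a) == pytest.approx(eloc_oracle(a))
        assert clustering_coefficient(a) == pytest.approx(cp_oracle(a))
        assert betweenness_centrality(a) == pytest.approx(bc_oracle(a))


def test_permutation_equivariance(rng):
    a = random_graph(rng, 10, 0.4)
    perm = rng.permutation(10)
    ap = a[np.ix_(perm, perm)]
    assert betweenness_centrality(ap) == pytest.approx(betweenness_centrality(a)[perm])
    assert clustering_coefficient(ap) == pytest.approx(clustering_coefficient(a))
    assert global_efficiency(ap) == pytest.approx(global_efficiency(a))
    assert characteristic_path_length(ap) == pytest.approx(
        characteristic_path_length(a)
    )


def test_adding_edges_monotone_for_lp_and_eg(rng):
    # monotonicity holds on connected graphs (on disconnected ones a bridge
    # adds long reachable distances under the reachable-pairs convention)
    for _ in range(20):
        a = random_graph(rng, 9, 0.4)
        if not is_connected(a):
            continue
        zeros = np.argwhere(np.triu(a == 0, k=1))
        if len(zeros) == 0:
            continue
        i, j = zeros[rng.integers(len(zeros))]
        b = a.copy()
        b[i, j] = b[j, i] = 1
        if np.isfinite(characteristic_path_length(a)):
            assert characteristic_path_length(b) <= characteristic_path_length(a) + 1e-12
        assert global_efficiency(b) >= global_efficiency(a) - 1e-12


def test_rewiring_preserves_degree_sequence(rng):
    for _ in range(10):
        a = random_graph(rng, 15, 0.3)
        if not is_connected(a):
            continue
        b = degree_preserving_rewire(a, rng=rng)
        assert np.array_equal(a.sum(1), b.sum(1))
        assert np.all(np.diagonal(b) == 0)
        assert np.array_equal(b, b.T)
        assert is_connected(b)


def test_triangle_has_no_valid_swap(rng):
    k3 = (np.ones((3, 3)) - np.eye(3)).astype(int)
    with pytest.warns(UserWarning, match="no valid"):
        out = degree_preserving_rewire(k3, rng=rng)
    assert np.array_equal(out, k3)


def test_rewiring_destroys_lattice_clustering(rng):
    # ring lattice n=20, k=4: high clustering that random rewiring erodes
    n, half = 20, 2
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for d in range(1, half + 1):
            a[i, (i + d) % n] = a[(i + d) % n, i] = 1
    cp_lattice = clustering_coefficient(a)
    cps = [
        clustering_coefficient(degree_preserving_rewire(a, rng=rng))
        for _ in range(20)
    ]
    assert np.mean(cps) < 0.6 * cp_lattice


def test_sigma_identity_and_null_degree_sequence(rng):
    a = random_graph(rng, 20, 0.3)
    while not is_connected(a):
        a = random_graph(rng, 20, 0.3)
    gm, ens = small_world(a, n_null=10, rng=rng, return_ensemble=True)
    assert gm.sigma == gm.gamma / gm.lam  # exact identity
    for null in ens.matrices:
        assert np.array_equal(null.sum(1), a.sum(1))


def test_small_world_regimes(rng):
    # Watts-Strogatz-like ring lattice with shortcuts: sigma > 1
    n, half = 60, 3
    a = np.zeros((n, n), dtype=int)
    for i in range(n):
        for d in range(1, half + 1):
            a[i, (i + d) % n] = a[(i + d) % n, i] = 1
    for _ in range(18):  # ~10% shortcut edges
        i, j = rng.integers(0, n, 2)
        if i != j:
            a[i, j] = a[j, i] = 1
    gm = small_world(a, n_null=30, rng=rng)
    assert gm.sigma > 1.0
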