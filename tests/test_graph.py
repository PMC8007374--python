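"""Graph metrics against brute-force oracles; thresholding; small-world nulls."""

import numpy as np
import pytest

from cohnet import (
    auto_threshold,
    binarize,
    clustering,
    degree,
    global_efficiency,
    local_efficiency,
    metrics_suite,
    network_metrics,
    optimal_path_length,
    rewire_degree_preserving,
    shortest_paths,
    small_world,
)
from cohnet.containers import BinaryNetwork

from conftest import make_matrix, random_binary_network


# ---------------------------------------------------------------------------
# independent brute-force oracles


def floyd_warshall(adj):
    n = adj.shape[0]
    d = np.where(adj > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def brute_clustering(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for a in range(n):
        nbrs = np.flatnonzero(adj[a])
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(adj[u, v] for i, u in enumerate(nbrs) for v in nbrs[i + 1:])
        out[a] = 2 * links / (k * (k - 1))
    return out


def brute_local_efficiency(adj):
    n = adj.shape[0]
    out = np.zeros(n)
    for a in range(n):
        nbrs = np.flatnonzero(adj[a])
        k = len(nbrs)
        if k < 2:
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        d = floyd_warshall(sub)
        inv = 0.0
        for i in range(k):
            for j in range(k):
                if i != j and np.isfinite(d[i, j]):
                    inv += 1.0 / d[i, j]
        out[a] = inv / (k * (k - 1))
    return out


def exhaustive_auto_threshold(values):
    """Largest distinct coherence value leaving no isolated node."""
    v = values.copy()
    np.fill_diagonal(v, -1)
    candidates = np.unique(v[v >= 0])
    best = None
    for thr in candidates:
        adj = (values >= thr).astype(int)
        np.fill_diagonal(adj, 0)
        if (adj.sum(axis=0) > 0).all():
            best = thr if best is None else max(best, thr)
    return best


def path_graph(n=3):
    adj = np.zeros((n, n), int)
    for i in range(n - 1):
        adj[i, i + 1] = adj[i + 1, i] = 1
    return BinaryNetwork(adj, [chr(65 + i) for i in range(n)], 0.5)


def complete_graph(n):
    adj = np.ones((n, n), int) - np.eye(n, dtype=int)
    return BinaryNetwork(adj, [f"n{i}" for i in range(n)], 0.5)


# ---------------------------------------------------------------------------


class TestBinarize:
    def test_uniform_matrix_auto_gives_complete_graph(self):
        v = np.full((4, 4), 0.5)
        np.fill_diagonal(v, 1.0)
        net = binarize(make_matrix(v), "auto")
        assert net.threshold_used == pytest.approx(0.5)
        assert net.n_edges == 6

    def test_three_node_worked_example(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 0.4
        v[1, 2] = v[2, 1] = 0.3
        net = binarize(make_matrix(v, labels=["A", "B", "C"]), "auto")
        assert net.threshold_used == pytest.approx(0.4)
        assert net.n_edges == 2
        assert net.adjacency[0, 1] == 1 and net.adjacency[0, 2] == 1
        assert net.adjacency[1, 2] == 0

    def test_explicit_threshold_isolating_node_warns(self):
        v = np.eye(3)
        v[0, 1] = v[1, 0] = 0.9
        v[0, 2] = v[2, 0] = 0.4
        v[1, 2] = v[2, 1] = 0.3
        with pytest.warns(UserWarning, match="isolates"):
            net = binarize(make_matrix(v, labels=["A", "B", "C"]), 0.8)
        assert net.isolated_nodes == ("C",)

    @pytest.mark.parametrize("seed", range(10))
    def test_auto_threshold_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        v = rng.random((n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        m = make_matrix(v)
        assert auto_threshold(m) == pytest.approx(exhaustive_auto_threshold(v))
        net = binarize(m, "auto")
        assert (net.degrees() > 0).all()

    def test_lowering_threshold_never_decreases_degree_or_efficiency(self):
        rng = np.random.default_rng(33)
        v = rng.random((8, 8))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        m = make_matrix(v)
        prev_deg, prev_eg = -1.0, -1.0
        for thr in (0.8, 0.6, 0.4, 0.2):
            with np.errstate(all="ignore"):
                import warnings

                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    net = binarize(m, thr)
            if net.n_edges == 0:
                continue
            _, deg = degree(net)
            eg = global_efficiency(net)
            assert deg >= prev_deg and eg >= prev_eg
            prev_deg, prev_eg = deg, eg


class TestDistancesAndMetricsOracles:
    @pytest.mark.parametrize("seed", range(30))
    def test_all_metrics_match_brute_force(self, seed):
        rng = np.random.default_rng(100 + seed)
        n = int(rng.integers(5, 13))
        net = random_binary_network(rng, n, p=float(rng.uniform(0.2, 0.7)))
        adj = net.adjacency
        d_oracle = floyd_warshall(adj)
        np.testing.assert_array_equal(shortest_paths(net), d_oracle)
        off = ~np.eye(n, dtype=bool)
        finite = np.isfinite(d_oracle) & off
        lp, n_unreach = optimal_path_length(net)
        assert lp == pytest.approx(d_oracle[finite].mean())
        assert n_unreach == int((~np.isfinite(d_oracle) & off).sum())
        inv = np.where(finite, 1.0 / np.where(finite, d_oracle, 1), 0.0)
        assert global_efficiency(net) == pytest.approx(inv[off].mean())
        np.testing.assert_allclose(clustering(net)[0], brute_clustering(adj))
        np.testing.assert_allclose(
            local_efficiency(net)[0], brute_local_efficiency(adj)
        )
        deg_a, deg_mean = degree(net)
        np.testing.assert_array_equal(deg_a, adj.sum(axis=0))
        assert deg_a.sum() == 2 * net.n_edges  # handshake lemma

    def test_path_graph_hand_values(self):
        net = path_graph(3)
        lp, n_unreach = optimal_path_length(net)
        assert lp == pytest.approx(4 / 3)
        assert n_unreach == 0
        assert global_efficiency(net) == pytest.approx(5 / 6)
        _, deg_mean = degree(net)
        assert deg_mean == pytest.approx(4 / 3)
        assert clustering(net)[1] == 0.0

    def test_complete_graph_closed_form(self):
        for n in (5, 19):
            net = complete_graph(n)
            lp, _ = optimal_path_length(net)
            assert lp == 1.0
            assert global_efficiency(net) == 1.0
            assert clustering(net)[1] == 1.0
            assert local_efficiency(net)[1] == 1.0
            assert degree(net)[1] == n - 1

    def test_triangle_and_star(self):
        tri = complete_graph(3)
        assert clustering(tri)[1] == 1.0
        assert local_efficiency(tri)[1] == 1.0
        star = BinaryNetwork(
            np.array([[0, 1, 1, 1], [1, 0, 0, 0], [1, 0, 0, 0], [1, 0, 0, 0]]),
            ["hub", "a", "b", "c"], 0.5,
        )
        assert clustering(star)[1] == 0.0

    def test_disconnected_two_dyads(self):
        adj = np.zeros((4, 4), int)
        adj[0, 1] = adj[1, 0] = 1
        adj[2, 3] = adj[3, 2] = 1
        net = BinaryNetwork(adj, list("abcd"), 0.5)
        lp, n_unreach = optimal_path_length(net)
        assert lp == 1.0
        assert n_unreach == 8
        assert global_efficiency(net) == pytest.approx(1 / 3)

    def test_edgeless_network_fails(self):
        net = BinaryNetwork(np.zeros((3, 3), int), list("abc"), 0.9)
        with pytest.raises(ValueError, match="edgeless"):
            optimal_path_length(net)


class TestSmallWorld:
    def test_rewiring_preserves_degree_sequence_exactly(self):
        rng = np.random.default_rng(50)
        for _ in range(10):
            net = random_binary_network(rng, 12, p=0.3)
            null = rewire_degree_preserving(net, rng)
            np.testing.assert_array_equal(null.degrees(), net.degrees())

    def test_complete_graph_sigma_is_one(self):
        gamma, lam, sigma = small_world(complete_graph(19), n_random=5, seed=1)
        assert gamma == lam == sigma == 1.0

    def test_ring_lattice_with_shortcuts_is_small_world(self):
        import networkx as nx

        hits = 0
        for seed in range(10):
            g = nx.connected_watts_strogatz_graph(19, 4, 0.1, seed=seed)
            net = BinaryNetwork(nx.to_numpy_array(g).astype(int),
                                [f"n{i}" for i in range(19)], 0.5)
            _, _, sigma = small_world(net, n_random=20, seed=seed)
            hits += sigma > 1
        assert hits >= 9

    def test_dense_random_graph_sigma_near_one(self):
        import networkx as nx

        sigmas = []
        for seed in range(5):
            g = nx.erdos_renyi_graph(19, 0.5, seed=seed)
            net = BinaryNetwork(nx.to_numpy_array(g).astype(int),
                                [f"n{i}" for i in range(19)], 0.5)
            sigmas.append(small_world(net, n_random=20, seed=seed)[2])
        assert 0.8 < np.mean(sigmas) < 1.2

    def test_metrics_suite_deterministic_given_seed(self):
        rng = np.random.default_rng(60)
        v = rng.random((10, 10))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 1.0)
        m = make_matrix(v)
        a = metrics_suite(m, "auto", n_random=10, seed=3)
        b = metrics_suite(m, "auto", n_random=10, seed=3)
        assert a.as_dict() == b.as_dict()
        c = metrics_suite(m, "auto", n_random=10, seed=4)
        # deterministic panel identical; only the null normalization moves
        for key in ("Lp", "Eg", "CC", "Eloc", "Deg"):
            assert a.as_dict()[key] == c.as_dict()[key]

    def test_k19_metrics_panel(self):
        v = np.ones((19, 19))
        m = make_matrix(v)
        res = metrics_suite(m, "auto", n_random=3, seed=0)
        assert (res.Lp, res.Eg, res.CC, res.Eloc, res.Deg) == (1, 1, 1, 1, 18)
        assert res.sigma == 1.0
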