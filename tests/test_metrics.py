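"""Graph-metric tests: thresholding arithmetic, hand-computable fixtures, and
agreement with the brute-force oracles on random graphs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from numpy.testing import assert_allclose

import networkx as nx

from nirsnet import (
    PipelineConfig,
    ThresholdedNetwork,
    clustering_coefficient,
    global_efficiency,
    local_efficiency,
    metric_auc,
    nodal_betweenness,
    nodal_efficiency,
    shortest_paths,
    threshold_network,
)
from nirsnet.metrics import edge_count
from oracles import (
    betweenness_brute,
    clustering_brute_binary,
    clustering_brute_weighted,
    floyd_warshall,
    global_efficiency_brute,
    lengths_of,
    local_efficiency_brute,
    nodal_efficiency_brute,
    random_graph,
)


def net_of(adj, mode="binary", sparsity=0.3):
    return ThresholdedNetwork(adjacency=np.asarray(adj, float),
                              sparsity=sparsity, mode=mode)


def path3(mode="binary"):
    A = np.zeros((3, 3))
    A[0, 1] = A[1, 0] = A[1, 2] = A[2, 1] = 1.0
    return net_of(A, mode)


def complete(n):
    A = np.ones((n, n)) - np.eye(n)
    return net_of(A)


def star(n):
    A = np.zeros((n, n))
    A[0, 1:] = A[1:, 0] = 1.0
    return net_of(A)


class TestThresholding:
    def test_edge_count_46_channels_sparsity_017(self, rng):
        r = rng.uniform(0.01, 0.99, (46, 46))
        r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = threshold_network(r, 0.17)
        assert net.n_edges == 176  # round(0.17 * 1035)

    def test_sparsity_grid_yields_34_networks(self, config):
        grid = config.sparsity_grid()
        assert len(grid) == 34
        assert grid[0] == pytest.approx(0.17)
        assert grid[-1] == pytest.approx(0.50)

    def test_total_ties_resolved_deterministically(self):
        n = 10
        fc = np.full((n, n), 0.5)
        np.fill_diagonal(fc, 1.0)
        nets = [threshold_network(fc, 0.3) for _ in range(3)]
        for net in nets[1:]:
            assert np.array_equal(net.adjacency, nets[0].adjacency)
        assert nets[0].n_edges == edge_count(0.3, n)
        # lexicographic tie-break: the first edges in (i, j) order are kept
        iu, ju = np.triu_indices(n, 1)
        kept = nets[0].adjacency[iu, ju]
        assert np.all(kept[: nets[0].n_edges] == 1)

    def test_weighted_mode_keeps_r_values(self, rng):
        r = rng.uniform(0.1, 0.9, (8, 8)); r = (r + r.T) / 2
        np.fill_diagonal(r, 1.0)
        net = threshold_network(r, 0.3, mode="weighted")
        iu, ju = np.triu_indices(8, 1)
        kept = net.adjacency[iu, ju]
        assert np.all(kept[kept > 0] > 0)
        sel = kept > 0
        assert_allclose(kept[sel], r[iu, ju][sel])
        # kept edges are the strongest ones
        assert kept[sel].min() >= np.sort(r[iu, ju])[::-1][net.n_edges - 1]

    def test_insufficient_positive_entries_fails_with_counts(self):
        fc = -0.5 * np.ones((8, 8))
        np.fill_diagonal(fc, 1.0)
        fc[0, 1] = fc[1, 0] = 0.9
        with pytest.raises(ValueError, match="positive"):
            threshold_network(fc, 0.4)

    def test_rounding_modes(self):
        assert edge_count(0.17, 46, "round") == 176
        assert edge_count(0.17, 46, "floor") == 175


class TestHandComputableFixtures:
    def test_path_graph_distances(self):
        D, sigma = shortest_paths(path3())
        assert D[0, 2] == 2.0
        assert sigma[0, 2] == 1.0

    def test_isolated_node_infinite_distances(self):
        A = np.zeros((4, 4)); A[0, 1] = A[1, 0] = 1.0
        D, _ = shortest_paths(net_of(A))
        assert np.isinf(D[2, [0, 1, 3]]).all()

    def test_complete_graph_efficiencies(self):
        net = complete(4)
        assert_allclose(nodal_efficiency(net), 1.0)
        assert global_efficiency(net) == pytest.approx(1.0)

    def test_path_graph_nodal_efficiency(self):
        assert_allclose(nodal_efficiency(path3()), [0.75, 1.0, 0.75])

    def test_path_graph_betweenness(self):
        assert_allclose(nodal_betweenness(path3()), [0.0, 0.5, 0.0])

    def test_star_center_betweenness(self):
        # unordered-pair convention: (n-1)(n-2)/2 pairs over (n-1)(n-2)
        b = nodal_betweenness(star(8))
        assert b[0] == pytest.approx(0.5)
        assert_allclose(b[1:], 0.0)

    def test_triangle_clustering_and_local_efficiency(self):
        tri = complete(3)
        C, Ci = clustering_coefficient(tri)
        assert C == pytest.approx(1.0)
        assert local_efficiency(tri) == pytest.approx(1.0)

    def test_path_clustering_zero(self):
        C, _ = clustering_coefficient(path3())
        assert C == 0.0

    def test_star_local_efficiency_zero(self):
        assert local_efficiency(star(6)) == 0.0

    def test_disconnected_efficiency_zero(self):
        net = net_of(np.zeros((5, 5)))
        assert global_efficiency(net) == 0.0

    def test_global_equals_mean_nodal_exactly(self, rng):
        A = random_graph(rng, 12, "binary")
        net = net_of(A)
        assert global_efficiency(net) == float(np.mean(nodal_efficiency(net)))


class TestOracleAgreement:
    """Random small graphs against the independent brute-force oracles."""

    @pytest.mark.parametrize("mode,seed", [("binary", 0), ("binary", 1),
                                           ("weighted", 2), ("weighted", 3)])
    def test_all_metrics_match_bruteforce(self, mode, seed):
        rng = np.random.default_rng(seed)
        tol = 1e-12 if mode == "binary" else 1e-9
        for _ in range(10):
            n = int(rng.integers(5, 13))
            A = random_graph(rng, n, mode)
            net = net_of(A, mode)
            L = lengths_of(A, mode)
            D, _ = shortest_paths(net)
            assert_allclose(D, floyd_warshall(L), atol=tol)
            assert_allclose(nodal_efficiency(net), nodal_efficiency_brute(L), atol=tol)
            assert_allclose(global_efficiency(net), global_efficiency_brute(L), atol=tol)
            assert_allclose(nodal_betweenness(net), betweenness_brute(L), atol=tol)
            got_C, got_Ci = clustering_coefficient(net)
            exp_C, exp_Ci = (clustering_brute_binary(A) if mode == "binary"
                             else clustering_brute_weighted(A))
            assert_allclose(got_Ci, exp_Ci, atol=tol)
            assert got_C == pytest.approx(exp_C, abs=tol)
            assert local_efficiency(net) == pytest.approx(
                local_efficiency_brute(L, A), abs=tol)

    def test_betweenness_total_mass_matches_oracle(self, rng):
        for _ in range(5):
            A = random_graph(rng, 9, "binary")
            got = nodal_betweenness(net_of(A))
            exp = betweenness_brute(lengths_of(A, "binary"))
            assert got.sum() == pytest.approx(exp.sum(), abs=1e-12)

    def test_weighted_betweenness_matches_networkx(self, rng):
        # independent cross-check through a different algorithm (Brandes)
        for seed in range(3):
            r = np.random.default_rng(seed)
            A = random_graph(r, 12, "weighted")
            net = net_of(A, "weighted")
            G = nx.from_numpy_array(lengths_of(A, "weighted"))
            bx = nx.betweenness_centrality(G, weight="weight", normalized=True)
            expected = np.array([bx[i] for i in range(12)]) / 2.0  # unordered pairs
            assert_allclose(nodal_betweenness(net), expected, atol=1e-9)


class TestMetricAUC:
    def test_constant_curve(self, config):
        grid = config.sparsity_grid()
        assert metric_auc(np.full(34, 2.0), grid) == pytest.approx(0.33 * 2.0)

    def test_linear_curve(self, config):
        grid = config.sparsity_grid()
        curve = np.linspace(0.0, 1.0, 34)
        assert metric_auc(curve, grid) == pytest.approx(0.33 * 0.5)

    def test_matches_composite_trapezoid_oracle(self, rng, config):
        grid = config.sparsity_grid()
        curve = rng.standard_normal(34)
        manual = sum((curve[k] + curve[k + 1]) / 2 * (grid[k + 1] - grid[k])
                     for k in range(33))
        assert metric_auc(curve, grid) == pytest.approx(manual, abs=1e-14)

    def test_length_mismatch_rejected(self, config):
        with pytest.raises(ValueError, match="mismatch"):
            metric_auc(np.zeros(10), config.sparsity_grid())


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_efficiency_monotone_under_edge_addition(seed):
    """Adding any edge never decreases global or nodal efficiency."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(4, 10))
    A = random_graph(rng, n, "binary", p=0.3)
    absent = [(i, j) for i in range(n) for j in range(i + 1, n) if A[i, j] == 0]
    if not absent:
        return
    i, j = absent[int(rng.integers(len(absent)))]
    before = nodal_efficiency(net_of(A))
    A2 = A.copy(); A2[i, j] = A2[j, i] = 1.0
    after = nodal_efficiency(net_of(A2))
    assert np.all(after >= before - 1e-12)
    assert after.mean() >= before.mean() - 1e-12


def test_metric_pipeline_is_deterministic(rng):
    from nirsnet.metrics import network_profile
    from nirsnet.connectivity import ConnectivityMatrix

    r = rng.uniform(0.05, 0.95, (20, 20)); r = (r + r.T) / 2
    np.fill_diagonal(r, 1.0)
    fc = ConnectivityMatrix(values=r, method="pearson", duration_s=60.0,
                            subject_id="S01", run_id="1")
    grid = PipelineConfig().sparsity_grid()
    p1 = network_profile(fc, grid, "binary")
    p2 = network_profile(fc, grid, "binary")
    for key in p1:
        assert np.array_equal(np.asarray(p1[key]), np.asarray(p2[key]))
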