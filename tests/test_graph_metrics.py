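import numpy as np
import pytest

from _oracles import (
    oracle_clustering,
    oracle_global_efficiency,
    oracle_local_efficiency,
    oracle_path_length,
)
from fcgraph.graph_metrics import (
    MetricCurve,
    auc_over_sparsity,
    characteristic_path_length,
    clustering_coefficient,
    compute_metric_curves,
    degree_preserving_rewire,
    global_efficiency,
    local_efficiency,
    small_world_normalize,
)
from fcgraph.network_construction import SparsityGrid, pearson_matrix, \
    sparsity_binarize
from fcgraph.signal_cleaning import RoiTimeSeries
from fcgraph.synthetic_cohort import benchmark_graph
from conftest import random_simple_graph


class TestClustering:
    def test_complete_graph(self):
        assert clustering_coefficient(benchmark_graph("complete", 4)) == 1.0

    def test_star_graph(self):
        assert clustering_coefficient(benchmark_graph("star", 6)) == 0.0

    def test_triangle_with_pendant(self, triangle_pendant):
        expected = (1 / 3 + 1 + 1 + 0) / 4
        assert clustering_coefficient(triangle_pendant) == pytest.approx(
            expected, abs=1e-12
        )


class TestPathLength:
    def test_complete_graph(self):
        assert characteristic_path_length(
            benchmark_graph("complete", 4)) == 1.0

    def test_path_graph(self):
        # P4 ordered pairs: six at d=1, four at d=2, two at d=3
        expected = 12 / (6 + 4 / 2 + 2 / 3)
        assert characteristic_path_length(
            benchmark_graph("path", 4)) == pytest.approx(expected, abs=1e-12)

    def test_disconnected_pairs_harmonic_convention(self):
        adj = np.zeros((4, 4), np.uint8)
        adj[:3, :3] = benchmark_graph("complete", 3)
        np.fill_diagonal(adj, 0)
        assert characteristic_path_length(adj) == pytest.approx(2.0)

    def test_edgeless_graph_rejected(self):
        with pytest.raises(ValueError, match="density too low"):
            characteristic_path_length(np.zeros((5, 5), np.uint8))


class TestEfficiency:
    def test_global_complete(self):
        assert global_efficiency(benchmark_graph("complete", 4)) == 1.0

    def test_global_path_graph(self):
        expected = (6 + 4 / 2 + 2 / 3) / 12
        assert global_efficiency(benchmark_graph("path", 4)) == pytest.approx(
            expected, abs=1e-12
        )

    def test_global_edgeless(self):
        assert global_efficiency(np.zeros((4, 4), np.uint8)) == 0.0

    def test_local_complete(self):
        assert local_efficiency(benchmark_graph("complete", 4)) == 1.0

    def test_local_star(self):
        assert local_efficiency(benchmark_graph("star", 6)) == 0.0

    def test_local_triangle_with_pendant(self, triangle_pendant):
        expected = (1 / 3 + 1 + 1 + 0) / 4
        assert local_efficiency(triangle_pendant) == pytest.approx(
            expected, abs=1e-12
        )

    def test_adding_edge_never_decreases_global_efficiency(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            adj = random_simple_graph(rng, n_max=10)
            zero = np.argwhere(np.triu(adj == 0, k=1))
            if not zero.size:
                continue
            i, j = zero[rng.integers(len(zero))]
            before = global_efficiency(adj)
            adj2 = adj.copy()
            adj2[i, j] = adj2[j, i] = 1
            assert global_efficiency(adj2) >= before - 1e-12


class TestOracleAgreement:
    def test_metrics_match_brute_force_on_random_graphs(self):
        rng = np.random.default_rng(123)
        checked = 0
        while checked < 100:
            adj = random_simple_graph(rng, n_max=8)
            assert clustering_coefficient(adj) == pytest.approx(
                oracle_clustering(adj), abs=1e-10
            )
            assert global_efficiency(adj) == pytest.approx(
                oracle_global_efficiency(adj), abs=1e-10
            )
            assert local_efficiency(adj) == pytest.approx(
                oracle_local_efficiency(adj), abs=1e-10
            )
            if adj.sum() > 0:
                assert characteristic_path_length(adj) == pytest.approx(
                    oracle_path_length(adj), abs=1e-10
                )
            checked += 1


class TestRewiring:
    def test_complete_graph_unchanged_with_flag(self):
        k4 = benchmark_graph("complete", 4)
        res = degree_preserving_rewire(k4, seed=0)
        assert res.unchanged
        assert np.array_equal(res.adjacency, k4)

    def test_degree_sequence_preserved_exactly(self):
        rng = np.random.default_rng(11)
        for seed in range(10):
            adj = random_simple_graph(rng, n_max=12)
            if adj.sum() < 4:
                continue
            res = degree_preserving_rewire(adj, seed=seed)
            assert np.array_equal(
                res.adjacency.sum(axis=0), adj.sum(axis=0)
            )
            assert np.all(np.diag(res.adjacency) == 0)
            assert np.array_equal(res.adjacency, res.adjacency.T)

    def test_deterministic_given_seed(self):
        adj = benchmark_graph("erdos_renyi", 30, 0.3, seed=4)
        a = degree_preserving_rewire(adj, seed=99).adjacency
        b = degree_preserving_rewire(adj, seed=99).adjacency
        assert np.array_equal(a, b)

    def test_er_graphs_actually_rewired(self):
        adj = benchmark_graph("erdos_renyi", 20, 0.3, seed=0)
        moved = 0
        for seed in range(100):
            null = degree_preserving_rewire(adj, seed=seed).adjacency
            inter = np.triu(adj & null, 1).sum()
            union = np.triu(adj | null, 1).sum()
            if inter / union < 1.0:
                moved += 1
        assert moved >= 99


class TestSmallWorldNormalization:
    def test_self_null_degenerate_case(self):
        adj = benchmark_graph("erdos_renyi", 20, 0.3, seed=1)
        sw = small_world_normalize(adj, n_null=1, seed=0, n_swap_factor=0)
        assert sw.gamma == pytest.approx(1.0, abs=1e-12)
        assert sw.lam == pytest.approx(1.0, abs=1e-12)
        assert sw.sigma == pytest.approx(1.0, abs=1e-12)

    def test_sigma_is_gamma_over_lambda(self):
        adj = benchmark_graph("watts_strogatz", 60, (6, 0.1), seed=2)
        sw = small_world_normalize(adj, n_null=10, seed=3)
        assert sw.sigma == pytest.approx(sw.gamma / sw.lam, abs=1e-12)

    def test_watts_strogatz_is_small_world(self):
        adj = benchmark_graph("watts_strogatz", 160, (10, 0.1), seed=5)
        sw = small_world_normalize(adj, n_null=20, seed=6)
        assert sw.sigma > 1

    def test_lattice_vs_er_watts_strogatz_ordering(self):
        lattice = benchmark_graph("ring_lattice", 160, 10)
        m = int(lattice.sum()) // 2
        er = benchmark_graph("erdos_renyi", 160, m / (160 * 159 / 2), seed=7)
        assert clustering_coefficient(lattice) > clustering_coefficient(er)
        assert characteristic_path_length(lattice) > \
            characteristic_path_length(er)


class TestAuc:
    def test_constant_curve(self):
        curve = MetricCurve.from_points(
            "m", np.linspace(0.05, 0.40, 18), np.full(18, 2.0)
        )
        assert curve.auc == pytest.approx(0.70, abs=1e-12)

    def test_linear_curve_exact(self):
        s = np.linspace(0.05, 0.40, 18)
        curve = MetricCurve.from_points("m", s, s)
        assert curve.auc == pytest.approx((0.40**2 - 0.05**2) / 2, abs=1e-12)

    def test_reversed_grid_rejected(self):
        curve = MetricCurve("m", np.array([0.4, 0.05]), np.array([1.0, 1.0]),
                            np.nan)
        with pytest.raises(ValueError, match="increasing"):
            auc_over_sparsity(curve)

    def test_single_point_rejected(self):
        curve = MetricCurve("m", np.array([0.1]), np.array([1.0]), np.nan)
        with pytest.raises(ValueError, match="2 grid points"):
            auc_over_sparsity(curve)


@pytest.fixture(scope="module")
def stack():
    rng = np.random.default_rng(8)
    block = np.kron(np.eye(2), np.full((10, 10), 0.5))
    np.fill_diagonal(block, 1.0)
    chol = np.linalg.cholesky(block + 1e-6 * np.eye(20))
    vals = rng.standard_normal((80, 20)) @ chol.T
    cm = pearson_matrix(RoiTimeSeries(vals, tr=2.0))
    return sparsity_binarize(cm, SparsityGrid(np.linspace(0.2, 0.4, 4)))


class TestMetricCurves:
    def test_normalized_curves_present_and_deterministic(self, stack):
        c1 = compute_metric_curves(stack, n_null=5, seed=3)
        c2 = compute_metric_curves(stack, n_null=5, seed=3)
        assert set(c1) == {"Cp", "Lp", "Eglob", "Eloc",
                           "gamma", "lambda", "sigma"}
        for name in c1:
            assert np.array_equal(c1[name].values, c2[name].values)
            assert np.all(np.isfinite(c1[name].values))

    def test_n_null_zero_skips_normalization(self, stack, caplog):
        with caplog.at_level("WARNING", logger="fcgraph"):
            curves = compute_metric_curves(stack, n_null=0, seed=3)
        assert set(curves) == {"Cp", "Lp", "Eglob", "Eloc"}
        assert "skipped" in caplog.text
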