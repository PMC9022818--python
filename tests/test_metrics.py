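import numpy as np
import pytest

from fcdyn import (
    BinarizationSpec,
    BinaryNetwork,
    all_pairs_shortest_paths,
    assortativity,
    betweenness,
    binarize,
    characteristic_path_length,
    clustering,
    global_efficiency,
    global_metrics,
    metrics_over_series,
    modularity,
    network_local_efficiency,
    nodal_metrics,
    normalized_metrics,
    partition_modularity,
    random_ensemble,
    transitivity,
)
from fcdyn.metrics import UndefinedMetricError, random_graph
from conftest import graph
import oracles


def corr3(ab, ac, bc):
    m = np.array([[1.0, ab, ac], [ab, 1.0, bc], [ac, bc, 1.0]])
    return m


class TestBinarize:
    spec_abs = BinarizationSpec(method="absolute", thresholds=(0.5,), sweep=False)

    def test_absolute_threshold_keeps_strictly_larger(self):
        g = binarize(corr3(0.6, 0.2, -0.7), self.spec_abs, 0.5)
        assert g.m == 1 and g.adjacency[0, 1] == 1

    def test_absolute_with_abs_values(self):
        spec = BinarizationSpec(method="absolute", thresholds=(0.5,), sweep=False, use_abs=True)
        g = binarize(corr3(0.6, 0.2, -0.7), spec, 0.5)
        assert g.m == 2
        assert g.adjacency[0, 1] == 1 and g.adjacency[1, 2] == 1

    def test_cost_keeps_top_fraction(self):
        spec = BinarizationSpec(method="cost", thresholds=(1 / 3,), sweep=False)
        g = binarize(corr3(0.6, 0.2, -0.7), spec, 1 / 3)
        assert g.m == 1 and g.adjacency[0, 1] == 1

    def test_proportional_relative_to_max(self):
        spec = BinarizationSpec(method="proportional", thresholds=(0.5,), sweep=False)
        # max off-diagonal 0.8 -> cutoff 0.4: keeps 0.8 and 0.5
        fc = corr3(0.8, 0.5, 0.3)
        g = binarize(fc, spec, 0.5)
        assert g.m == 2

    def test_nan_edges_never_kept(self):
        fc = corr3(0.9, 0.9, 0.9)
        fc[0, 1] = fc[1, 0] = np.nan
        g = binarize(fc, self.spec_abs, 0.5)
        assert g.adjacency[0, 1] == 0 and g.m == 2

    def test_cost_over_request_capped(self):
        fc = corr3(0.9, np.nan, np.nan)
        spec = BinarizationSpec(method="cost", thresholds=(1.0,), sweep=False)
        g = binarize(fc, spec, 1.0)
        assert g.m == 1

    def test_density_monotone_in_absolute_threshold(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(-1, 1, (8, 8))
        fc = (a + a.T) / 2
        np.fill_diagonal(fc, 1.0)
        degrees = [
            binarize(fc, self.spec_abs, t).degrees().mean()
            for t in np.linspace(-0.9, 0.9, 10)
        ]
        assert all(d1 >= d2 for d1, d2 in zip(degrees, degrees[1:]))

    def test_threshold_sweep_values(self):
        spec = BinarizationSpec(thresholds=(0.5, 0.85, 0.01))
        vals = spec.threshold_values()
        assert vals.size == 36
        assert vals[0] == pytest.approx(0.5) and vals[-1] == pytest.approx(0.85)


class TestClosedFormFixtures:
    def test_complete_graph_k4(self, k4):
        assert global_efficiency(k4) == 1.0
        assert network_local_efficiency(k4) == 1.0
        assert clustering(k4)[1] == 1.0
        assert characteristic_path_length(k4) == 1.0
        assert transitivity(k4) == 1.0
        assert modularity(k4)[0] == pytest.approx(0.0, abs=1e-12)

    def test_star_graph(self, star4):
        assert global_efficiency(star4) == pytest.approx(0.75)
        assert characteristic_path_length(star4) == pytest.approx(1.5)
        assert network_local_efficiency(star4) == 0.0
        assert clustering(star4)[1] == 0.0
        assert transitivity(star4) == 0.0
        assert assortativity(star4) == pytest.approx(-1.0)
        nm = nodal_metrics(star4)
        assert nm.betweenness[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm.betweenness[1:], 0.0)
        assert nm.E_nodal[0] == pytest.approx(1.0)
        np.testing.assert_allclose(nm.E_nodal[1:], 2 / 3)

    def test_path_graph_distances_and_efficiency(self):
        p3 = graph([(0, 1), (1, 2)], 3)
        d = all_pairs_shortest_paths(p3)
        assert d[0, 2] == 2
        assert global_efficiency(p3) == pytest.approx(5 / 6)

    def test_triangle(self, triangle):
        c, c_net = clustering(triangle)
        np.testing.assert_allclose(c, 1.0)
        assert c_net == 1.0
        assert network_local_efficiency(triangle) == 1.0
        np.testing.assert_allclose(nodal_metrics(triangle).betweenness, 0.0)

    def test_two_disjoint_edges_reachable_only_path_length(self):
        g = graph([(0, 1), (2, 3)], 4)
        assert characteristic_path_length(g) == 1.0

    def test_triangle_plus_pendant_transitivity(self):
        g = graph([(0, 1), (1, 2), (0, 2), (2, 3)], 4)
        assert transitivity(g) == pytest.approx(0.6)

    def test_two_disjoint_triangles_modularity(self, two_triangles):
        q, part = modularity(two_triangles)
        assert q == pytest.approx(0.5)
        assert sorted(sorted(c) for c in part) == [[0, 1, 2], [3, 4, 5]]

    def test_cycle_assortativity_is_nan(self):
        g = graph([(0, 1), (1, 2), (2, 3), (3, 0)], 4)
        assert np.isnan(assortativity(g))

    def test_no_reachable_pair_raises(self):
        g = BinaryNetwork(adjacency=np.zeros((3, 3), dtype=int))
        with pytest.raises(UndefinedMetricError):
            characteristic_path_length(g)


class TestOracleEquivalence:
    """Spot checks against naive oracles on moderate random graphs."""

    def test_distances_match_floyd_warshall(self):
        rng = np.random.default_rng(1)
        adj = oracles.random_adjacency(50, rng, p=0.08)
        g = BinaryNetwork(adjacency=adj)
        np.testing.assert_array_equal(
            all_pairs_shortest_paths(g), oracles.floyd_warshall(adj)
        )

    def test_clustering_matches_triple_scan(self):
        rng = np.random.default_rng(2)
        adj = oracles.random_adjacency(30, rng, p=0.2)
        g = BinaryNetwork(adjacency=adj)
        np.testing.assert_allclose(
            clustering(g)[0], oracles.clustering_brute(adj), atol=1e-12
        )

    def test_transitivity_matches_triple_scan(self):
        rng = np.random.default_rng(3)
        adj = oracles.random_adjacency(30, rng, p=0.2)
        assert transitivity(BinaryNetwork(adjacency=adj)) == pytest.approx(
            oracles.transitivity_brute(adj), abs=1e-12
        )

    def test_assortativity_matches_direct_correlation(self):
        rng = np.random.default_rng(4)
        adj = oracles.random_adjacency(40, rng, p=0.15)
        assert assortativity(BinaryNetwork(adjacency=adj)) == pytest.approx(
            oracles.assortativity_brute(adj), abs=1e-12
        )

    def test_betweenness_matches_path_enumeration(self):
        rng = np.random.default_rng(5)
        adj = oracles.random_adjacency(25, rng, p=0.15)
        np.testing.assert_allclose(
            betweenness(BinaryNetwork(adjacency=adj)),
            oracles.betweenness_brute(adj),
            atol=1e-12,
        )

    def test_betweenness_matches_networkx(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(6)
        for _ in range(5):
            adj = oracles.random_adjacency(20, rng, p=0.2)
            G = nx.from_numpy_array(adj)
            expected = np.array(
                [nx.betweenness_centrality(G, normalized=True)[i] for i in range(20)]
            )
            np.testing.assert_allclose(
                betweenness(BinaryNetwork(adjacency=adj)), expected, atol=1e-12
            )

    def test_mean_nodal_clustering_equals_network_clustering(self):
        rng = np.random.default_rng(7)
        adj = oracles.random_adjacency(20, rng, p=0.3)
        c, c_net = clustering(BinaryNetwork(adjacency=adj))
        assert c.mean() == pytest.approx(c_net, abs=1e-15)

    def test_greedy_modularity_bounded_by_exact(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            adj = oracles.random_adjacency(7, rng, p=0.4)
            g = BinaryNetwork(adjacency=adj)
            if g.m == 0:
                continue
            q_greedy, _ = modularity(g, method="greedy")
            q_exact, part = modularity(g, method="exact")
            assert q_greedy <= q_exact + 1e-12
            assert q_greedy >= -1e-12  # never worse than one module
            assert q_exact == pytest.approx(
                oracles.modularity_exhaustive(adj), abs=1e-12
            )
            assert partition_modularity(g, part) == pytest.approx(q_exact, abs=1e-12)


class TestRandomEnsemble:
    def test_saturated_graph_forces_complete_members(self, k4):
        ens = random_ensemble(k4, size=5, seed=0)
        assert ens.C_rand == 1.0 and ens.L_rand == 1.0

    def test_seed_determinism(self, star4):
        e1 = random_ensemble(star4, size=10, seed=123)
        e2 = random_ensemble(star4, size=10, seed=123)
        np.testing.assert_array_equal(e1.C_members, e2.C_members)
        np.testing.assert_array_equal(e1.L_members, e2.L_members)

    def test_members_preserve_node_and_edge_counts(self):
        rng = np.random.default_rng(9)
        g = random_graph(12, 20, rng)
        assert g.n == 12 and g.m == 20

    def test_er_clustering_matches_density_expectation(self):
        rng = np.random.default_rng(10)
        n, m = 100, 300
        cs = [clustering(random_graph(n, m, rng))[1] for _ in range(30)]
        density = 2 * m / (n * (n - 1))
        se = np.std(cs, ddof=1) / np.sqrt(len(cs))
        assert abs(np.mean(cs) - density) < 3 * se + 0.01


class TestNormalizedMetrics:
    def test_self_normalization_near_unity(self):
        rng = np.random.default_rng(11)
        g = random_graph(30, 90, rng)
        ens = random_ensemble(g, size=20, seed=7)
        c_norm, l_norm, s = normalized_metrics(g, ens)
        se_c, se_l = ens.standard_errors()
        assert abs(clustering(g)[1] - ens.C_rand) <= 5 * ens.C_members.std(ddof=1)
        assert abs(l_norm - 1) < 0.2 and abs(c_norm - 1) < 1.0
        assert s == pytest.approx(c_norm / l_norm)

    def test_ring_lattice_is_small_world(self):
        n, k = 20, 4
        adj = np.zeros((n, n), dtype=int)
        for i in range(n):
            for d in range(1, k // 2 + 1):
                adj[i, (i + d) % n] = adj[(i + d) % n, i] = 1
        g = BinaryNetwork(adjacency=adj)
        ens = random_ensemble(g, size=20, seed=1)
        c_norm, l_norm, s = normalized_metrics(g, ens)
        assert s > 1.0 and c_norm > l_norm

    def test_zero_clustering_ensemble_raises(self, star4):
        from fcdyn import RandomEnsemble

        ens = RandomEnsemble(
            n=4, m=3, size=3, seed=0,
            C_members=np.zeros(3), L_members=np.ones(3) * 1.5,
        )
        with pytest.raises(UndefinedMetricError):
            normalized_metrics(star4, ens)


class TestMetricsOverSeries:
    def _tiny_fc(self, n_windows=3, R=4, seed=0):
        from fcdyn import ROITimeSeries, WindowSpec, sliding_window_fc

        rng = np.random.default_rng(seed)
        values = rng.standard_normal((12 + n_windows, R))
        ts = ROITimeSeries(values=values, tr=1.0)
        return sliding_window_fc(ts, WindowSpec(window_size=12))

    def test_sweep_evaluates_36_thresholds(self):
        fc = self._tiny_fc(n_windows=2)
        spec = BinarizationSpec(method="absolute", thresholds=(0.5, 0.85, 0.01))
        df, _ = metrics_over_series(fc, spec, which=("avg_degree",))
        assert df["threshold"].nunique() == 36
        assert df.shape[0] == fc.n_windows * 36

    def test_identical_windows_give_flat_trajectories(self):
        from fcdyn import ROITimeSeries, WindowSpec, sliding_window_fc

        rng = np.random.default_rng(12)
        block = rng.standard_normal((6, 4))
        values = np.tile(block, (5, 1))  # period-6 series: all 6-TR windows repeat
        ts = ROITimeSeries(values=values, tr=1.0)
        fc = sliding_window_fc(ts, WindowSpec(window_size=6, step_size=6))
        df, _ = metrics_over_series(
            fc, BinarizationSpec(thresholds=(0.3,), sweep=False), which=("E_glob", "avg_degree")
        )
        assert df.groupby("threshold")["E_glob"].nunique().max() == 1

    def test_rerun_is_deterministic(self):
        fc = self._tiny_fc(n_windows=3, seed=13)
        spec = BinarizationSpec(thresholds=(0.2, 0.4), sweep=False)
        kwargs = dict(which=("E_glob", "C_norm", "S"), ensemble_size=5, seed=99)
        df1, _ = metrics_over_series(fc, spec, **kwargs)
        df2, _ = metrics_over_series(fc, spec, **kwargs)
        assert df1.equals(df2)

    def test_nodal_long_format(self):
        fc = self._tiny_fc(n_windows=2, seed=14)
        spec = BinarizationSpec(thresholds=(0.2,), sweep=False)
        _, nodal = metrics_over_series(fc, spec, nodal=("degree", "betweenness"))

        assert set(nodal.columns) == {"window", "threshold", "node", "metric", "value"}
        assert nodal["metric"].nunique() == 2
        assert nodal.shape[0] == fc.n_windows * 1 * 4 * 2  # windows x thresholds x nodes x metrics


class TestMetricBounds:
    def test_unit_interval_metrics_on_random_graphs(self):
        rng = np.random.default_rng(15)
        for _ in range(25):
            adj = oracles.random_adjacency(rng.integers(3, 10), rng, p=rng.uniform(0.1, 0.9))
            g = BinaryNetwork(adjacency=adj)
            assert 0.0 <= global_efficiency(g) <= 1.0
            assert 0.0 <= clustering(g)[1] <= 1.0
            assert 0.0 <= transitivity(g) <= 1.0
            if g.m >= 1:
                assert characteristic_path_length(g) >= 1.0
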