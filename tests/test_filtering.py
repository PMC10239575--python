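"""Efficiency statistic, threshold optimization and edge filtering."""

import numpy as np
import pytest

from nucgraph import (
    CentroidSet,
    EdgeFeatureTable,
    build_candidate_graph,
    compute_edge_features,
    ecdf_fraction,
    efficiency,
    filter_edges,
    generate_tissue,
    infer_neighbor_graph,
    loss_mean,
    optimize_distance_only,
    optimize_thresholds,
)

from oracles import brute_force_best_thresholds


def outlier_features():
    """Five tight edges plus one long, wide-angle outlier."""
    return EdgeFeatureTable(
        i=[0, 1, 2, 3, 4, 5],
        j=[1, 2, 3, 4, 5, 6],
        r=[1.0] * 5 + [10.0],
        theta=[60.0] * 5 + [170.0],
    )


class TestEfficiencyComponents:
    @pytest.mark.parametrize(
        "query,expected",
        [((2.0, 20.0), 2 / 3), ((3.0, 30.0), 1.0), ((0.5, 5.0), 0.0)],
    )
    def test_ecdf_fraction_counts_qualifying_edges(self, toy_features, query, expected):
        assert ecdf_fraction(toy_features, *query) == pytest.approx(expected)

    def test_loss_zero_at_minima_one_at_maxima(self, toy_features):
        assert loss_mean(1.0, 10.0, toy_features) == 0.0
        assert loss_mean(3.0, 30.0, toy_features) == 1.0
        assert loss_mean(2.0, 20.0, toy_features) == pytest.approx(0.5)

    def test_loss_outside_observed_range_raises(self, toy_features):
        with pytest.raises(ValueError):
            loss_mean(0.5, 20.0, toy_features)
        with pytest.raises(ValueError):
            loss_mean(2.0, 40.0, toy_features)

    def test_efficiency_zero_at_joint_maxima(self, toy_features):
        assert efficiency(3.0, 30.0, toy_features) == pytest.approx(0.0)

    def test_efficiency_midrange_example(self, toy_features):
        # F = 2/3 by count, L = 0.5 at both range midpoints
        assert efficiency(2.0, 20.0, toy_features) == pytest.approx(2 / 3 - 0.5)

    def test_efficiency_at_minima_is_tied_multiplicity(self):
        feats = outlier_features()
        assert efficiency(1.0, 60.0, feats) == pytest.approx(5 / 6)

    def test_empty_table_raises(self):
        empty = EdgeFeatureTable(i=[], j=[], r=[], theta=[])
        with pytest.raises(ValueError):
            ecdf_fraction(empty, 1.0, 1.0)


class TestOptimizeThresholds:
    def test_outlier_edge_is_cut(self):
        feats = outlier_features()
        thr, surface = optimize_thresholds(feats)
        assert (thr.r_star, thr.theta_star) == (1.0, 60.0)
        assert thr.efficiency_at_optimum == pytest.approx(5 / 6)
        assert surface.E.max() == pytest.approx(5 / 6)

    def test_degenerate_identical_features_keep_everything(self):
        feats = EdgeFeatureTable(i=[0, 1, 2], j=[1, 2, 3], r=[1.0] * 3, theta=[60.0] * 3)
        thr, surface = optimize_thresholds(feats)
        assert (thr.r_star, thr.theta_star) == (1.0, 60.0)
        assert thr.efficiency_at_optimum == pytest.approx(1.0)  # L defined 0, F = 1

    def test_optimum_efficiency_never_negative(self, rng):
        # the grid contains (r_max, theta_max) where E is exactly 0
        for _ in range(20):
            m = int(rng.integers(1, 40))
            feats = EdgeFeatureTable(
                i=np.arange(m),
                j=np.arange(m) + 1,
                r=rng.lognormal(0, 0.5, m),
                theta=rng.uniform(1, 179, m),
            )
            thr, surface = optimize_thresholds(feats)
            assert thr.efficiency_at_optimum >= 0
            assert surface.E[-1, -1] == pytest.approx(0.0, abs=1e-12)

    def test_surface_invariants(self, rng):
        m = 60
        feats = EdgeFeatureTable(
            i=np.arange(m),
            j=np.arange(m) + 1,
            r=rng.lognormal(0, 0.4, m),
            theta=rng.uniform(5, 175, m),
        )
        _, s = optimize_thresholds(feats)
        assert np.allclose(s.E, s.F - s.L)
        assert np.all((s.F >= 0) & (s.F <= 1)) and np.all((s.L >= 0) & (s.L <= 1))
        # F and L nondecreasing along both axes
        assert np.all(np.diff(s.F, axis=0) >= 0) and np.all(np.diff(s.F, axis=1) >= 0)
        assert np.all(np.diff(s.L, axis=0) >= 0) and np.all(np.diff(s.L, axis=1) >= 0)

    def test_matches_dense_grid_brute_force(self, rng):
        """Grid argmax dominates a dense 500x500 brute-force evaluation."""
        for _ in range(10):
            m = int(rng.integers(5, 50))
            feats = EdgeFeatureTable(
                i=np.arange(m),
                j=np.arange(m) + 1,
                r=rng.lognormal(0, 0.5, m),
                theta=rng.uniform(1, 179, m),
            )
            thr, _ = optimize_thresholds(feats)
            best_e, _, _ = brute_force_best_thresholds(feats.r, feats.theta)
            assert thr.efficiency_at_optimum >= best_e - 1e-12

    def test_ties_break_toward_stricter_thresholds(self):
        # anti-correlated features: E = 0 at all four grid corners (a 4-way tie)
        feats = EdgeFeatureTable(i=[0, 1], j=[1, 2], r=[1.0, 2.0], theta=[20.0, 10.0])
        thr, surface = optimize_thresholds(feats)
        ties = np.argwhere(surface.E == surface.E.max())
        assert len(ties) >= 2  # a genuine tie exists in this construction
        assert (thr.r_star, thr.theta_star) == (1.0, 10.0)

    def test_scale_invariance_of_thresholds(self, rng):
        tissue = generate_tissue(60, 2, "hexagonal", jitter=0.08, seed=7)
        graph, thr, _ = infer_neighbor_graph(tissue.centroids)
        scaled = tissue.centroids.transformed(scale=3.5)
        graph2, thr2, _ = infer_neighbor_graph(scaled)
        assert thr2.r_star == pytest.approx(3.5 * thr.r_star, rel=1e-9)
        assert thr2.theta_star == pytest.approx(thr.theta_star, abs=1e-9)
        assert graph2.kept_edges == graph.kept_edges


class TestDistanceOnlyBaseline:
    def test_outlier_distance_is_cut(self):
        feats = EdgeFeatureTable(
            i=range(6), j=range(1, 7), r=[1, 1, 1, 1, 1, 10], theta=[50] * 6
        )
        thr = optimize_distance_only(feats)
        assert thr.r_star == 1.0
        assert thr.mode == "distance_only"
        assert thr.theta_star == feats.theta_max  # angle unconstrained

    def test_all_equal_distances_keep_everything(self):
        feats = EdgeFeatureTable(i=range(3), j=range(1, 4), r=[2.0] * 3, theta=[10, 20, 30])
        thr = optimize_distance_only(feats)
        assert thr.r_star == 2.0
        assert thr.efficiency_at_optimum == pytest.approx(1.0)

    def test_joint_mode_is_no_less_strict_at_equal_r_star(self, rng):
        for seed in range(5):
            tissue = generate_tissue(40, 2, "uniform", seed=seed)
            gj, tj, _ = infer_neighbor_graph(tissue.centroids, mode="joint")
            gd, td, _ = infer_neighbor_graph(tissue.centroids, mode="distance_only")
            if tj.r_star == td.r_star:
                assert gj.kept_edges <= gd.kept_edges


class TestFilterEdges:
    def _graph_and_features(self):
        cs = CentroidSet(
            (0, 1, 2, 3), [(0.0, 0.0), (2.0, 0.0), (1.0, 2.0), (1.0, 0.5)]
        )
        g = build_candidate_graph(cs)
        return g, compute_edge_features(g, cs)

    def test_max_thresholds_keep_all(self):
        g, feats = self._graph_and_features()
        thr, _ = optimize_thresholds(feats)
        from nucgraph.filtering import Thresholds

        keep_all = Thresholds(feats.r_max, feats.theta_max, 0.0)
        result = filter_edges(g, feats, keep_all)
        assert result.fraction_removed == 0.0
        assert result.kept_edges == set(g.edges)

    def test_conjunction_of_conditions(self):
        g, feats = self._graph_and_features()
        from nucgraph.filtering import Thresholds

        # r accepts everything, theta excludes the wide-angle edges
        thr = Thresholds(feats.r_max, 90.0, 0.0)
        result = filter_edges(g, feats, thr)
        assert all(
            (t <= 90.0) == k for t, k in zip(result.theta, result.kept)
        )

    def test_fraction_removed_example(self):
        feats = outlier_features()
        from nucgraph.filtering import Thresholds

        g, _ = self._graph_and_features()
        # six feature rows, one above thresholds
        thr = Thresholds(1.0, 60.0, 5 / 6)
        result = filter_edges(g, feats, thr)
        assert int(result.kept.sum()) == 5
        assert result.fraction_removed == pytest.approx(1 / 6)

    def test_monotone_in_thresholds(self, rng):
        tissue = generate_tissue(50, 2, "uniform", seed=3)
        from nucgraph import build_candidate_graph, compute_edge_features
        from nucgraph.filtering import Thresholds

        g = build_candidate_graph(tissue.centroids)
        feats = compute_edge_features(g, tissue.centroids)
        r_grid = np.quantile(feats.r, [0.3, 0.6, 1.0])
        t_grid = np.quantile(feats.theta, [0.3, 0.6, 1.0])
        previous = set()
        for rv, tv in zip(r_grid, t_grid):
            kept = filter_edges(g, feats, Thresholds(rv, tv, 0.0)).kept_edges
            assert previous <= kept
            previous = kept
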