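"""Generator contracts: landscape bounds, point placement, bout statistics,
forward presence model."""

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Point

from routescape.resources import nearest_neighbor_z, network_point_distances
from routescape.synthetic import (SyntheticConfig, generate_dem, generate_gaps,
                                  generate_travel_bouts, generate_trees,
                                  generate_scenario, simulate_route_presence)
from conftest import separated_edges

EXTENT = (0.0, 0.0, 800.0, 625.0)  # 50 ha


class TestDem:
    def test_zero_roughness_is_flat_at_midpoint(self):
        dem = generate_dem(EXTENT, (65.0, 264.0), roughness=0.0, seed=1)
        assert np.allclose(dem.data, (65.0 + 264.0) / 2.0)

    @pytest.mark.parametrize("seed", [0, 1, 99])
    def test_values_within_elevation_range(self, seed):
        dem = generate_dem(EXTENT, (65.0, 264.0), seed=seed)
        assert dem.data.min() >= 65.0 and dem.data.max() <= 264.0

    def test_same_seed_bit_identical(self):
        a = generate_dem(EXTENT, seed=5)
        b = generate_dem(EXTENT, seed=5)
        assert np.array_equal(a.data, b.data)

    def test_degenerate_extent_rejected(self):
        with pytest.raises(ValueError, match="extent"):
            generate_dem((0, 0, 0, 100), seed=0)


class TestGaps:
    def test_zero_fraction_empty(self):
        assert generate_gaps(EXTENT, 0.0, seed=0) == []

    def test_union_area_near_target(self):
        gaps = generate_gaps(EXTENT, 0.07, n_patches=8, seed=3)
        area = shapely.ops.unary_union(gaps).area
        target = 0.07 * 50e4  # 3.5 ha on a 50 ha extent
        assert abs(area - target) / target <= 0.20
        for g in gaps:
            assert g.is_valid and g.is_simple

    def test_polygons_inside_extent(self):
        gaps = generate_gaps(EXTENT, 0.10, seed=4)
        box = shapely.box(*EXTENT).buffer(1e-6)
        assert all(box.contains(g) for g in gaps)

    def test_infeasible_patch_count(self):
        with pytest.raises(ValueError):
            generate_gaps(EXTENT, 0.05, n_patches=0, seed=0)


class TestTrees:
    def test_csr_count_containment_and_no_clustering(self, disc_hr):
        gaps = [Point(300, 300).buffer(30.0)]
        trees = generate_trees(disc_hr, gaps, 137, mode="CSR", seed=2)
        assert len(trees) == 137
        region = disc_hr.difference(gaps[0])
        assert shapely.contains_xy(region.buffer(1e-9),
                                   trees.x.to_numpy(), trees.y.to_numpy()).all()
        z = nearest_neighbor_z(trees[["x", "y"]].to_numpy(), region.area)
        assert z > -1.96  # not significantly clustered

    def test_route_biased_limit_lies_on_graph(self, disc_hr):
        edges = separated_edges(0)
        shifted = [type(e)(e.xy + 150.0, e.multiplicity) for e in edges]
        trees = generate_trees(disc_hr, None, 50, mode="route_biased",
                               bias_lambda=1e6, route_graph=shifted, seed=3)
        d = network_point_distances(trees[["x", "y"]].to_numpy(),
                                    [e.xy for e in shifted])
        assert d.max() < 1.0

    def test_route_biased_closer_than_csr(self, disc_hr):
        edges = [type(e)(e.xy + 150.0, e.multiplicity)
                 for e in separated_edges(1)]
        csr_d, biased_d = [], []
        for seed in range(20):
            c = generate_trees(disc_hr, None, 60, mode="CSR", seed=seed)
            b = generate_trees(disc_hr, None, 60, mode="route_biased",
                               bias_lambda=0.05, route_graph=edges, seed=seed)
            geo = [e.xy for e in edges]
            csr_d.append(network_point_distances(c[["x", "y"]].to_numpy(), geo).mean())
            biased_d.append(network_point_distances(b[["x", "y"]].to_numpy(), geo).mean())
        assert np.mean(biased_d) < np.mean(csr_d)

    def test_empty_region_rejected(self, disc_hr):
        with pytest.raises(ValueError, match="empty"):
            generate_trees(disc_hr, [disc_hr.buffer(5.0)], 10, seed=0)


class TestTravelBouts:
    def test_perfect_fidelity_no_noise_fixes_on_graph(self, disc_hr):
        cfg = SyntheticConfig(seed=0, n_weeks=6)
        edges = [type(e)(e.xy + 150.0, e.multiplicity)
                 for e in separated_edges(2)]
        tb = generate_travel_bouts(edges, 1.0, 0.0, cfg, disc_hr, seed=1)
        d = network_point_distances(tb[["x", "y"]].to_numpy(),
                                    [e.xy for e in edges])
        assert d.max() < 0.6  # on the graph, within densification slack

    def test_empty_graph_with_fidelity_raises(self, disc_hr):
        cfg = SyntheticConfig(seed=0)
        with pytest.raises(ValueError, match="route_graph"):
            generate_travel_bouts([], 0.5, 6.6, cfg, disc_hr, seed=0)
        tb = generate_travel_bouts([], 0.0, 6.6, cfg, disc_hr, seed=0)
        assert len(tb) > 0  # pure random walks are fine without a graph

    def test_bout_length_matches_study_distribution(self, disc_hr):
        lens = []
        for seed in range(4):
            cfg = SyntheticConfig(seed=seed, n_weeks=20)
            edges = separated_edges(seed, (1, 2, 4, 7))
            edges = [type(e)(e.xy + 150.0, e.multiplicity) for e in edges]
            tb = generate_travel_bouts(edges, 0.75, 6.6, cfg, disc_hr,
                                       seed=seed + 10)
            lens.extend(
                np.hypot(np.diff(g.x), np.diff(g.y)).sum()
                for _, g in tb.groupby("bout_id"))
        assert len(lens) >= 1000
        assert abs(np.mean(lens) - 65.3) <= 10.0

    def test_determinism(self, disc_hr):
        cfg = SyntheticConfig(seed=0, n_weeks=4)
        edges = [type(e)(e.xy + 150.0, e.multiplicity)
                 for e in separated_edges(3)]
        a = generate_travel_bouts(edges, 0.8, 6.6, cfg, disc_hr, seed=9)
        b = generate_travel_bouts(edges, 0.8, 6.6, cfg, disc_hr, seed=9)
        pd.testing.assert_frame_equal(a, b)


class TestRoutePresenceForwardModel:
    def _quadrats(self, rng, n=10_000):
        return pd.DataFrame({
            "ft_density": rng.uniform(0, 1, n),
            "gap_pct": rng.uniform(0, 30, n),
            "group_id": rng.choice(["A", "B"], n),
        })

    def test_null_model_rate_half(self, rng):
        q = self._quadrats(rng)
        y = simulate_route_presence(q, {"intercept": 0.0}, seed=1)
        assert abs(y.mean() - 0.5) <= 0.03

    def test_positive_effect_monotone_over_deciles(self, rng):
        q = self._quadrats(rng, 40_000)
        y = simulate_route_presence(q, {"intercept": -1.0, "ft_density": 0.9},
                                    seed=2)
        dec = pd.qcut(q["ft_density"], 10, labels=False)
        rates = pd.Series(y).groupby(dec).mean()
        # monotone trend: top decile clearly above bottom, rank correlation high
        assert rates.iloc[-1] > rates.iloc[0]
        assert rates.corr(pd.Series(range(10), index=rates.index),
                          method="spearman") > 0.9

    def test_same_seed_identical(self, rng):
        q = self._quadrats(rng, 500)
        a = simulate_route_presence(q, {"ft_density": 1.0}, seed=3)
        b = simulate_route_presence(q, {"ft_density": 1.0}, seed=3)
        assert np.array_equal(a, b)

    def test_missing_covariate_named(self, rng):
        q = self._quadrats(rng, 100)
        with pytest.raises(KeyError, match="slope_deg"):
            simulate_route_presence(q, {"slope_deg": 1.0}, seed=0)


def test_scenario_determinism_and_containment(small_config):
    a = generate_scenario(small_config)
    b = generate_scenario(small_config)
    pd.testing.assert_frame_equal(a.tracks, b.tracks)
    pd.testing.assert_frame_equal(a.trees, b.trees)
    assert np.array_equal(a.dem.data, b.dem.data)
    box = shapely.box(*small_config.extent).buffer(1e-6)
    for g in a.groups:
        assert box.contains(g.home_range)
        t = g.trees
        assert shapely.contains_xy(g.home_range.buffer(1e-9),
                                   t.x.to_numpy(), t.y.to_numpy()).all()
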