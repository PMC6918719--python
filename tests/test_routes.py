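"""Segment matching, weekly deduplication and network accumulation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from routescape.routes import (MatchParams, bearing_diff_deg,
                               build_route_network, build_weekly_paths,
                               local_bearings, match_mask, matched_runs,
                               network_coverage, path_length, resample_path,
                               shared_segments, smooth_path, usage_along_path)


def straight(length=100.0, y=0.0, n=None):
    n = int(length) + 1 if n is None else n
    return np.column_stack([np.linspace(0.0, length, n), np.full(n, y)])


def brute_force_matched_mask(A, B, params):
    """Exhaustive all-pairs nearest-vertex matcher (independent oracle)."""
    half = max(1, int(round(params.bearing_window_m / (2 * params.step_m))))

    def bearing(P, i):
        j1, j2 = max(0, i - half), min(len(P) - 1, i + half)
        v = P[j2] - P[j1]
        return np.arctan2(v[1], v[0])

    mask = np.zeros(len(A), dtype=bool)
    for i in range(len(A)):
        dists = [float(np.hypot(*(A[i] - B[j]))) for j in range(len(B))]
        j = int(np.argmin(dists))
        if dists[j] <= params.buffer_m:
            d = abs(bearing(A, i) - bearing(B, j)) % np.pi
            if np.degrees(min(d, np.pi - d)) <= params.max_dev_deg:
                mask[i] = True
    return mask


def random_resampled_path(rg, n_max=8):
    n = rg.integers(3, n_max)
    start = rg.uniform(0, 50, 2)
    return resample_path(start + np.cumsum(rg.normal(0, 15, (n, 2)), axis=0), 1.0)


class TestResample:
    def test_straight_100m_gives_101_vertices(self):
        out = resample_path(np.array([[0.0, 0.0], [100.0, 0.0]]), 1.0)
        assert len(out) == 101
        assert np.allclose(np.diff(out[:, 0]), 1.0)

    def test_length_preserved(self, rng):
        pts = np.cumsum(rng.normal(0, 20, (6, 2)), axis=0)
        out = resample_path(pts, 1.0)
        assert abs(path_length(out) - path_length(pts)) / path_length(pts) < 1e-6

    def test_closed_loop_preserved(self):
        t = np.linspace(0, 2 * np.pi, 200)
        loop = np.column_stack([50 * np.cos(t), 50 * np.sin(t)])
        out = resample_path(loop, 1.0)
        assert np.allclose(out[0], out[-1])
        assert abs(path_length(out) - path_length(loop)) < 1e-6 * path_length(loop)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            resample_path(np.array([[0.0, 0.0]]), 1.0)


class TestSharedSegments:
    def test_identical_lines_fully_shared(self):
        line = straight(100.0)
        segs = shared_segments(line, line.copy())
        assert len(segs) == 1
        assert abs(path_length(segs[0]) - 100.0) <= 1.0

    def test_parallel_within_buffer_shared(self):
        a = straight(50.0)
        segs = shared_segments(a, a + [0.0, 5.0])
        assert len(segs) == 1 and path_length(segs[0]) >= 15.0
        assert path_length(segs[0]) >= 45.0

    def test_perpendicular_not_shared(self):
        a = straight(100.0)
        b = np.column_stack([np.full(101, 50.0), np.linspace(-50, 50, 101)])
        assert shared_segments(a, b) == []

    def test_outside_buffer_not_shared(self):
        a = straight(50.0)
        assert shared_segments(a, a + [0.0, 12.0]) == []

    def test_unresampled_input_rejected(self):
        coarse = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 0.0]])
        with pytest.raises(ValueError, match="resample"):
            shared_segments(coarse, straight(100.0))

    def test_agrees_with_brute_force_oracle(self):
        rg = np.random.default_rng(77)
        params = MatchParams()
        for _ in range(30):
            a, b = random_resampled_path(rg), random_resampled_path(rg)
            fast, _ = match_mask(a, local_bearings(a), b, local_bearings(b),
                                 params)
            assert np.array_equal(fast, brute_force_matched_mask(a, b, params))


class TestWeeklyDedup:
    def test_identical_daily_paths_collapse(self):
        line = straight(100.0)
        weekly = build_weekly_paths([line, line.copy()])
        assert len(weekly) == 1
        assert abs(sum(map(path_length, weekly)) - 100.0) < 1.0

    def test_disjoint_paths_both_kept(self):
        a, b = straight(80.0), straight(80.0, y=50.0)
        weekly = build_weekly_paths([a, b])
        assert len(weekly) == 2
        assert abs(sum(map(path_length, weekly)) - 160.0) < 1e-6

    def test_partial_overlap_kept_once(self):
        # two 100 m paths sharing their middle 40 m corridor
        a = straight(100.0)
        b = a.copy()
        b[:30, 1] += 30.0   # first 30 m far away
        b[70:, 1] += 30.0   # last 30 m far away
        b = resample_path(b, 1.0)
        weekly = build_weekly_paths([a, b])
        total = sum(map(path_length, weekly))
        # a kept whole (100) + unique climbs/remainders of b, shared ~40 m once
        assert total < path_length(a) + path_length(b) - 25.0


class TestNetwork:
    def test_same_path_four_weeks(self):
        line = straight(120.0)
        net = build_route_network({w: [line.copy()] for w in range(4)})
        assert all(s.weeks_used == 4 for s in net.segments)
        assert abs(net.total_length_m - 120.0) < 2.0
        assert abs(net.habitual_length_m - net.total_length_m) < 1e-9

    def test_disjoint_weeks_no_habitual(self):
        weekly = {w: [straight(60.0, y=100.0 * w)] for w in range(3)}
        net = build_route_network(weekly)
        assert all(s.weeks_used == 1 for s in net.segments)
        assert net.habitual() == []
        assert net.habitual_length_m == 0.0

    def test_weeks_used_bounded_by_sampled_weeks(self, small_config):
        from routescape.pipeline import RunConfig, build_group_network
        from routescape.synthetic import generate_scenario
        sc = generate_scenario(small_config)
        g = sc.groups[0]
        net = build_group_network(g.tracks, RunConfig(), group_id=g.group_id)
        n_weeks = g.tracks.week_id.nunique()
        assert all(1 <= s.weeks_used <= n_weeks for s in net.segments)

    def test_length_conservation_clean_geometry(self):
        # noiseless overlapping weekly paths: partition conserves length
        a = straight(200.0)
        half = resample_path(a[:101], 1.0)
        weekly = {0: [a], 1: [half], 2: [half.copy()]}
        net = build_route_network(weekly)
        assert abs(net.total_length_m - 200.0) / 200.0 < 0.01
        assert abs(net.habitual_length_m - 100.0) / 100.0 < 0.02

    def test_usage_along_path_reports_distinct_weeks(self):
        line = straight(120.0)
        net = build_route_network({w: [line.copy()] for w in range(5)})
        u = usage_along_path(net, line)
        assert u.max() == 5
        far = straight(120.0, y=500.0)
        assert usage_along_path(net, far).max() == 0

    def test_coverage_empty_network_zero(self):
        net = build_route_network({0: [straight(50.0)]})
        assert net.habitual() == []
        assert network_coverage([straight(50.0)], net) == 0.0

    def test_coverage_on_network_bouts(self):
        line = straight(150.0)
        net = build_route_network({w: [line.copy()] for w in range(3)})
        bouts = [resample_path(line[10:80], 1.0), straight(60.0, y=300.0)]
        assert network_coverage(bouts, net) == 0.5


class TestSmoothing:
    def test_smoothing_reduces_jitter(self, rng):
        base = straight(200.0)
        noisy = resample_path(base[::20] + rng.normal(0, 6.6, (11, 2)), 1.0)
        smoothed = smooth_path(noisy, 60.0)
        assert np.abs(smoothed[:, 1]).mean() < np.abs(noisy[:, 1]).mean()
        # endpoints stay near the raw track ends
        assert np.hypot(*(smoothed[0] - noisy[0])) < 8.0

    def test_zero_window_identity(self):
        p = straight(30.0)
        assert smooth_path(p, 0.0) is p


@given(a=st.floats(-10, 10), b=st.floats(-10, 10))
@settings(max_examples=200, deadline=None)
def test_bearing_difference_is_acute_angle(a, b):
    d = bearing_diff_deg(np.array([a]), np.array([b]))[0]
    assert 0.0 <= d <= 90.0 + 1e-9


@given(seed=st.integers(0, 1000))
@settings(max_examples=50, deadline=None)
def test_resample_spacing_uniform_and_bounded(seed):
    rg = np.random.default_rng(seed)
    pts = np.cumsum(rg.normal(0, 10, (5, 2)), axis=0)
    if path_length(pts) < 1e-6:
        return
    out = resample_path(pts, 1.0)
    gaps = np.hypot(*np.diff(out, axis=0).T)
    assert gaps.max() <= 1.0 + 1e-9
    assert np.allclose(out[0], pts[0]) and np.allclose(out[-1], pts[-1])
    assert abs(path_length(out) - path_length(pts)) <= 1e-9 * path_length(pts)
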