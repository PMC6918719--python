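"""Habitual route-network construction from repeated daily travel paths.

The recurrence rule: a vertex of path A matches path B when its nearest
B vertex lies within ``buffer_m`` (default 10 m) and the local bearings at
the two locations differ by at most ``max_dev_deg`` (default 45 deg, taken
modulo 180 deg so direction of travel is ignored). Maximal runs of matched
vertices spanning at least ``min_overlap_m`` (default 15 m) count as shared
segments. Daily paths are first deduplicated within each sampling week
("weekly paths"), then weekly paths are folded, week by week in
chronological order, into an accumulating network whose segments carry the
set of distinct weeks in which they were used. Segments used in at least
two separate weeks form the habitual route network.

All paths are polylines in planar metric coordinates, resampled to a 1 m
vertex spacing before matching.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "MatchParams",
    "RouteSegment",
    "RouteNetwork",
    "path_length",
    "resample_path",
    "smooth_path",
    "local_bearings",
    "bearing_diff_deg",
    "match_mask",
    "matched_runs",
    "shared_segments",
    "build_weekly_paths",
    "build_route_network",
    "network_coverage",
]


@dataclass(frozen=True)
class MatchParams:
    """Thresholds of the segment-recurrence rule."""

    buffer_m: float = 10.0
    min_overlap_m: float = 15.0
    max_dev_deg: float = 45.0
    bearing_window_m: float = 10.0   # centered window for local bearings
    step_m: float = 1.0              # resampling step paths must satisfy


def path_length(xy: np.ndarray) -> float:
    xy = np.asarray(xy, dtype=float)
    if len(xy) < 2:
        return 0.0
    return float(np.hypot(*np.diff(xy, axis=0).T).sum())


def _cum_arc(xy: np.ndarray) -> np.ndarray:
    d = np.hypot(*np.diff(xy, axis=0).T)
    return np.concatenate([[0.0], np.cumsum(d)])


def resample_path(points: np.ndarray, step_m: float = 1.0,
                  keep_vertices: bool = True) -> np.ndarray:
    """Densify a polyline to vertices spaced ``L / ceil(L / step_m)`` apart
    in arc length; endpoints are always vertices.

    With ``keep_vertices`` (the default) the original vertices (corners)
    are retained, so geometry and total length are preserved exactly and
    spacing never exceeds ``step_m``. With ``keep_vertices=False`` only the
    equally spaced stations are returned (used e.g. to lay GPS fixes along
    a true path, where corner cutting is part of the measurement model).
    """
    xy = np.asarray(points, dtype=float)
    if xy.ndim != 2 or xy.shape[1] != 2 or len(xy) < 2:
        raise ValueError("resample_path needs at least two (x, y) points")
    if step_m <= 0:
        raise ValueError("step_m must be positive")
    arc = _cum_arc(xy)
    total = arc[-1]
    if total == 0.0:
        raise ValueError("degenerate path of zero length")
    n = max(1, int(np.ceil(total / step_m - 1e-9)))
    s = np.linspace(0.0, total, n + 1)
    if keep_vertices:
        s = np.union1d(s, arc)
        # drop near-duplicate stations (a corner sitting on a grid multiple)
        keep = np.concatenate([[True], np.diff(s) > 1e-9])
        s = s[keep]
    x = np.interp(s, arc, xy[:, 0])
    y = np.interp(s, arc, xy[:, 1])
    return np.column_stack([x, y])


def smooth_path(xy: np.ndarray, window_m: float, step_m: float = 1.0) -> np.ndarray:
    """Centered moving-average smoothing of a resampled path.

    Averages vertices over a centered arc window, with reflection padding at
    the ends so endpoints are not dragged toward the path interior. Used to
    suppress per-fix GPS jitter before segment matching; ``window_m=0`` is a
    no-op.
    """
    xy = np.asarray(xy, dtype=float)
    if window_m <= 0 or len(xy) < 3:
        return xy
    half = max(1, int(round(window_m / (2.0 * step_m))))
    n = len(xy)
    k = min(half, n - 1)
    # reflect about the end vertices: 2*p_end - p
    head = 2 * xy[0] - xy[1:k + 1][::-1]
    tail = 2 * xy[-1] - xy[-k - 1:-1][::-1]
    ext = np.vstack([head, xy, tail])
    csum = np.vstack([np.zeros(2), np.cumsum(ext, axis=0)])
    i = np.arange(n) + k
    lo = i - min(half, k)
    hi = i + min(half, k)
    return (csum[hi + 1] - csum[lo]) / (hi - lo + 1)[:, None]


def local_bearings(xy: np.ndarray, window_m: float = 10.0,
                   step_m: float = 1.0) -> np.ndarray:
    """Bearing (radians) at each vertex over a centered arc window.

    The window smooths 1 m-step jitter; at the path ends the window is
    truncated. Bearings are undirected quantities downstream (compared
    modulo 180 deg).
    """
    xy = np.asarray(xy, dtype=float)
    n = len(xy)
    half = max(1, int(round(window_m / (2.0 * step_m))))
    i = np.arange(n)
    j1 = np.maximum(0, i - half)
    j2 = np.minimum(n - 1, i + half)
    vec = xy[j2] - xy[j1]
    return np.arctan2(vec[:, 1], vec[:, 0])


def bearing_diff_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Acute angle (deg) between two undirected bearings given in radians."""
    d = np.abs(a - b) % np.pi
    d = np.minimum(d, np.pi - d)
    return np.degrees(d)


def _check_resampled(xy: np.ndarray, step_m: float) -> None:
    d = np.hypot(*np.diff(xy, axis=0).T)
    if len(d) == 0:
        raise ValueError("path has fewer than two vertices")
    if d.max() > step_m * 1.01:
        raise ValueError(
            f"path not resampled at <= {step_m} m (max spacing {d.max():.2f} m); "
            "call resample_path first"
        )


def match_mask(
    a_xy: np.ndarray,
    a_bear: np.ndarray,
    b_xy: np.ndarray,
    b_bear: np.ndarray,
    params: MatchParams,
    tree: cKDTree | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-vertex match of A against reference geometry B.

    Returns (mask, nearest_index): vertex i of A is matched when its nearest
    B vertex is within ``buffer_m`` and the undirected bearing difference at
    the two locations is within ``max_dev_deg``.
    """
    if tree is None:
        tree = cKDTree(b_xy)
    dist, idx = tree.query(a_xy)
    dev = bearing_diff_deg(a_bear, b_bear[np.minimum(idx, len(b_bear) - 1)])
    mask = (dist <= params.buffer_m) & (dev <= params.max_dev_deg)
    return mask, idx


def matched_runs(mask: np.ndarray, arc: np.ndarray,
                 min_overlap_m: float) -> list[tuple[int, int]]:
    """Maximal runs of True with arc span >= min_overlap_m, as (i0, i1) inclusive."""
    runs: list[tuple[int, int]] = []
    n = len(mask)
    i = 0
    while i < n:
        if mask[i]:
            j = i
            while j + 1 < n and mask[j + 1]:
                j += 1
            if arc[j] - arc[i] >= min_overlap_m - 1e-9:
                runs.append((i, j))
            i = j + 1
        else:
            i += 1
    return runs


def _partition(n: int, runs: Sequence[tuple[int, int]]) -> list[tuple[int, int, bool]]:
    """Partition vertex range [0, n-1] into alternating (a, b, matched) pieces.

    Adjacent pieces share their boundary vertex so that edge length is
    conserved exactly across the partition.
    """
    pieces: list[tuple[int, int, bool]] = []
    prev = 0
    for (i0, i1) in runs:
        if i0 > prev:
            pieces.append((prev, i0, False))
        pieces.append((i0, i1, True))
        prev = i1
    if prev < n - 1:
        pieces.append((prev, n - 1, False))
    if not pieces:  # no runs at all
        pieces.append((0, n - 1, False))
    return pieces


def shared_segments(
    path_a: np.ndarray,
    path_b: np.ndarray,
    buffer_m: float = 10.0,
    min_overlap_m: float = 15.0,
    max_dev_deg: float = 45.0,
    params: MatchParams | None = None,
) -> list[np.ndarray]:
    """Sub-segments of A that retrace B under the recurrence rule.

    Both paths must already be resampled at the matching step (1 m default);
    unresampled input raises, because vertex-level matching is only
    meaningful on dense equidistant vertices.
    """
    if params is None:
        params = MatchParams(buffer_m=buffer_m, min_overlap_m=min_overlap_m,
                             max_dev_deg=max_dev_deg)
    a = np.asarray(path_a, dtype=float)
    b = np.asarray(path_b, dtype=float)
    _check_resampled(a, params.step_m)
    _check_resampled(b, params.step_m)
    a_bear = local_bearings(a, params.bearing_window_m, params.step_m)
    b_bear = local_bearings(b, params.bearing_window_m, params.step_m)
    mask, _ = match_mask(a, a_bear, b, b_bear, params)
    arc = _cum_arc(a)
    return [a[i0:i1 + 1] for i0, i1 in matched_runs(mask, arc, params.min_overlap_m)]


# ---------------------------------------------------------------------------
# weekly deduplication and network accumulation


@dataclass(frozen=True)
class RouteSegment:
    """A piece of route geometry with the set of distinct weeks it was used."""

    xy: np.ndarray
    weeks: frozenset
    group_id: str | None = None

    @property
    def weeks_used(self) -> int:
        return len(self.weeks)

    @property
    def length_m(self) -> float:
        return path_length(self.xy)


@dataclass
class RouteNetwork:
    segments: list[RouteSegment] = field(default_factory=list)
    habitual_threshold: int = 2
    group_id: str | None = None

    def habitual(self, min_weeks: int | None = None) -> list[RouteSegment]:
        t = self.habitual_threshold if min_weeks is None else min_weeks
        return [s for s in self.segments if s.weeks_used >= t]

    @property
    def total_length_m(self) -> float:
        return sum(s.length_m for s in self.segments)

    @property
    def habitual_length_m(self) -> float:
        return sum(s.length_m for s in self.habitual())


def _concat_reference(
    seg_xy: Sequence[np.ndarray], params: MatchParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, cKDTree]:
    """Stack segment vertex arrays into one reference with bookkeeping."""
    coords = np.vstack(seg_xy)
    bear = np.concatenate(
        [local_bearings(s, params.bearing_window_m, params.step_m) for s in seg_xy]
    )
    seg_id = np.concatenate(
        [np.full(len(s), k, dtype=int) for k, s in enumerate(seg_xy)]
    )
    local = np.concatenate([np.arange(len(s)) for s in seg_xy])
    return coords, bear, seg_id, local, cKDTree(coords)


def build_weekly_paths(
    daily_paths: Sequence[np.ndarray],
    params: MatchParams | None = None,
) -> list[np.ndarray]:
    """Collapse within-week repeats of the same route to one representative.

    Paths are processed in the given (day) order; portions of a later path
    that retrace already retained geometry for at least ``min_overlap_m``
    are dropped, earlier geometry being the representative. The result is
    the set of unique path pieces of that week.
    """
    params = params or MatchParams()
    kept: list[np.ndarray] = []
    for xy in daily_paths:
        xy = np.asarray(xy, dtype=float)
        _check_resampled(xy, params.step_m)
        if not kept:
            kept.append(xy)
            continue
        coords, bear, _, _, tree = _concat_reference(kept, params)
        a_bear = local_bearings(xy, params.bearing_window_m, params.step_m)
        mask, _ = match_mask(xy, a_bear, coords, bear, params, tree)
        runs = matched_runs(mask, _cum_arc(xy), params.min_overlap_m)
        for a, b, matched in _partition(len(xy), runs):
            if not matched and b - a >= 1:
                kept.append(xy[a:b + 1])
    return kept


def _consolidate(segments: list[RouteSegment], params: MatchParams,
                 group_id: str | None) -> list[RouteSegment]:
    """Union week sets across network segments that are the same route.

    GPS noise leaves near-parallel copies of one route in the accumulated
    network, with the weeks of use scattered over the copies. Any two
    segments that satisfy the same-segment rule (within the buffer, bearing
    within the deviation limit, over at least the minimum overlap) represent
    the same route, so the weeks of each are credited to the other on the
    matched stretch. Segments are then re-split wherever the combined week
    set changes.
    """
    if len(segments) < 2:
        return segments
    seg_xy = [s.xy for s in segments]
    coords, bear, seg_id, local, tree = _concat_reference(seg_xy, params)
    week_sets: list[list[set]] = [
        [set(s.weeks) for _ in range(len(s.xy))] for s in segments
    ]
    neighbors = tree.query_ball_point(coords, params.buffer_m)
    offset = np.concatenate([[0], np.cumsum([len(s) for s in seg_xy])])
    for si, s in enumerate(segments):
        n = len(s.xy)
        base = offset[si]
        my_bear = bear[base:base + n]
        # per neighboring segment: mask of my vertices it matches
        per_seg: dict[int, np.ndarray] = {}
        for i in range(n):
            for j in neighbors[base + i]:
                t = seg_id[j]
                if t == si:
                    continue
                if bearing_diff_deg(my_bear[i], bear[j]) <= params.max_dev_deg:
                    per_seg.setdefault(int(t), np.zeros(n, dtype=bool))[i] = True
        arc = _cum_arc(s.xy)
        for t, m in per_seg.items():
            for i0, i1 in matched_runs(m, arc, params.min_overlap_m):
                for i in range(i0, i1 + 1):
                    week_sets[si][i] |= segments[t].weeks
    out: list[RouteSegment] = []
    for si, s in enumerate(segments):
        ws = week_sets[si]
        a = 0
        for b in range(1, len(ws) + 1):
            if b == len(ws) or ws[b] != ws[a]:
                # adjacent pieces share the boundary vertex (length conserved)
                hi = min(b + 1, len(ws)) if b < len(ws) else len(ws)
                if hi - a >= 2:
                    out.append(RouteSegment(s.xy[a:hi], frozenset(ws[a]), group_id))
                a = b
    return out


def build_route_network(
    weekly_paths: Mapping[object, Sequence[np.ndarray]],
    params: MatchParams | None = None,
    habitual_threshold: int = 2,
    group_id: str | None = None,
    consolidate: bool = True,
) -> RouteNetwork:
    """Fold weekly path sets into a usage-counted route network.

    Weeks are processed in chronological (sorted-key) order. Each week's
    paths are matched against the current network's representative geometry;
    matched portions add that week to the touched segments' week sets
    (at most once per week), unmatched portions enter the network as new
    segments used in that week only. Segments are split where the within-week
    usage mask changes, so every piece of network geometry carries the exact
    number of distinct weeks in which it was retraced.
    """
    params = params or MatchParams()
    segments: list[RouteSegment] = []
    for week in sorted(weekly_paths):
        paths = [np.asarray(p, dtype=float) for p in weekly_paths[week]]
        for p in paths:
            _check_resampled(p, params.step_m)
        if not segments:
            segments = [
                RouteSegment(p, frozenset([week]), group_id)
                for p in paths if len(p) >= 2
            ]
            continue
        seg_xy = [s.xy for s in segments]
        coords, bear, seg_id, local, tree = _concat_reference(seg_xy, params)
        marks = [np.zeros(len(s), dtype=bool) for s in seg_xy]
        new_pieces: list[np.ndarray] = []
        for xy in paths:
            a_bear = local_bearings(xy, params.bearing_window_m, params.step_m)
            mask, idx = match_mask(xy, a_bear, coords, bear, params, tree)
            runs = matched_runs(mask, _cum_arc(xy), params.min_overlap_m)
            for (i0, i1) in runs:
                hit = idx[i0:i1 + 1]
                for k in np.unique(seg_id[hit]):
                    loc = local[hit[seg_id[hit] == k]]
                    marks[k][loc.min():loc.max() + 1] = True
            for a, b, matched in _partition(len(xy), runs):
                if not matched and b - a >= 1:
                    new_pieces.append(xy[a:b + 1])
        updated: list[RouteSegment] = []
        for seg, m in zip(segments, marks):
            if not m.any():
                updated.append(seg)
                continue
            runs = matched_runs(m, _cum_arc(seg.xy), 0.0)
            for a, b, matched in _partition(len(seg.xy), runs):
                if b - a < 1:
                    continue
                weeks = seg.weeks | {week} if matched else seg.weeks
                updated.append(replace(seg, xy=seg.xy[a:b + 1], weeks=frozenset(weeks)))
        segments = updated + [
            RouteSegment(p, frozenset([week]), group_id) for p in new_pieces
        ]
    if consolidate:
        segments = _consolidate(segments, params, group_id)
    return RouteNetwork(segments=segments, habitual_threshold=habitual_threshold,
                        group_id=group_id)


def usage_along_path(
    network: RouteNetwork,
    path: np.ndarray,
    params: MatchParams | None = None,
) -> np.ndarray:
    """Distinct weeks of use attributed to route geometry along a polyline.

    For each vertex of the (resampled) query path, takes the union of the
    week sets of all network segments with a bearing-compatible vertex
    within the matching buffer, and returns the count of distinct weeks.
    This is the overlay notion of usage frequency at a location: the number
    of separate sampling weeks in which travel passed there along the same
    route.
    """
    params = params or MatchParams()
    path = np.asarray(path, dtype=float)
    _check_resampled(path, params.step_m)
    if not network.segments:
        return np.zeros(len(path), dtype=int)
    seg_xy = [s.xy for s in network.segments]
    coords, bear, seg_id, _, tree = _concat_reference(seg_xy, params)
    pb = local_bearings(path, params.bearing_window_m, params.step_m)
    out = np.zeros(len(path), dtype=int)
    for i, ix in enumerate(tree.query_ball_point(path, params.buffer_m)):
        weeks: set = set()
        for j in ix:
            if bearing_diff_deg(pb[i], bear[j]) <= params.max_dev_deg:
                weeks |= network.segments[seg_id[j]].weeks
        out[i] = len(weeks)
    return out


def network_coverage(
    travel_bouts: Iterable[np.ndarray],
    network: RouteNetwork,
    params: MatchParams | None = None,
    min_weeks: int | None = None,
    bout_fraction: float = 0.5,
) -> float:
    """Fraction of travel bouts that fall within the habitual network.

    A bout counts as "within" when at least ``bout_fraction`` (default one
    half) of its vertices match habitual segments under the buffer/bearing
    rule. Returns 0.0 when the habitual network is empty.
    """
    params = params or MatchParams()
    habitual = network.habitual(min_weeks)
    bouts = list(travel_bouts)
    if not bouts:
        raise ValueError("no travel bouts supplied")
    if not habitual:
        return 0.0
    coords, bear, _, _, tree = _concat_reference([s.xy for s in habitual], params)
    within = 0
    for xy in bouts:
        xy = np.asarray(xy, dtype=float)
        a_bear = local_bearings(xy, params.bearing_window_m, params.step_m)
        mask, _ = match_mask(xy, a_bear, coords, bear, params, tree)
        if mask.mean() >= bout_fraction:
            within += 1
    return within / len(bouts)
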