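"""Quadrat-grid landscape covariates: elevation, slope, canopy-gap cover,
route presence.

Quadrats are axis-aligned 10 x 10 m cells whose centers fall inside a
group's home range; the grid origin is the floor of the polygon bounds.
Elevation is bilinearly sampled at cell centers; slope is the
maximum-rate-of-change over the 8 neighboring quadrats; gap cover is the
percentage of a 25 m disc around the center overlapped by gap polygons.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Point, Polygon
from shapely.ops import unary_union
from shapely.strtree import STRtree

from .raster import Raster
from .routes import RouteNetwork

__all__ = [
    "make_grid",
    "slope_at",
    "slope_grid",
    "gap_coverage",
    "route_presence",
    "quadrat_table",
]


def make_grid(home_range: Polygon, cell_m: float = 10.0) -> pd.DataFrame:
    """Cells (center x/y, row/col) whose centers fall inside ``home_range``."""
    if home_range.is_empty or home_range.area <= 0:
        raise ValueError("degenerate home-range polygon")
    if cell_m <= 0:
        raise ValueError("cell_m must be positive")
    xmin, ymin, xmax, ymax = home_range.bounds
    x0 = math.floor(xmin)
    y0 = math.floor(ymin)
    ncol = int(math.ceil((xmax - x0) / cell_m))
    nrow = int(math.ceil((ymax - y0) / cell_m))
    cols, rows = np.meshgrid(np.arange(ncol), np.arange(nrow))
    cx = x0 + (cols.ravel() + 0.5) * cell_m
    cy = y0 + (rows.ravel() + 0.5) * cell_m
    inside = shapely.contains_xy(home_range, cx, cy)
    df = pd.DataFrame({
        "row": rows.ravel()[inside],
        "col": cols.ravel()[inside],
        "x": cx[inside],
        "y": cy[inside],
    })
    df.insert(0, "cell_id", [f"r{r}c{c}" for r, c in zip(df["row"], df["col"])])
    df.attrs["cell_m"] = cell_m
    df.attrs["origin"] = (x0, y0)
    return df.reset_index(drop=True)


_NEIGHBORS = [(-1, -1), (-1, 0), (-1, 1), (0, -1),
              (0, 1), (1, -1), (1, 0), (1, 1)]


def slope_at(elev: Mapping[tuple[int, int], float], cell: tuple[int, int],
             cell_m: float = 10.0) -> float:
    """Slope (degrees) at one quadrat: max |dz|/distance over 8 neighbors.

    ``elev`` maps (row, col) to center elevation; neighbors absent from the
    map are ignored (edge cells), and a cell with no neighbor at all raises.
    """
    r, c = cell
    z0 = elev[(r, c)]
    best = None
    for dr, dc in _NEIGHBORS:
        key = (r + dr, c + dc)
        if key in elev:
            dist = cell_m * math.sqrt(dr * dr + dc * dc)
            g = abs(elev[key] - z0) / dist
            best = g if best is None else max(best, g)
    if best is None:
        raise ValueError(f"quadrat {cell} has no neighbors to compute slope from")
    return math.degrees(math.atan(best))


def slope_grid(cells: pd.DataFrame, elevation: np.ndarray,
               cell_m: float = 10.0) -> np.ndarray:
    """Vectorized ``slope_at`` over a quadrat table with an elevation column."""
    elev = {(int(r), int(c)): float(z)
            for r, c, z in zip(cells["row"], cells["col"], elevation)}
    return np.array([
        slope_at(elev, (int(r), int(c)), cell_m)
        for r, c in zip(cells["row"], cells["col"])
    ])


def gap_coverage(cell_center: tuple[float, float],
                 gap_polygons: Sequence[Polygon],
                 radius_m: float = 25.0) -> float:
    """Percent of the ``radius_m`` disc around the center covered by gaps."""
    if radius_m <= 0:
        raise ValueError("radius_m must be positive")
    if not gap_polygons:
        return 0.0
    disc = Point(cell_center).buffer(radius_m, quad_segs=64)
    inter = disc.intersection(unary_union(list(gap_polygons)))
    return 100.0 * inter.area / disc.area


def route_presence(cell: tuple[float, float], network: RouteNetwork,
                   min_weeks: int, cell_m: float = 10.0) -> int:
    """1 iff a segment used in >= ``min_weeks`` weeks intersects the cell square.

    The square is closed: touching its boundary (even a corner) counts.
    """
    half = cell_m / 2.0
    sq = shapely.box(cell[0] - half, cell[1] - half, cell[0] + half, cell[1] + half)
    for seg in network.habitual(min_weeks):
        if sq.intersects(shapely.LineString(seg.xy)):
            return 1
    return 0


def _route_presence_column(cells: pd.DataFrame, network: RouteNetwork,
                           min_weeks: int, cell_m: float) -> np.ndarray:
    segs = network.habitual(min_weeks)
    out = np.zeros(len(cells), dtype=int)
    if not segs:
        return out
    lines = [shapely.LineString(s.xy) for s in segs]
    tree = STRtree(lines)
    half = cell_m / 2.0
    boxes = shapely.box(cells["x"].to_numpy() - half, cells["y"].to_numpy() - half,
                        cells["x"].to_numpy() + half, cells["y"].to_numpy() + half)
    hit_box, _ = tree.query(boxes, predicate="intersects")
    out[np.unique(hit_box)] = 1
    return out


def quadrat_table(
    group_id: str,
    home_range: Polygon,
    core_area: Polygon | None,
    dem: Raster,
    gaps: Sequence[Polygon],
    network: RouteNetwork,
    other_home_ranges: Sequence[Polygon] = (),
    cell_m: float = 10.0,
    gap_radius_m: float = 25.0,
    habitual_weeks: int = 2,
    highuse_weeks: int = 4,
) -> pd.DataFrame:
    """Assemble the per-quadrat covariate/response table for one group.

    Columns: cell_id, group_id, x, y, elevation_m, rel_elevation (elevation
    minus the group minimum), slope_deg, gap_pct, route_ge2, route_ge4,
    overlap_flag (cell also inside another group's range), core_flag.
    The food-tree density index is merged in by the resource module.
    """
    cells = make_grid(home_range, cell_m)
    elev = dem.sample_bilinear(cells["x"].to_numpy(), cells["y"].to_numpy())
    slope = slope_grid(cells, elev, cell_m)
    gp = np.array([
        gap_coverage((x, y), gaps, gap_radius_m)
        for x, y in zip(cells["x"], cells["y"])
    ]) if gaps else np.zeros(len(cells))
    ge2 = _route_presence_column(cells, network, habitual_weeks, cell_m)
    ge4 = _route_presence_column(cells, network, highuse_weeks, cell_m)
    if other_home_ranges:
        others = unary_union(list(other_home_ranges))
        overlap = shapely.contains_xy(others, cells["x"].to_numpy(),
                                      cells["y"].to_numpy()).astype(int)
    else:
        overlap = np.zeros(len(cells), dtype=int)
    if core_area is not None and not core_area.is_empty:
        core = shapely.contains_xy(core_area, cells["x"].to_numpy(),
                                   cells["y"].to_numpy()).astype(int)
    else:
        core = np.zeros(len(cells), dtype=int)
    out = cells.copy()
    out["group_id"] = group_id
    out["elevation_m"] = elev
    out["rel_elevation"] = elev - elev.min()
    out["slope_deg"] = slope
    out["gap_pct"] = gp
    out["route_ge2"] = ge2
    out["route_ge4"] = ge4
    out["overlap_flag"] = overlap
    out["core_flag"] = core
    return out
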