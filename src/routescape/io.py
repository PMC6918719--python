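"""Readers and writers for the pipeline's on-disk formats.

Tables are CSV; vector geometry is GeoJSON (plain planar metric
coordinates, no CRS handling); elevation rasters are ESRI ASCII grids
(see :mod:`routescape.raster`).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import mapping, shape

from .routes import RouteNetwork, RouteSegment

__all__ = [
    "read_tracks", "write_tracks",
    "read_trees", "write_trees",
    "read_polygons_geojson", "write_polygons_geojson",
    "write_network_geojson", "read_network_geojson",
    "write_homeranges_geojson",
]

_TRACK_COLS = ["group_id", "week_id", "day_id", "bout_id", "fix_idx",
               "x", "y", "rectype"]


def write_tracks(tracks: pd.DataFrame, path: str | Path) -> None:
    tracks[_TRACK_COLS].to_csv(path, index=False, float_format="%.3f")


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_TRACK_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"tracks file is missing columns: {sorted(missing)}")
    return df


def write_trees(trees: pd.DataFrame, path: str | Path) -> None:
    trees.to_csv(path, index=False, float_format="%.3f")


def read_trees(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x", "y"):
        if col not in df.columns:
            raise ValueError(f"trees file is missing column {col!r}")
    return df


def write_polygons_geojson(polys: Sequence, path: str | Path,
                           properties: Sequence[dict] | None = None) -> None:
    feats = []
    for i, p in enumerate(polys):
        props = dict(properties[i]) if properties is not None else {}
        feats.append({"type": "Feature", "properties": props,
                      "geometry": mapping(p)})
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=None))


def read_polygons_geojson(path: str | Path):
    gj = json.loads(Path(path).read_text())
    geoms, props = [], []
    for f in gj.get("features", []):
        geoms.append(shape(f["geometry"]))
        props.append(f.get("properties", {}))
    return geoms, props


def write_network_geojson(network: RouteNetwork, path: str | Path) -> None:
    feats = []
    for seg in network.segments:
        feats.append({
            "type": "Feature",
            "properties": {
                "group_id": seg.group_id,
                "weeks_used": seg.weeks_used,
                "weeks": sorted(int(w) for w in seg.weeks),
                "length_m": round(seg.length_m, 2),
            },
            "geometry": mapping(shapely.LineString(np.round(seg.xy, 3))),
        })
    Path(path).write_text(json.dumps(
        {"type": "FeatureCollection", "features": feats}, indent=None))


def read_network_geojson(path: str | Path) -> RouteNetwork:
    gj = json.loads(Path(path).read_text())
    segs = []
    group_id = None
    for f in gj.get("features", []):
        props = f.get("properties", {})
        xy = np.asarray(f["geometry"]["coordinates"], dtype=float)
        weeks = frozenset(props.get("weeks", range(props.get("weeks_used", 1))))
        group_id = props.get("group_id", group_id)
        segs.append(RouteSegment(xy, weeks, props.get("group_id")))
    return RouteNetwork(segments=segs, group_id=group_id)


def write_homeranges_geojson(home_ranges: dict, path: str | Path) -> None:
    polys, props = [], []
    for gid, hr in home_ranges.items():
        for q, poly in sorted((hr.isopleths or {0.95: hr.hr95}).items()):
            polys.append(poly)
            props.append({"group_id": gid, "isopleth": q,
                          "area_ha": round(poly.area / 1e4, 3)})
    write_polygons_geojson(polys, path, props)
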