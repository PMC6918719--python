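"""End-to-end orchestration: synthetic or user data in, analysis tables out.

Stages: (1) generate or load inputs; (2) KDE home ranges from scan fixes;
(3) habitual route network per group from travel bouts; (4) quadrat
landscape covariates and resource metrics (buffer counts vs. the CSR null,
segment interception rates, food-tree density index, nearest-neighbor
clustering); (5) the three mixed models. Every stage writes plain-text
artifacts (CSV / GeoJSON / ESRI ASCII / JSON) into the output directory,
and all randomness flows from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .landscape import quadrat_table
from .models import run_core_models
from .ranging import HomeRange, hr_summary, kde_home_range
from .raster import write_ascii_grid
from .resources import (csr_null, ft_density_column, nearest_neighbor_z,
                        segment_rate_table, trees_in_network_buffers)
from .routes import (MatchParams, RouteNetwork, build_route_network,
                     build_weekly_paths, network_coverage, resample_path,
                     smooth_path)  # noqa: F401 (resample/smooth re-exported)
from .synthetic import SyntheticConfig, generate_scenario

__all__ = ["RunConfig", "run_all", "bout_paths_by_week", "build_group_network"]

log = logging.getLogger("routescape")


@dataclass
class RunConfig:
    """Thresholds and sizes of one pipeline run (defaults: the study values).

    ``synthetic`` drives generation; alternatively point ``tracks_csv``,
    ``trees_csv``, ``gaps_geojson`` and ``dem_asc`` at existing files.
    """

    seed: int = 0
    out_dir: str = "results"
    synthetic: SyntheticConfig | None = None
    tracks_csv: str | None = None
    trees_csv: str | None = None
    gaps_geojson: str | None = None
    dem_asc: str | None = None

    buffer_m: float = 10.0
    min_overlap_m: float = 15.0
    max_dev_deg: float = 45.0
    habitual_weeks: int = 2
    highuse_weeks: int = 4
    network_radii: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0)
    visual_radii: tuple[float, ...] = (5.0, 10.0, 15.0, 20.0, 25.0, 30.0, 35.0)
    grid_cell_m: float = 10.0
    gap_radius_m: float = 25.0
    n_sims: int = 10_000
    smooth_window_m: float = 60.0
    kde_grid_res_m: float = 5.0
    d_grid: tuple[float, ...] = tuple(range(1, 31))
    exclude_group: str | None = None

    def __post_init__(self) -> None:
        for name in ("buffer_m", "min_overlap_m", "max_dev_deg",
                     "habitual_weeks", "highuse_weeks", "grid_cell_m",
                     "gap_radius_m", "n_sims"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def match_params(self) -> MatchParams:
        return MatchParams(buffer_m=self.buffer_m,
                           min_overlap_m=self.min_overlap_m,
                           max_dev_deg=self.max_dev_deg)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def bout_paths_by_week(tracks: pd.DataFrame, params: MatchParams,
                       smooth_window_m: float) -> dict[int, list[np.ndarray]]:
    """Travel-bout polylines per week: 1 m resampled, jitter-smoothed."""
    out: dict[int, list[np.ndarray]] = {}
    travel = tracks[tracks["rectype"] == "travel"]
    for (w, _b), grp in travel.groupby(["week_id", "bout_id"], sort=True):
        xy = grp.sort_values("fix_idx")[["x", "y"]].to_numpy(dtype=float)
        if len(xy) < 2:
            continue
        p = resample_path(xy, params.step_m)
        p = smooth_path(p, smooth_window_m, params.step_m)
        out.setdefault(int(w), []).append(p)
    if not out:
        raise ValueError("no travel bouts in tracks")
    return out


def build_group_network(tracks: pd.DataFrame, config: RunConfig,
                        group_id: str | None = None) -> RouteNetwork:
    """Weekly dedup + chronological fold for one group's travel bouts."""
    params = config.match_params
    weekly_raw = bout_paths_by_week(tracks, params, config.smooth_window_m)
    weekly = {w: build_weekly_paths(ps, params) for w, ps in weekly_raw.items()}
    return build_route_network(weekly, params,
                               habitual_threshold=config.habitual_weeks,
                               group_id=group_id)


def _load_inputs(config: RunConfig, out: Path):
    if config.synthetic is not None:
        sc = dataclasses.replace(config.synthetic, seed=config.seed)
        scenario = generate_scenario(sc)
        tracks, trees = scenario.tracks, scenario.trees
        gaps, dem = scenario.gaps, scenario.dem
        rio.write_tracks(tracks, out / "tracks.csv")
        rio.write_trees(trees, out / "trees.csv")
        rio.write_polygons_geojson(gaps, out / "gaps.geojson")
        write_ascii_grid(dem, out / "dem.asc")
        truth = {
            "seed": sc.seed,
            "tree_mode": scenario.truth.tree_mode,
            "route_graph": {
                gid: [{"multiplicity": e.multiplicity,
                       "xy": np.round(e.xy, 3).tolist()}
                      for e in edges]
                for gid, edges in scenario.truth.route_graph.items()
            },
        }
        (out / "truth.json").write_text(json.dumps(truth))
        return tracks, trees, gaps, dem
    for name in ("tracks_csv", "trees_csv"):
        p = getattr(config, name)
        if p is None or not Path(p).exists():
            raise FileNotFoundError(
                f"real-data mode needs {name} (got {p!r}); nothing was computed")
    tracks = rio.read_tracks(config.tracks_csv)
    trees = rio.read_trees(config.trees_csv)
    gaps = []
    if config.gaps_geojson and Path(config.gaps_geojson).exists():
        gaps, _ = rio.read_polygons_geojson(config.gaps_geojson)
    if config.dem_asc and Path(config.dem_asc).exists():
        from .raster import read_ascii_grid
        dem = read_ascii_grid(config.dem_asc)
    else:
        raise FileNotFoundError("real-data mode needs dem_asc")
    return tracks, trees, gaps, dem


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the artifact directory.

    Deterministic for a fixed config and seed: rerunning into a fresh
    directory reproduces byte-identical tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if not log.handlers:
        h = logging.StreamHandler(sys.stderr)
        h.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
        log.addHandler(h)
        log.setLevel(logging.INFO)
    fh = logging.FileHandler(out / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s: %(message)s"))
    log.addHandler(fh)
    try:
        return _run_all(config, out)
    finally:
        log.removeHandler(fh)
        fh.close()


def _run_all(config: RunConfig, out: Path) -> Path:
    import routescape

    ss = np.random.SeedSequence(config.seed)
    csr_streams = ss.spawn(64)
    log.info("routescape %s seed=%d config=%s", routescape.__version__,
             config.seed, config.config_hash())

    log.info("stage 1/5: inputs")
    tracks, trees, gaps, dem = _load_inputs(config, out)
    group_ids = sorted(tracks["group_id"].unique())

    log.info("stage 2/5: KDE home ranges (%d groups)", len(group_ids))
    home_ranges: dict[str, HomeRange] = {}
    for gid in group_ids:
        scans = tracks.query("group_id == @gid and rectype == 'scan'")
        home_ranges[gid] = kde_home_range(
            scans[["x", "y"]].to_numpy(dtype=float),
            grid_res_m=config.kde_grid_res_m, group_id=gid)
    rio.write_homeranges_geojson(home_ranges, out / "homeranges.geojson")
    hr_summary(home_ranges).to_csv(out / "homerange_summary.csv", index=False,
                                   float_format="%.4f")

    log.info("stage 3/5: route networks")
    networks: dict[str, RouteNetwork] = {}
    net_rows = []
    all_segments = []
    for gid in group_ids:
        gtracks = tracks[tracks["group_id"] == gid]
        net = build_group_network(gtracks, config, group_id=gid)
        networks[gid] = net
        weekly_raw = bout_paths_by_week(gtracks, config.match_params,
                                        config.smooth_window_m)
        bouts = [p for ps in weekly_raw.values() for p in ps]
        cov = network_coverage(bouts, net, config.match_params)
        net_rows.append({
            "group_id": gid,
            "total_length_m": round(net.total_length_m, 1),
            "habitual_length_m": round(net.habitual_length_m, 1),
            "n_segments": len(net.segments),
            "bout_coverage": round(cov, 4),
        })
        all_segments.extend(net.segments)
        log.info("  %s: %.1f km total, %.1f km habitual, coverage %.3f",
                 gid, net.total_length_m / 1e3, net.habitual_length_m / 1e3, cov)
    rio.write_network_geojson(
        RouteNetwork(all_segments, config.habitual_weeks), out / "network.geojson")
    pd.DataFrame(net_rows).to_csv(out / "network_summary.csv", index=False)

    log.info("stage 4/5: landscape & resource metrics")
    quadrat_frames, bc_rows, rate_frames, nn_rows = [], [], [], []
    for k, gid in enumerate(group_ids):
        hr = home_ranges[gid]
        net = networks[gid]
        gtrees = trees[trees["group_id"] == gid] if "group_id" in trees.columns \
            else trees
        others = [home_ranges[o].hr95 for o in group_ids if o != gid]
        q = quadrat_table(gid, hr.hr95, hr.core50, dem, gaps, net,
                          other_home_ranges=others,
                          cell_m=config.grid_cell_m,
                          gap_radius_m=config.gap_radius_m,
                          habitual_weeks=config.habitual_weeks,
                          highuse_weeks=config.highuse_weeks)
        q["ft_density"] = ft_density_column(q, gtrees, config.visual_radii)
        quadrat_frames.append(q)
        nn_rows.append({"group_id": gid,
                        "nn_z": nearest_neighbor_z(
                            gtrees[["x", "y"]].to_numpy(), hr.hr95)})
        if net.habitual():
            obs = trees_in_network_buffers(net, gtrees, config.network_radii)
            null = csr_null(len(gtrees), hr.hr95, gaps, net,
                            config.network_radii, n_sims=config.n_sims,
                            seed=np.random.default_rng(csr_streams[k]),
                            observed_counts=obs["observed_count"].tolist())
            null.insert(0, "group_id", gid)
            bc_rows.append(null)
        rates = segment_rate_table(net, gtrees, config.network_radii)
        rate_frames.append(rates)
    quadrats = pd.concat(quadrat_frames, ignore_index=True)
    quadrats.to_csv(out / "quadrats.csv", index=False, float_format="%.6f")
    buffer_counts = pd.concat(bc_rows, ignore_index=True) if bc_rows \
        else pd.DataFrame()
    buffer_counts.to_csv(out / "buffer_counts.csv", index=False,
                         float_format="%.4f")
    segment_rates = pd.concat(rate_frames, ignore_index=True)
    segment_rates.to_csv(out / "segment_rates.csv", index=False,
                         float_format="%.6f")
    pd.DataFrame(nn_rows).to_csv(out / "tree_clustering.csv", index=False,
                                 float_format="%.3f")

    log.info("stage 5/5: mixed models")
    results = run_core_models(buffer_counts, segment_rates, quadrats,
                              exclude_group=config.exclude_group,
                              D_grid=config.d_grid)
    report = results["report"]
    report.to_csv(out / "models_report.csv", index=False, float_format="%.6f")
    summary = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": routescape.__version__,
        "groups": net_rows,
        "D_route_ge2": results.get("D_route_ge2"),
        "D_route_ge4": results.get("D_route_ge4"),
        "lrt_full_null": {k: v for k, v in results["lrt_full_null"].items()
                          if v is not None},
        "drop1": {k: v.to_dict(orient="records")
                  for k, v in results["drop1"].items()},
    }
    (out / "models_report.json").write_text(json.dumps(summary, indent=2,
                                                       default=float))
    log.info("done: %s", out)
    return out
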