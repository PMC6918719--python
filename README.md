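# routescape

Habitual route networks, food-tree visibility and landscape models for
group-living arboreal animals.

Many arboreal mammals — howler monkeys are the motivating case — do not
roam freely through their home range but travel along a network of
re-used arboreal pathways. `routescape` is a Python toolkit for the full
analysis chain behind that observation: given GPS fixes of group travel
bouts (a fix every ~20 m), locations of food-tree stems, an elevation
raster and canopy-gap polygons, it

1. estimates kernel-density home ranges (95% isopleth) and core areas
   (50% isopleth) from scan-sample fixes;
2. reconstructs the **habitual route network**: daily paths that run
   within 10 m of each other for at least 15 m without deviating more
   than 45° are the same travel segment; segments used in ≥ 2 distinct
   sampling weeks are habitual, and every segment carries its count of
   distinct weeks of use;
3. tests whether food trees (FTs) cluster along routes by comparing
   observed FT counts in 5–20 m network buffers with a complete-spatial-
   randomness (CSR) Monte Carlo null of the same number of stems placed
   uniformly in the home range outside canopy gaps;
4. computes per-quadrat (10 × 10 m) landscape covariates — slope
   (8-neighbor maximum gradient), relative elevation, 25 m canopy-gap
   cover — and the **FT-density index**, a proxy for visual access to
   food: cumulative FT counts in buffers of 5, 10, …, 35 m around the
   quadrat center, summed, divided by 7 and by the total FTs in the home
   range (each tree at distance d contributes (#radii ≥ d)/7/total);
5. fits mixed models for route placement: Gaussian LMMs for buffer counts
   (real vs simulated locations) and log FTs-per-meter vs usage
   frequency, and binomial GLMMs (Laplace ML, random intercept +
   uncorrelated random slopes per group) for quadrat-level route presence
   — `presence ~ sqrt(slope) + gap presence + elevation × FT density +
   overlap + core + autocorrelation term` — where the autocorrelation
   term for observation *i* is the Gaussian-kernel weighted average
   `Σ_j exp(−d²_ij/2D²) e_j / Σ_j w_ij` of the other same-group
   residuals, with kernel SD *D* optimized on a grid to maximize the
   full-model log-likelihood; inference is by likelihood-ratio tests with
   marginality-respecting single-term deletions.

Field datasets of this kind are rarely public, so the package includes a
first-class synthetic-data generator (`routescape.synthetic`) that plants
known ground truth — route geometry with per-segment week multiplicities,
CSR or route-biased tree placement, logistic regression coefficients —
and the test suite verifies that each stage recovers what was planted,
including under the realistic 6.6 m GPS fix error.

## Worked example

```python
from routescape.synthetic import SyntheticConfig, generate_scenario
from routescape.pipeline import RunConfig, build_group_network
from routescape.resources import trees_in_network_buffers, csr_null

cfg = SyntheticConfig(seed=42, n_groups=1, extent=(0, 0, 450, 450),
                      n_weeks=8, n_trees=140, route_nodes=10)
scenario = generate_scenario(cfg)
group = scenario.groups[0]

net = build_group_network(group.tracks, RunConfig(), group_id=group.group_id)
print(f"network: {net.total_length_m/1e3:.2f} km total, "
      f"{net.habitual_length_m/1e3:.2f} km habitual "
      f"({len(net.habitual())} segments used in >= 2 weeks)")

obs = trees_in_network_buffers(net, group.trees)
null = csr_null(len(group.trees), group.home_range, scenario.gaps, net,
                n_sims=1000, seed=1,
                observed_counts=obs.observed_count.tolist())
print(null.round(3).to_string(index=False))
```

prints

```
network: 2.76 km total, 1.42 km habitual (136 segments used in >= 2 weeks)
 buffer_m  sim_mean  sim_sd  observed_count  exceedance_frac
      5.0    14.275   3.490              16            0.367
     10.0    23.563   4.314              27            0.255
     15.0    31.951   4.898              37            0.173
     20.0    40.167   5.275              44            0.255
```

One sampled group's eight weeks of noisy travel bouts rebuild into a
2.76 km network of which 1.42 km was used in at least two separate weeks.
The CSR null then asks: of 1,000 random relocations of the 140 stems,
what fraction intercepts at least as many trees as observed within each
buffer of the habitual network? Here the trees were planted spatially at
random, and the exceedance fractions (0.17–0.37) are correctly
unremarkable; trees planted along routes drive them below 0.05.

## Command line

```
routescape all --config run.toml --seed 42 --out results/
```

runs every stage (synthetic or real-data mode per the TOML config) and
writes `tracks.csv`, `trees.csv`, `gaps.geojson`, `dem.asc`,
`homeranges.geojson`, `network.geojson`, `quadrats.csv`,
`buffer_counts.csv`, `segment_rates.csv`, `models_report.csv/json` and a
seeded run log. `synth`, `homerange`, `network`, `metrics` and `models`
rerun individual stages from a data directory. Outputs are byte-identical
for a fixed config and seed.

## Method notes

See [docs/methods.md](docs/methods.md) for the model assumptions, the
numerical choices (bandwidths, smoothing, tie-breaks, zero handling),
what the generator does and does not emulate, and known limitations.
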