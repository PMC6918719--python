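# Methods

`routescape` reconstructs habitual route networks from repeated GPS travel
bouts of group-living arboreal animals, quantifies visual access to food
trees along those networks against a spatial-randomness null, extracts
landscape covariates on a quadrat grid, and fits autocorrelation-controlled
mixed models for route placement. Because typical field datasets of this
kind are not public, the package ships a synthetic-data generator that
plants known ground truth (route geometry, per-segment usage weeks, tree
placement, regression coefficients), so every stage of the chain is
verifiable end to end.

All computation is in planar projected meters (x east, y north). Coordinate
reference system handling is deliberately out of scope: whatever produced
the input CSVs is responsible for projecting to a metric CRS.

## Movement and landscape generator

The generator emulates a Neotropical forest study system: five-ish social
groups with ~7–15 ha home ranges, ~130–230 marked food-tree stems per
range, terrain spanning 65–264 m a.s.l., canopy gaps near 7% of the area,
group-centre GPS fixes every 20 m with 6.6 m error, travel bouts averaging
65.3 m (SD 57.5 m), and groups sampled in discrete weeks separated by
multi-week gaps.

**Elevation** is a smoothed Gaussian random field: white noise filtered
with a Gaussian kernel (default 60 m), min–max rescaled into the elevation
range. Only the range/smoothness contract matters downstream (slope and
relative elevation), not the spectral details.

**Canopy gaps** are elliptical blobs with Dirichlet-distributed areas,
placed uniformly and rescaled iteratively until the clipped union covers
the requested fraction of the extent within 20%.

**Route graphs** are Euclidean minimum spanning trees over random nodes
inside the home range, plus a few short chords to create loops, with gentle
perpendicular midpoint jitter so edges are not perfectly straight. Each
edge carries a planted multiplicity: the number of distinct sampling weeks
in which the group travels it, drawn right-skewed over 1–7 so that roughly
two thirds of planted length is habitual (≥ 2 weeks).

**Travel bouts.** Each edge is assigned exactly `multiplicity` distinct
weeks. Within a scheduled week, consecutive on-graph bouts cover the edge
end to end, so planted usage is realized exactly; leftover bout budget is
spent walking onward over this week's scheduled edges (doubling back at
dead ends). Independently, each remaining bout is on-graph with probability
`route_fidelity` (default 0.75) and otherwise a correlated random walk
(5 m steps, wrapped-normal turning angles, SD 40°, steered back at the
home-range boundary). The group repositions between bouts without recording
travel — in the field, bouts are separated by stationary activities, and
the generator does not simulate the unrecorded interludes. Free on-graph
walks are restricted to the week's scheduled edges: allowing them anywhere
would silently raise realized usage above the planted multiplicities and
destroy the ground truth that the recovery tests depend on.

True bout lengths are log-normal with moments matched to the GPS-measured
targets (mean 65.3 m, SD 57.5 m). Because summing noisy fix-to-fix
distances inflates measured length, drawn true lengths are deflated by the
expected inflation factor `sqrt(1 + 2.5 (σ/Δ)²)` (σ = fix noise SD, Δ =
20 m fix spacing; the constant was calibrated against the generator's own
realized lengths), so the *realized noisy* lengths match the target mean.
Fixes are laid every 20 m of arc length along the true path and then
perturbed with isotropic Gaussian noise, per fix, independently.

**Scan fixes** for home-range estimation are a 55/45 mixture of
uniform-in-range and Gaussian-around-the-centroid points (utilization is
center-weighted in range-resident groups), plus fix noise. With the
reference-bandwidth KDE below, this produces 95% isopleth areas within
~±10% of the planted range area; a purely uniform utilization would be
oversmoothed to ~+20%.

**What the generator does not emulate:** feeding bouts and diet, group
fission/fusion, temporally autocorrelated GPS error, canopy structure,
route emergence over time. Passing tests therefore demonstrate that the
*pipeline* recovers planted structure under idealized recurrence and
isotropic noise — not that any particular field system behaves this way.

One RNG stream per component (DEM, gaps, per-group routes/trees/bouts/
scans) is spawned from the master seed, so partial reruns reproduce.

## Home ranges

Bivariate Gaussian KDE on scan fixes with the isotropic reference
bandwidth `h = σ·n^(-1/6)`, `σ² = (var(x)+var(y))/2`, evaluated on a 5 m
grid padded 3 bandwidths beyond the data. An isopleth at mass q is the
smallest-area set of grid cells containing fraction q of total density;
its polygon is the union of those cells, with no smoothing, so the reported
area is exactly the cell-count area. The home range is the 95% isopleth and
the core the 50% isopleth; nesting holds by construction.

## Route networks

Paths are resampled to ≤ 1 m vertex spacing (original corner vertices are
retained so length is conserved exactly) and smoothed with a centered 60 m
moving average with reflection padding. Smoothing controls per-fix GPS
jitter: without it, two traversals of the same route with 6.6 m fix noise
match the 10 m buffer / 45° rule on only ~70% of their length; with it,
~92%. The 60 m window (three fix spacings) was chosen as the smallest
window that brings pairwise matching above 90% without visibly cutting
corners at route bends.

**Recurrence rule.** A vertex of path A matches reference geometry B when
its nearest B vertex lies within 10 m and the local bearings differ by at
most 45°, taken modulo 180° so direction of travel is ignored. Local
bearing is the direction across a centered 10 m window. Maximal runs of
matched vertices spanning ≥ 15 m are shared segments. With both paths at
1 m spacing, nearest-vertex distance equals nearest-point distance to
within 0.5 m, far inside the 10 m buffer; a brute-force all-pairs matcher
is kept in the tests as the oracle for this equivalence.

**Weekly paths.** Within each sampling week, daily/bout paths are
deduplicated in day order: portions of a later path that retrace already
retained geometry for ≥ 15 m are dropped (earlier geometry is the
representative). This prevents short revisit intervals within a week from
inflating usage counts.

**Accumulation.** Weeks are folded chronologically into the network. A
week's paths are matched against the current network's representative
geometry; matched portions add that week to the touched segments' week
sets (at most once per week), unmatched portions become new segments.
Segments split wherever the within-week usage mask changes, with adjacent
pieces sharing their boundary vertex so partition length is conserved.

**Consolidation.** GPS noise leaves near-parallel copies of a route in the
network, with usage weeks scattered across the copies. Any two segments
that themselves satisfy the recurrence rule (within 10 m, ≤ 45°, ≥ 15 m)
are by definition the same route, so a final pass unions their week sets
on the matched stretches and re-splits. Segment endpoints are not snapped
to a grid: with 1 m resampled vertices and index-based splitting, snapping
is unnecessary and would break exactness tests at zero noise.

The habitual network is the set of segments used in ≥ 2 distinct weeks
(≥ 4 for the high-use network). A travel bout "falls within" the habitual
network when ≥ 50% of its vertices match habitual geometry under the same
rule; the 50% threshold is a package choice, as the underlying bout-level
notion is not standardized.

## Landscape quadrats

A 10 × 10 m grid is anchored at the floor of the home-range bounds; cells
whose centers fall inside the range are kept. Elevation is bilinear at the
cell center; relative elevation subtracts the group minimum (the covariate
passed to models — raw elevation is retained for reporting). Slope is the
8-neighborhood maximum rate of change, `atan(max |Δz|/distance)` with 10 m
orthogonal and 10√2 m diagonal distances; edge cells use the neighbors
they have. Gap cover is the percent of a 25 m disc around the center
overlapped by gap polygons. Route presence (≥ 2 and ≥ 4 weeks) is a closed
intersection test between the cell square and habitual segments — touching
the boundary counts. Cells inside several home ranges appear once per
group with `overlap_flag = 1`; `core_flag` marks cells in the 50% core.

## Resource metrics

Distances from points to the network are measured to polylines densified
at 0.5 m (error < 1 cm at the 5–35 m radii used); thresholds are closed
(a tree exactly at distance r counts as inside), consistently everywhere.

* **Buffer counts:** trees within 5/10/15/20 m of *any* habitual segment,
  each tree once per radius (union, no double counting).
* **CSR null:** the same count for n trees placed uniformly in the home
  range minus gaps (rejection sampling from the bounding box), repeated
  `n_sims` times (default 10,000). The exceedance fraction is the share of
  simulations with a count ≥ observed; small values mean the observed
  trees are closer to routes than chance. Note that when home ranges are
  KDE-estimated, oversmoothing enlarges the null's sampling region
  relative to where trees actually stand, which biases the null mildly
  toward "enrichment"; the calibration tests therefore plant trees and the
  null in the same region.
* **Trees per meter:** per segment × buffer radius, trees within the
  radius divided by segment length; segments shorter than 15 m are skipped
  (endpoint-dominated rates).
* **Food-tree density (visual access) index:** per quadrat center, trees
  within each of the 7 radii 5, 10, …, 35 m are counted cumulatively
  (trees in small buffers recount in every larger one — this weights trees
  near the center), the 7 counts are summed, divided by 7 and by the total
  trees in the home range. Equivalent per-tree weight: a tree at distance
  d ≤ 35 contributes `(number of radii ≥ d)/7/total`. 35 m is the assumed
  maximum distance at which a howler can visually inspect a tree.
* **Clark–Evans Z:** `(d̄_obs − 0.5/√(n/A)) / (0.26136/√(n²/A))`, no edge
  correction. Without correction the statistic carries a positive boundary
  bias (~+0.85 under CSR in a square window at n = 64–500); the tests
  assert this truthful calibration rather than an idealized N(0, 1).

## Mixed models

Three models mirror the analysis chain:

1. `N trees ~ location type (real vs simulated mean) + buffer size`,
   Gaussian LMM.
2. `log(trees per meter) ~ weeks used + buffer size`, Gaussian LMM. Zero
   rates get `log(half the minimum positive rate)`; row exclusion is
   available as an alternative.
3. `route presence (≥2 / ≥4 weeks) ~ sqrt(slope) + gap presence +
   rel. elevation × FT density + overlap + core + autocorrelation term`,
   binomial GLMM with logit link, fitted separately per threshold.

All models include a random intercept and *uncorrelated* random slopes per
group (the `||` structure). Gaussian models are fitted by ML (not REML, so
likelihood-ratio tests are valid) through statsmodels MixedLM with
variance components for the slopes; the Powell optimizer is used because
gradient methods misbehave at the zero-variance boundary. Binomial models
are fitted by Laplace-approximate ML implemented in this package: for
fixed variance parameters the joint mode of (β, u) is found by penalized
Newton iterations with step halving; the Laplace marginal log-likelihood
(joint log-density at the mode minus half the log-determinant of the
random-effects Hessian block) is maximized over the log-SDs by Powell
search; Wald SEs come from the observed-information block inverse. The fit
matches lme4's `glmer` to ~3 decimal places in coefficients and
log-likelihood on shared test data, and `glmer` is retained in the test
suite as the independent oracle. Fits that fail to converge, or show
separation (|β| > 25 or non-finite SEs), are flagged and refused by
downstream inference.

Continuous covariates are z-standardized by default (binary flags and the
autocorrelation term are left raw); raw mode is available. Interactions
are products of the (standardized) main-effect columns and must appear
with their main effects.

**Autocorrelation term.** For observation i, the Gaussian-kernel
distance-weighted average of the *other* same-group residuals:
`ac_i = Σ_{j≠i} w_ij e_j / Σ w_ij`, `w_ij = exp(−d²_ij/(2D²))`, computed
from the model fitted without the term (response minus fitted mean, with
predicted random effects included). The focal point is excluded from its
own average — self-inclusion would leak the residual into the covariate.
Singleton groups get 0. The kernel SD D is chosen on a 1–30 m unit grid
(ties to the smallest D) to maximize the refitted full-model
log-likelihood; a grid is used instead of continuous optimization because
the profile is noisy and the grid is reproducible. The term is computed
once from the base fit's residuals (no residual–term–refit iteration); on
fields simulated with a 6 m kernel the selected D concentrates at 3–5 m.

**Inference.** Full vs null (controls + random effects only) comparison by
likelihood-ratio χ², df = difference in parameter count (fixed + variance
parameters). Per-term tests follow single-term deletions with marginality
respected: the interaction is tested first, and a main effect is never
dropped while its interaction is in the model. 95% intervals are Wald.
With ≤ 5 groups, random-effect variances are weakly identified; this is
inherent to small-cluster mixed models and is why non-convergent fits are
flagged rather than silently reported.

## Problem sizes

The shipped test suite and the reproduction script run reduced but
structurally complete problems: 2–3 groups, 6–8 sampling weeks, 100–140
trees per group, CSR nulls of 200–2,000 simulations, model-recovery runs
of 200 replicates at 5 × 2,000 quadrats, LRT calibration at 1,000
replicates, and D-grid searches over 1–30 m. The defaults in
`SyntheticConfig` and `RunConfig` (5 groups, 20 weeks, 10,000 simulations,
unit D grid) reproduce the full study conditions.

## Known limitations

* The recurrence rule conflates geometrically convergent routes at shallow
  junction angles (< 45°); usage counts near junctions can mix.
* Usage counts are path-recurrence counts, not traversal counts: several
  traversals within one week count once by design.
* The CSR null inherits any bias in the home-range polygon (see above).
* The Laplace approximation is known to bias variance components downward
  with few clusters; fixed-effect estimates are much less affected.
* No viewshed computation: "visual access" is the 2-D buffer index, not
  line-of-sight over terrain or through canopy.
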