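# Methods

This note records the models, conventions, parameters and deliberate design
choices behind the package, in the order the pipeline runs them.

## Spatial model

All computation happens on flat, north-up, square-cell grids
(`GridSpec`). The CRS is an opaque string used only to assert that inputs
belong together: the package never reprojects. Real-world use therefore
requires projecting all inputs to one planar CRS (e.g. a Lambert conformal
conic) beforehand; the synthetic scenes are generated directly on a
projected plane in meters.

Cell ownership is half-open: cell (row, col) owns
`[x0, x0+cs) × (y0−cs, y0]` from its top-left corner, and indices come from
flooring offsets from the grid origin. A point exactly on a vertical edge
belongs to the right-hand cell, one on a horizontal edge to the cell below,
and the top edge of the grid is included. This removes every boundary
ambiguity from point extraction, turbine binning and buffer membership.

NoData propagates: any NoData input cell yields NoData output in every
raster operation, and excluded ground in the siting map is NoData rather
than score 0, so excluded areas can never masquerade as merely "low
suitability".

Two grids are used by default: a 1-km habitat-modeling grid and a 300-m
siting grid over the same extent. Where the two meet (conflict maps),
habitat classes are regridded to the siting grid by nearest-neighbor — an
explicit interpretation, since nothing forces a unique reconciliation.

## Synthetic landscapes

Continuous fields are white noise convolved with a uniform disk kernel of
radius `autocorr_len` cells (default 6), standardized, then affinely
rescaled to a per-variable mean and spread chosen to look like seasonal
climate layers (temperature 16 ± 7 °C, solar radiation 15,000 ± 4,000
kJ m⁻² day⁻¹, vapor pressure 1.2 ± 0.45 kPa, wind speed 4.5 ± 1.6 m s⁻¹,
precipitation 55 ± 30 mm). The disk kernel buys spatial autocorrelation
cheaply; no Gaussian-process covariance is claimed. Each season mixes a
shared spatial component with season-specific noise (weight 0.5), so
seasonal layers differ but correlate, as real climate normals do. Land
cover is a smoothed field quantile-sliced into k = 5 equal-area classes.

Ground truth is a logistic surface over z-scored variables,
`σ(logit(τ) + Σ c_f · feature_f)`, with linear, squared and product
features available. The default truth has three nonzero linear
coefficients (temperature +1.6, vapor pressure +1.1, precipitation −0.9),
enough structure for parameter-recovery tests without making the problem
trivially separable. Presences are sampled at cell centers with
probability proportional to truth, *with replacement*, so exact duplicate
coordinates occur and the occurrence-cleaning stage has genuine work.

Raw occurrence records add realistic contamination: ~15% human
observations, years drawn wider than the 1970–2020 window, and ~4% missing
months. Turbines are sampled with probability ∝ exp(bias × wind power
class), bias 0.8, so they concentrate where a real build-out would.

What the generator does **not** emulate: geographic coordinate systems and
geodesic distances, sampling bias fields (roads, museums), observation
error in coordinates, temporal non-stationarity, and realistic land-cover
geometry. Passing tests therefore demonstrate that the algorithms are
correct and the pipeline recovers known structure under its own
assumptions — not that any particular real-world dataset would yield good
models.

## Occurrence cleaning

Filters keep records with year in [1970, 2020] (inclusive) and
basis-of-record equal to "preserved specimen" after normalizing case,
spaces and underscores. Records missing year or month are dropped (the
seasonal split needs months); counts removed by each rule are logged.
Seasons are meteorological: Mar–May, Jun–Aug, Sep–Nov, Dec–Feb.
Deduplication and thinning run within season, not on the pooled set.

Spatial rarefaction is greedy: repeatedly remove the record with the most
neighbors closer than the window (10 km default), breaking ties with a
seeded uniform draw, until no violating pair remains. The *postcondition*
is the contract — every retained pair is ≥ window apart, verified
brute-force in tests — and the heuristic is merely one conformant
algorithm. It is idempotent for a fixed seed, and retained-set size is
non-increasing in the window. Distances are Euclidean on projected
coordinates (meters) or haversine on degrees; the metric is the caller's
declaration, since occurrence files do not carry it.

## Maximum-entropy model

Features: continuous variables are min-max scaled to [0, 1] with bounds
from the training sample (presences ∪ background); evaluation values
outside the bounds are clamped before scaling. LQP expansion: one linear
and one quadratic feature per variable and one product per distinct pair;
categorical variables expand to one indicator per observed class.
Zero-variance variables are dropped with a warning.

The fit maximizes the penalized training gain J(λ) given in the README.
Per-feature penalties are `β_j = rm · c(kind) · max(sd_j, ε)/√m` with the
feature's presence-sample standard deviation, a single base constant per
feature class (1.0) and variance floor ε = 1e-3. This preserves the
qualitative regularization mechanism (penalties shrink with sample size,
scale with feature spread, and are tuned by one multiplier) without
reproducing any reference tool's interpolation tables; everything is
configurable.

Solver: cyclic coordinate descent. Each coordinate takes a Newton step on
the smooth part (gradient `g_j = presence mean − background expectation`,
curvature = background variance of the feature), soft-thresholds against
β_j, and backtracks on the exact 1-D penalized gain so steps never
overshoot. Convergence is declared on the KKT residual: `|g_j| ≤ β_j + tol`
for zero coefficients and `|g_j − sign(λ_j)β_j| ≤ tol` otherwise, with
tol = 1e-6. Non-convergence within `max_iter` (default 1000 sweeps)
returns a flagged fit with a warning, never silently. Note that complete
separation (presence feature values beyond everything in the background)
makes the penalized gain unbounded whenever β is smaller than the
unreachable gradient gap; this is a property of the model, and such fits
come back flagged.

Output scales: `raw` sums to 1 over the training background;
`H = −Σ raw·log raw` is the fitted distribution's entropy; logistic output
is `raw·e^H / (1 + raw·e^H)`, the prevalence-0.5 transform, so a
featureless model scores exactly 0.5 everywhere. Thresholding and habitat
classes operate on the logistic scale.

Model selection: AICc computed from raw values renormalized over an extent
sample (the training background by default), with k = number of nonzero
coefficients; undefined (and excluded) when k = 0 or k ≥ m − 1. The rm
grid is 0.5, 1.0, …, 5.0 — it starts at 0.5 rather than 0 because an
unpenalized fit can diverge under separation; ties go to the smaller rm.

Evaluation: AUC is the rank-based (Mann–Whitney) probability that a random
presence outscores a random background point, ties counting ½; it equals
all-pairs enumeration exactly. Cross-validation partitions presences into
k = 5 seeded random folds against the shared background. Variable
contributions are permutation importance: each variable's derived feature
columns (products count for both parents) are jointly row-permuted 10
times, the mean drop in training AUC is floored at zero and normalized to
percentages. Response curves come from univariate models (linear +
quadratic, or indicators) at rm = 1. The collinearity screen reports
pairwise Pearson r at the background sample and flags |r| ≥ 0.7 without
dropping anything — flagged pairs are for the analyst.

## Habitat classes

The r-omission threshold is the (⌊r·m⌋+1)-th smallest training
suitability, so at most ⌊r·m⌋ training presences fall strictly below it;
it is deterministic under ties. With rates 0.10 and 0.50 the classes are
`s < t_low` unsuitable, `t_low ≤ s < t_high` low-to-moderate, `s ≥ t_high`
high — half-open boundaries chosen so the classes are exhaustive and
monotone in suitability. Thresholds are computed on the thinned training
presences, not on held-out points, and are recorded in a JSON sidecar next
to each classified raster.

## Siting multi-criteria overlay

Composite score = Σ weight × criterion score, weights {wind power class 3,
distance to roads 2, distance to transmission lines 2, land cover 2, slope
2, population density 1}, each criterion reclassified to 0–4, giving 0–48.
The shipped reclassification tables (distance bands favoring proximity,
slope bands favoring flat ground, population bands favoring sparse
settlement, a 1–7 → 0–4 wind-class map, and land-cover scores spread 4→0
across the observed classes) are documented configuration defaults in the
style of published GIS siting studies — every breakpoint is overridable
and none is asserted as ground truth. Band tables are half-open [lo, hi);
a value on an interior breakpoint takes the upper bin; values outside a
table's coverage are an error listing the offenders.

Exclusion (military and protected polygons, points within 1 km of an
airport) is a union mask applied as NoData. Class bounds are inclusive
integers: 0–16 low, 17–32 moderate, 33–48 high. The
`turbine_score_quantile` operation reports the fraction of turbines on
valid cells with score strictly below a cutoff, so users can check a
turbine-distribution-derived threshold on their own data.

## Overlap products

Impact classes per turbine: unsuitable → unlikely, low-to-moderate →
moderate, high → high, NoData or off-grid → off-map; percentages use the
total supplied turbine count as denominator and off-map turbines are shown
explicitly, so each season's row sums to the turbine count. The turbine
loader requires capacity strictly greater than 65 kW and rotor strictly
greater than 30 m, skipping a filter (with a warning) for records missing
that attribute.

Conflict classes exist only on high-siting cells: high habitat → high
potential conflict, low-to-moderate → low, unsuitable → minimum; all other
cells are "none". Roost buffers use direct point-to-roost distances
(≤ 100 km) rather than discretized buffer polygons — equivalent for
membership tests and free of polygon-segmentization error; pooled counts
use the union of buffers.

## Problem sizes and determinism

The documented study configuration is a 100 × 100 habitat grid (1-km
cells), four seasons, ~150 raw records per season, 10,000 background
points and the full 10-candidate rm grid; the complete pipeline runs in
well under a minute on one CPU. The test suite uses smaller but complete
configurations (e.g. 50-km scenes, 2 seasons, 800 background points) for
the end-to-end determinism check, and the spec-scale recovery checks
(100 × 100, m = 500, B = 5,000) in the acceptance suite. Every random
stage has its own named seed in the config; the provenance manifest
records the config hash, seeds, selected multipliers and thresholds, and
two runs from one config produce byte-identical tabular outputs.

## Known limitations

- No reprojection, geodesic math or multi-band rasters; all inputs must
  share one planar CRS.
- AICc normalization extent defaults to the training background; a
  full-extent variant is a config switch, and the choice shifts absolute
  AICc values (not usually the argmin).
- Permutation importance is not the same attribution as training-gain
  "percent contribution" heuristics in reference tools; numbers are
  comparable in spirit, not digit-by-digit.
- Presence-background test AUC is bounded well below 1 when a large
  fraction of the landscape is genuinely suitable; small training sets
  after 10-km thinning (tens of points) make seasonal AUCs noisy.
- The greedy thinning heuristic maximizes nothing; it only guarantees the
  distance postcondition.
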