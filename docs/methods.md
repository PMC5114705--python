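# Methods

## Scope and data model

The pipeline estimates the climatically suitable range of a species from
presence-only records and gridded environmental layers, then measures how
that range moves under projected future climates. All grids are
unprojected lon/lat, cell-edge registered with row 0 northernmost, and
share one nodata rule: a cell masked in any layer is excluded everywhere
(a model needs all of its predictors). Supported raster dialects are ESRI
ASCII grid (text, used for fixtures) and single-band GeoTIFF; the extent is
cropped to the smallest cell-aligned window containing a requested
bounding box. Cell areas are true spherical-zone areas,
`A = R² Δλ (sin φ_N − sin φ_S)` with R = 6371 km, so area totals are exact
on the sphere rather than nominal per-cell constants; a 2.5-arc-minute
cell at the equator is ≈ 21.47 km², not the nominal 25 km² sometimes used
as shorthand for that resolution.

A point exactly on a cell edge belongs to the cell to its north-west
(ceil − 1 on both axes). This is arbitrary but deterministic, and the
within-cell jitter in the synthetic generator exercises it.

## Occurrence preparation

Cleaning removes records with non-finite or out-of-range coordinates,
exact duplicate (species, lon, lat) rows (first kept), records outside the
stack extent and records in masked cells, tallying removals per reason.
Thinning keeps at most one record per analysis-grid cell to blunt
spatially clustered sampling effort; within a cell the record that sorts
first by (source id, lon, lat) is kept — fully deterministic and
idempotent — with a seeded uniform choice available as an alternative.
Cleaning precedes thinning on the combined record set.

## The maximum-entropy model

Features per scaled variable v ∈ [0, 1] (scaling bounds frozen from the
training background): linear v, quadratic v², products v_a·v_b per
unordered pair, and hinge pairs max(0, (v−t)/(1−t)) and max(0, (t−v)/t)
with knots at equally spaced background quantiles (5 per variable by
default; knots falling on 0 or 1 are dropped since the corresponding
feature would be degenerate). When projecting onto new layers the scaled
values are clamped to [0, 1] by default (extrapolation control; a switch
turns it off for sensitivity analysis).

The penalty weights are βⱼ = r·sⱼ/√m with sⱼ the presence-sample standard
deviation of feature j (population form, ddof = 0), floored at 1e-6·r.
A single global multiplier r (default 1.0) replaces per-feature-class
interpolation tables: one tunable knob, and the training gain is provably
non-increasing in it. The objective is maximized by splitting λ into
non-negative parts and running L-BFGS-B (box constraints make the split
problem smooth); the result is accepted only if the L1 subgradient
conditions hold within tol (default 1e-6, iteration cap 10,000), with one
automatic tighter-tolerance restart before a convergence error is raised.
Coefficients below 1e-12 are snapped to zero so the split parametrization
cannot leave both halves active.

Background = all unmasked cells when there are ≤ 50,000, otherwise a
seeded uniform sample of 10,000 — the convention of presence-background
modelling tools. Entropy H is computed over the defining background, and
the logistic suitability q·e^H/(1 + q·e^H) keeps the "typical training
cell scores 0.5" interpretation (prevalence parameter at its conventional
0.5). Gain is the unpenalized mean log-ratio against the uniform model,
(1/m) Σ ln(q(xᵢ)·N_b).

## Model selection

Screening fits one single-variable model per candidate (gain in
isolation) and one drop-one model (omission gain drop = full-model gain −
drop-one gain), retaining the union of the top-4 variables on each
criterion (both configurable). The collinearity filter then greedily
removes, from every pair with |Pearson r| strictly above 0.8 over the
background (pairs visited in descending |r|, ties by name), the member
with the lower isolation gain; constant variables drop first with reason
"zero variance".

Every non-empty subset of the survivors (capped at 12 variables) is fit
and scored. The AICc likelihood uses the raw output renormalized over all
unmasked landscape cells — the convention under which published AICc
values for these models are produced — with n the thinned presence count
and k the number of coefficients with |λ| > 1e-9 (the lasso effective-
parameter convention). Subsets with k ≥ n − 1 are flagged invalid; Akaike
weights exp(−Δ/2)/Σ exp(−Δ/2) are computed over all valid scored models.
Because published comparison tables typically show only models within a
few units of the best, printed weights (which sum to < 1) are not
reproduction targets; the weight *ratios* and ΔAICc values are.

Cross-validated AUC deals shuffled presences round-robin into 10 seeded
folds, refits on each training remainder, and scores held-out presences
against the shared background using the normalized Mann–Whitney U (ties
0.5). AUC is invariant to any strictly monotone transform of scores, so
raw and logistic outputs give identical values — asserted in tests.

## Projection and ensembles

Projection recomputes features with the training scaling bounds (clamped),
renormalizes the raw mass over the projection landscape, and applies the
logistic transform with the training entropy frozen. Renormalizing
per-landscape keeps the mass a proper distribution on any extent;
freezing H keeps suitability values comparable across landscapes.
Averaging across GCM members acts on logistic suitability (the mapped,
bounded quantity), cell-wise with equal weights, mask = union of member
masks. Whether one should average before or after the logistic step is
genuinely open; averaging the mapped suitability is this package's choice
and the off-switch on clamping plus raw outputs allow the alternative to
be evaluated.

## Range metrics

Suprathreshold area sums spherical cell areas over cells with suitability
strictly above τ = 0.5 ("> 50%"). Percent change is (future −
current)/current × 100 and is undefined (an error) for a zero current
area. Retention is the area suprathreshold in both maps divided by the
current suprathreshold area. The centroid is the suitability-weighted
mean of cell-center unit vectors on the sphere — weights suitability ×
cell area over ALL unmasked cells, not only suprathreshold ones, so a
projection whose highly suitable range vanishes still has a well-defined
centroid (ranges that collapse to zero area still produce centroid
displacement rows). Displacement is the haversine distance between
current and future centroids, direction the initial great-circle bearing
binned into 16 compass winds (sector boundaries at 11.25° + k·22.5°), and
the rate divides by decades elapsed from a 2010 baseline (4 for 2050, 6
for 2070), rounding half away from zero to an integer. Published tables
of this quantity round exact .5 values inconsistently in both directions,
so agreement checks count a row as reproduced when the unrounded rate is
within the half-unit rounding tie of the printed integer. Cross-scenario
medians are sample medians (mean of the two middle order statistics for
even counts) over all species × scenario rows.

## Synthetic landscapes

The generator emulates the structure of the real inputs, not their
climatology. Layers are deterministic trends in latitude and a generated
elevation surface plus a seeded smooth Gaussian random field (low-order
spectral synthesis: the first few 2-D Fourier modes with squared-
exponential amplitude decay, normalized to unit variance). Designated
layer pairs are re-mixed against each other to hit a target correlation,
exercising the |r| > 0.8 filter. The default configuration emulates the
full input surface (ELEV + 19 bioclim-like layers on an 80 × 80 half-
degree grid over lon [−120, −80] × lat [10, 50]); the driver-recovery
configuration uses one temperature-like and one precipitation-like true
driver plus three pure-noise decoys.

The true suitability is a Gibbs mass ∝ exp(η) with η a quadratic niche
polynomial in the scaled drivers, peaked at mid-range. The default
curvature (linear/quadratic coefficients 60/−60 for the temperature
driver, 30/−30 for precipitation) concentrates ~95% of the truth mass in
a band covering roughly a fifth of the scaled variable's range — a few
degrees of latitude, a regional-scale climatic envelope. Much flatter
niches leave presence feature moments nearly indistinguishable from the
background, in which case the L1 penalty correctly shrinks the fit toward
uniform; the recovery experiment is about a species with an actual
climatic signal. Presences are drawn with replacement proportional to the
truth mass and jittered uniformly within their cells (m = 300 by
default). Future members add a scenario shift δ = warming(RCP) ×
horizon-fraction(year) to the designated layers (warming strictly
increasing in RCP: 1.0 / 1.8 / 2.2 / 3.7 units; horizon fractions 0.6 for
2050 and 1.0 for 2070) plus seeded smooth noise scaled by σ_g = 0.3, with
11 members per scenario.

What passing the synthetic tests shows: the pipeline recovers known
drivers, tracks a known suitability surface, and propagates an imposed
directional climate shift into the expected centroid displacement. What
it does not show: realistic spatial sampling bias, observation error,
topographically coherent climate surfaces, or dispersal limits — results
on real data depend on those.

## Numerical choices and degenerate inputs

Log-sum-exp is used for every normalizer; the logistic transform is
computed in log space so extreme q·e^H cannot overflow. Constant
variables are dropped from feature expansion with a warning. The centroid
raises on all-zero suitability and on a resultant vector shorter than
1e-9 of the total weight (balanced antipodal mass). Empty occurrence
input cleans to an empty set with zeroed counts rather than erroring.
Model JSON serialization round-trips all floats exactly (repr-precision
doubles).

Problem sizes in the bundled experiments (80 × 80 grid, 300 presences,
31-subset exhaustive scoring with linear + quadratic features, 10
replicates) keep a full recovery run under ten seconds on one CPU while
leaving every statistical conclusion comfortably away from its threshold.

## Known limitations

- Only lon/lat, cell-edge-registered, single-band rasters; no
  reprojection or resampling.
- The β schedule is a single global multiplier, not per-class tuned; the
  absolute shrinkage differs from tools with interpolated per-class
  tables, so coefficient values (not rankings) differ across tools.
- Threshold features, categorical predictors, sampling-bias grids and
  spatially blocked cross-validation are out of scope.
- Akaike weights depend on the candidate set actually scored; comparisons
  against truncated published tables must use ΔAICc, not weights.
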