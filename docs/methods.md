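# Methods

## The presence/background model

`nichecast` fits the classic maximum-entropy species distribution
model: a Gibbs density q(x) = exp(λ·f(x))/Z over a background sample of
landscape cells, chosen so that feature expectations under q match the
presence sample, which is equivalent to minimising the L1-penalised
negative presence log-likelihood. The implementation is a batch convex
solver (monotone accelerated proximal gradient with backtracking);
λ starts at 0, iteration stops when the relative objective change
drops below 1e-6 (hard cap 5000 iterations, non-convergence raises
with the objective trace attached). The accelerated step falls back to
a plain proximal step whenever momentum would increase the objective,
so the recorded trace is non-increasing by construction.

Assumptions worth keeping in mind:

* presences are an unbiased sample from the species' occupancy density
  over the landscape (no detection or survey bias model);
* background cells stand in for the available environment; presence
  cells are included in the background (standard convention);
* environmental layers are continuous; categorical covariates are out
  of scope.

## Features and regularization

Variables are min–max scaled to [0, 1] on the background; constant
variables are excluded with a warning. Feature classes: linear,
quadratic, pairwise products, threshold steps and forward/reverse
hinges. Knots: 10 per variable for thresholds and 10 per hinge
direction, equally spaced in scaled (0, 1) — a fixed-knot design keeps
the design width bounded and the fit reproducible, at the cost of the
data-driven knot placement some implementations use.

Per-feature penalties are β_j = rm · β_class(m) · s_j / √m, where
s_j is the feature's background standard deviation, m the presence
count, and β_class interpolates {10: 1.0, 30: 0.6, 100: 0.5} on m for
linear/quadratic/product features, with constants 1.0 for threshold
and 0.5 for hinge features. The global multiplier rm is the tuning
knob exposed to model selection. During projection onto other
landscapes, scaled values are clamped to [0, 1] (no extrapolation).

Output scales: `raw` is the density itself (sums to 1 over the
training background); `cloglog` is 1 − exp(−e^H · q) with H the
entropy of the fitted density, the bounded scale used for zoning. For
the null model this is 1 − 1/e everywhere, which the tests assert as a
closed form.

## Model selection

Candidates form the full cross product of a regularization-multiplier
list and a feature-combination list (defaults: 40 log-spaced values
spanning [0.1, 40], and all 31 non-empty subsets of {L,Q,P,T,H} —
both configurable; duplicated grid entries are deduplicated). Each
candidate is scored by AICc = 2k − 2LL + 2k(k+1)/(n−k−1), where the
raw map is renormalised over all valid cells, LL sums the log
normalised scores at the presences, k counts weights with |λ| > 1e-8
and n is the presence count; candidates with n ≤ k+1 are invalid and
excluded. The minimum-AICc candidate is selected (delta.AICc = 0),
with ties broken by smaller k, then smaller rm, then lexicographic
feature combination.

Variable selection precedes model tuning in the scripted analysis:
variables with zero permutation contribution are dropped, then pairs
with Pearson |r| > 0.85 at the occurrence cells are resolved in
descending |r|, keeping the higher-contribution member (alphabetical
on ties). Processing pairs by descending |r| makes transitive chains
(A–B and B–C hot, A–C not) resolve deterministically.

## Variable importance

Percent contribution is a seeded permutation importance: a variable's
raw values are permuted jointly across presences and background
(5 permutations), every feature derived from it is recomputed, and the
drop in training gain (fixed weights, renormalised Z) is averaged,
truncated at zero, and normalised to sum 100. Path-based contribution
accounting as reported by sequential-update solvers depends on solver
order and is not reproducible with a batch solver, so permutation
importance is used throughout. Note that with strongly correlated
variables permutation importance can concentrate on whichever
correlate the sparse fit happened to select. The jackknife reports
training gains for with-only-v and without-v refits per variable
(2V + 1 gains); because gains are the unpenalised part of the
objective at penalised optima, the nested-model inequality
gain_without ≤ gain_full holds only up to a small regularization
slack, which the tests allow for.

## Thresholding, zoning, areas

The binarisation threshold P maximises sensitivity(t) + specificity(t)
over candidate thresholds t = all distinct observed scores, treating
background as pseudo-absence; scoring uses integer counts on a common
denominator so ties are exact, and the smallest maximiser is returned.
Classes: [0, P) unsuitable, [P, 0.33) poor, [0.33, 0.66) moderate,
[0.66, 1] most suitable; if P ≥ 0.33 the poor class is structurally
empty (logged). By default P is estimated once on the current-scenario
scores and reused for future projections (configurable to re-estimate
per scenario); reusing one P keeps scenario areas comparable on a
common scale.

Cell areas use spherical geometry on WGS84 longitude/latitude grids:
row area R²·Δλ·(sin φ_N − sin φ_S) with R = 6371.0088 km. Reports give
per-class areas in 10⁴ km², shares of the total suitable area, and
percent change against a baseline, rounded half-away-from-zero to two
decimals (printed with one decimal when the second is zero).

## Range-shift analytics

Overlaying two suitable/unsuitable masks yields
stable/expand/shrink/never cells with the exact conservation
identities |stable|+|shrink| = |current| and |stable|+|expand| =
|future|; change proportions are area-weighted with the denominators
the names imply (current area for stable and shrink, future area for
expand). Class transitions form a 4×4 area matrix whose marginals
equal the per-class areas of the two maps. The centroid of the most
suitable class is the cell-area-weighted mean of cell-center
coordinates (area weighting matches standard zonal-centroid practice;
suitability weighting would be an alternative). Displacements are
haversine distances with initial bearing from north and an 8-sector
compass word; distances are on the sphere, not a projected plane.

## The synthetic landscape

The generator produces what the pipeline needs to be testable without
external data: smooth Gaussian random fields (white noise smoothed by
an isotropic Gaussian kernel, reflecting boundaries), standardised and
then linearly mixed after an empirical orthonormalisation so requested
pairwise Pearson correlations are achieved exactly in sample; a known
generating niche (linear or unimodal log-density); presences drawn
from the true density and placed at cell centers so thinning and
extraction are exactly reproducible; and future stacks built by
additive per-layer offsets.

Default study conditions: a 100×100-cell window of 0.05° cells in the
subtropics, 8 layers with two pairs at r = 0.9, a unimodal two-driver
niche (weights 4 and 2, optima 0.8 and 0.5 on the standardised scale —
strong enough that the niche, not sampling noise, dominates the fit),
123 cell-thinned presences (the thinned sampler tops up draws until
exactly 123 distinct cells are occupied), and three future scenarios
shifting the thermal driver by +0.3/+0.6/+1.08 standard deviations
with proportional drying of the moisture driver. These emulate the
statistical structure of a real bioclimatic stack — collinearity,
spatial autocorrelation, presence-only sampling — but not the
semantics of actual bioclim variables, soil classes or human-footprint
indices, nor coordinate error, survey bias or non-additive climate
change; passing tests therefore certify the arithmetic and the
estimator behaviour under the stated generating process, not
performance on real occurrence data.

A hand-enumerable 6×6 two-layer fixture (committed as golden ASCII
copies under `tests/data/`) carries expected values — thinning counts,
maxSSS threshold, class counts, overlay counts, centroid — recomputed
by plain-loop enumeration independent of the vectorised code paths.

## Numerical choices and degenerate inputs

* maxSSS ties: smallest threshold; all-identical scores return that
  constant with a warning.
* Point-in-cell assignment uses half-open [west, east) × [south,
  north) intervals; points on the far east/north grid edge are
  dropped. Per-cell thinning keeps the first record in input order and
  is idempotent.
* ESRI ASCII I/O accepts both corner and center header dialects
  (center is converted by subtracting half a cell) and round-trips
  values including nodata sentinels.
* Zero-variance variables at occurrences get r = 0 in the Pearson
  matrix (flagged) so they can never trigger the collinearity rule.
* All stochastic steps (field generation, sampling, background
  subsampling, replicate splits, permutations) take explicit seeds;
  replicate seeds are spawned from a SeedSequence so they are distinct
  and reproducible.

## Problem sizes

The scripted analysis and the reproduction script run the full
pipeline at the default 100×100 scale with a compact tuning grid
(rm ∈ {0.5, 1, 2} × {L, LQ, LQP}, 10 replicate splits), which keeps a
complete end-to-end run in the seconds range while exercising every
stage; the full 40 × 31 default grid is available through
`default_rm_values()` and `all_feature_combinations()` when a
exhaustive sweep is wanted.

## Known limitations

* No sampling-bias correction, categorical variables, cumulative
  output or novel-climate (extrapolation) diagnostics.
* Percent contribution is permutation-based, not path-based; values
  are not numerically comparable to sequential-solver outputs.
* Areas are computed in spherical geographic geometry only (no
  projected-CRS equal-area option).
* The fixed-knot threshold/hinge design is coarser than data-driven
  knot placement; very sharp response edges may be smoothed.
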