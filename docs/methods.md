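# Methods

This note documents the statistical models, the numerical choices, and the
design decisions behind `larmap`, in the order the pipeline runs.

## Change of support and realignment

Covariates arrive either as point surveys at locations that do not
coincide with the response locations (point-to-misaligned-point support)
or as rasters (block-to-point support). Both are resolved by brute
realignment before any modelling: every covariate is summarised over a
square pixel (default 25 m) centred on each response location as the mean
over a regular `array_dim × array_dim` array of points spanning that pixel
(default 100 × 100). The array points sit at the centres of an
`array_dim²` subdivision of the pixel — strictly interior, half-open
convention — so the array mean of any function affine in the coordinates
equals its value at the pixel centre.

Point surveys are interpolated to the array by a classical 2-D thin plate
spline with kernel U(r) = r² log r, fitted by the standard augmented
linear system with side conditions (radial weights orthogonal to affine
functions). Coordinates are internally centred and rescaled before the
solve, and a ridge jitter of 1e-13 is added to the radial block for rank
safety; with zero smoothing the spline interpolates its knots to well
below 1e-8. Rasters are queried at the array points by nearest-pixel
lookup (no bilinear smoothing — the raster value *is* the areal datum);
nodata handling is configurable (error by default, or mean over valid
points). Coordinates are treated as planar metres in a projected CRS
throughout; no geodesy is attempted.

Realigning outside the regression model amounts to assuming the realigned
covariate values are error-free — the main modelling limitation of the
two-stage approach, shared with any realign-then-regress workflow.

## Design expansion and collinearity filtering

Base covariates are expanded to powers 1..4 and all pairwise products
(`p` covariates → `4p + p(p−1)/2` terms; 63 → 2205), computed on raw
realigned values. Filtering enforces a maximum correlation coefficient
magnitude (MCCM) between any retained pair by greedy elimination: the
currently largest |Pearson r| above the threshold is found and one member
dropped, preferring (1) the finer native spatial resolution, (2) the lower
derivation complexity, (3) a seeded random choice. Interactions inherit
the coarser parent resolution and the sum of parent complexities plus one;
powers inherit the parent resolution and add (power − 1). Greedy
largest-first ordering is a choice (any order satisfying the
post-condition is defensible); it is deterministic, order-invariant (the
scan operates on name-sorted columns, exact ties break lexicographically),
and guarantees the post-condition that every retained pair satisfies
|r| ≤ MCCM. Correlations are computed once on the full realigned dataset
before splitting, matching a filter-once-then-resample workflow.

Standardization follows the LAR convention: training columns are recentred
to mean zero and rescaled to **unit Euclidean norm** (not unit standard
deviation), the response is centred on its training mean, and the same
affine transforms are mirrored onto the validation data (which is
therefore generally not standardized). Zero-variance training columns are
flagged out of selection for that split only.

## The LAR-LASSO path

The L1-penalised least-squares path is computed from scratch by Least
Angle Regression with the LASSO modification. At every breakpoint all
active covariates share the same absolute correlation with the residual,
strictly larger than any inactive covariate's; the prediction vector moves
along the equiangular direction until an inactive covariate catches up
(add step) or an active coefficient crosses zero (drop step — the
coefficient is removed and the direction recomputed for the reduced active
set). The path terminates when the degrees of freedom are exhausted
(min(n − 1, p) active terms; the intercept consumes one) or the maximal
absolute correlation falls below a configurable threshold (default 0, i.e.
run to exhaustion). λ is never a user input — each breakpoint corresponds
to λ = 2·(max |correlation|), and model choice along the path is made by
validation.

Numerical guards: correlations within 1e-12 are treated as tied and the
smallest index enters; simultaneous zero-crossings drop the lowest index
first and re-evaluate; a candidate whose entry would make the active Gram
matrix singular (condition number above 1e12) is skipped with a warning
and excluded; input column norms must be within 1e-6 of unity. Between
breakpoints the path is piecewise linear in the coefficients, so
`coefficients_at_l1` interpolates linearly in the L1 arc-length
coordinate.

Correctness is certified two ways in the tests: every breakpoint must
satisfy the LASSO KKT conditions at its implied penalty to 1e-8, and
breakpoints with penalties bounded away from the non-unique near-zero-λ
regime must match an independent coordinate-descent convex-optimisation
solution to 1e-6. Orthonormal designs reproduce the soft-thresholding
closed form; for p < n the path terminates at the OLS solution.

The ridge case (squared penalty) has a closed form and is deliberately out
of scope; `PenalizedFitSpec` validates that the penalty exponent is 1.

## Comparator selectors

Exhaustive best subsets (plain enumeration, guarded to ≤ 30 candidates),
forward stepwise, backward stepwise (requires an estimable full model,
p ≤ n − 1), and sequential replacement (forward step followed by
first-improvement swap passes, scanning in-model terms in index order, to
a fixed point) all return one OLS model per subset size. All are
deterministic given the data. Exhaustive search dominates every heuristic
in training RSS at every size — a tested invariant.

## Repeated-split selection and model averaging

The data are divided into `n_splits` (default 500; 100 in the scaled-down
study) unique partitions of 35 training / 25 validation observations,
drawn uniformly with uniqueness enforced by rejection. One split plan is
shared across methods and MCCM levels so that method comparisons are not
confounded by split noise. Per split, the selector's model sequence is
evaluated on the validation set and the candidate minimising the VSEPE sum
of squares is selected (ties → fewer terms, then the earlier candidate).

Models are combined with weights inversely proportional to their
validation error sums of squares, normalised to one. The exact-fit limit
is handled explicitly: splits with SSE below 1e-12 share all weight
equally and the rest get zero. Weights are scale-invariant in the SSEs.
Model-averaged predictions are convex combinations of the per-model
predictions.

Summaries report min/Q1/median/mean/Q3/max of the pooled absolute
validation errors, plus the coefficient of determination R² = 1 −
SS_res/SS_tot of the weighted model-averaged predictions against **all**
observations (an in-sample quantity: every observation appears in many
training sets). Selection frequencies count, for each term, the selected
models with a nonzero coefficient on it. The response is modelled
untransformed despite its skew; unmodellable high outliers inflate the
VSEPE maximum, not its median (a tested property).

## Spatial residual stage

Residuals are computed against the stage-1 weighted model average at the
observation locations (one documented interpretation; per-split residuals
would be an alternative) and regressed on a trend surface: single powers
E^k, N^k for k = 1..12 and two-factor products E^a·N^b with
a + b ≤ 6 — the product cap at half the maximum single order avoids
confounding high-order products with high-order single terms. With the
defaults this is 24 + 15 = 39 columns. Coordinates are recentred to their
midrange and rescaled to [−1, 1] before powering, which is essential for
conditioning at order 12 and makes the design invariant to affine changes
of coordinate units up to column scaling absorbed by standardization.
The same LAR + validation-selection + inverse-SSE-averaging machinery is
reused; by default a fresh seeded split plan is drawn (reusing the stage-1
plan is a config switch). Kriging and semivariogram-based alternatives are
out of scope by design.

## Full-cover mapping

Point-survey covariates are rasterized by thin-plate-spline interpolation
to the common grid. At every pixel the stage-1 terms are computed from the
raster values, each split's standardization and coefficients applied, and
the weighted average taken; the stage-2 trend surface is evaluated at the
pixel centre and added once as a model-averaged surface (not per split).
Uncertainty is the width of the interval containing the middle 95 % of
the **unweighted** per-model predictions at the pixel, using numpy's
linear-interpolation quantile rule; a weighted variant is available. Nodata
pixels propagate nodata. The prediction raster restricted to
response-centred pixels reproduces the point predictions exactly.

## Synthetic scenes

`larmap.synth` generates fully self-contained test beds. Covariate and
residual fields are zero-mean stationary Gaussian random fields with an
exponential covariance C(d) = sill·exp(−d/range), simulated by circulant
embedding (FFT) on a doubled torus; slightly negative embedding
eigenvalues are clipped to zero, which is exact when the embedding is
positive semi-definite and a negligible approximation otherwise (the
empirical variance check in the tests is the guard). Fields are kept
deterministic given the seed.

Scene structure and defaults (the study conditions, chosen once):

- 60 response observations on a 60 × 60 grid of 25 m pixels, at distinct
  jittered pixel centres;
- 63 base covariates in 9 collinear blocks; within a block each covariate
  is √ρ·(shared latent field) + √(1−ρ)·(own field) with ρ = 0.975, so
  within-block pairs correlate at ρ and between-block pairs near zero.
  ρ = 0.975 is calibrated so that the 2205 expanded terms collapse to
  roughly 130–210 retained terms at the reference MCCM of 0.95 — the
  collinearity regime the analysis is designed for;
- fields have a 100 m correlation length on the 1.5 km domain — rough
  enough that 60 point observations retain a reasonable effective sample
  size, smooth enough that realignment and mapping are non-trivial;
- 6 covariates are delivered as misaligned point surveys of 500
  uniform-random points each; the rest as rasters;
- a sparse truth of 5 terms (linear/polynomial/interaction on distinct
  base covariates) with the combined signal rescaled to unit standard
  deviation, plus independent noise (default sd 0.5, i.e. a
  signal-to-noise variance ratio of 4 and a population R² of 0.8) and an
  optional spatially correlated residual field;
- the 3 largest responses multiplied by 2.5 to emulate a heavy right tail
  after shifting to a positive %-like scale.

The generator emulates the statistical structure of realigned field data —
collinear blocks, spatial autocorrelation, skew, misalignment. It does not
emulate real terrain derivatives, anisotropy, non-stationarity, or
covariate measurement error, so passing tests demonstrate correctness of
the machinery under the stated assumptions, not performance on any
particular real landscape.

## The recovery experiment

`larmap.recovery.recovery_experiment` is the package's parameter-recovery
benchmark. Recovery is only a well-posed question for effects the
candidate set can distinguish at the sample size, so the truth is planted
on terms that (a) **survive the MCCM filter** — a term removed at the
correlation cap is represented by a retained proxy and is not individually
identifiable (frequency tallies group a term with its high-correlation
proxies for exactly this reason) — and (b) have maximum |r| ≤ 0.85 with
every other retained term: at 35 training observations, a 0.9-correlated
competitor is statistically indistinguishable from the truth and selection
credit splits between them. Planted coefficients have equal magnitude and
random sign. Under these conditions the LAR ensemble places all five true
terms in the top decile of selection frequency in essentially every
replicate, with in-sample model-averaged R² typically between 0.75 and
0.95 around the 0.8 population ceiling.

The zero-noise comparison uses a small linear-only design (8 covariates,
3-term truth) so that exhaustive and backward selection are feasible;
every selector reaches R² ≈ 1 there, a sanity floor rather than a
discriminating benchmark.

## Problem sizes and determinism

Tests and the acceptance script run the scaled-down study (100 splits,
60 observations, 2205 → ~150 filtered terms) rather than 500-split rasters
at survey scale; the pipeline itself defaults to 500 splits. All
randomness flows through explicit integer seeds: scenes, split plans,
filter tie-breaks and truth planting are bit-reproducible, and the CLI
manifest records a hash of the resolved configuration so identical configs
can be verified to yield identical artifacts.

## Known limitations

- Realignment uncertainty is not propagated (no hierarchical misalignment
  model); covariates enter the regression as if observed without error.
- The middle-95 % interval reflects between-model spread only, not
  residual noise — it is an ensemble-disagreement band, not a predictive
  interval.
- Backward selection and exhaustive search are only available when the
  filtered design is narrow enough (p ≤ n_train − 1 and p ≤ 30
  respectively); the engine refuses infeasible combinations rather than
  approximating them.
- The exponential covariance and isotropy of the synthetic fields are
  conveniences, not claims about real data.
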