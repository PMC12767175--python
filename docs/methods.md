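# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `grasscast`, in the spirit of a package's statistical
reference manual.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The maximum-entropy niche model

### Objective

Given `m` presence points and `N` background cells with feature vectors
`f(x) in [0,1]^J`, the model is the Gibbs density over background cells
`pi(x) = exp(lambda . f(x)) / Z` minimizing

    J(lambda) = -(1/m) sum_presences lambda . f(x_i) + log Z(lambda)
                + sum_j beta_j |lambda_j|.

This is the standard presence-background MaxEnt formulation: the penalized
maximum-likelihood Gibbs density whose feature expectations match the
presence-sample means up to the lasso slack `beta_j`.  The objective is
convex; at an optimum with `beta = 0`,
`|E_pi[f_j] - mean_presence f_j| -> 0` (tested to 1e-5).

### Regularization schedule

`beta_j = r * beta0(kind, m) * s_j / sqrt(m)`, with `s_j` the presence-sample
standard deviation of feature `j` and `beta0` the published MaxEnt defaults:
linear and product features interpolate the table
`m = (10, 30, 100) -> beta0 = (1.0, 0.2, 0.05)` (clamped outside), hinge
features use the constant 0.5.  The global multiplier `r` defaults to 2, the
setting used throughout the grassland study this package operationalizes.

### Features

* **linear** — each layer min–max scaled to [0,1] over the background.
* **product** — pairwise products of scaled layers.
* **hinge** — forward `clip((x-k)/(max-k), 0, 1)` and reverse
  `clip((k-x)/(k-min), 0, 1)` at `n_hinge_knots` equally spaced quantile
  knots per layer (default 20; the desk-scale demo uses 8).  Quantile knots
  adapt resolution to the data; MaxEnt's per-value thresholds are
  impractical to reproduce and add little at these grid sizes.
* Feature classes are auto-selected by presence count: `<15` linear only,
  `15–79` +hinge, `>=80` +product — mirroring MaxEnt's documented
  sample-size rule restricted to the three feature classes the study names.
* Projection data are clamped to the background feature range (values map
  into [0,1]), MaxEnt's default extrapolation behaviour.  No MESS-style
  extrapolation diagnostics are computed.
* A constant layer contributes only its (identically zero) linear feature,
  with a warning.

### Optimization

Cyclic coordinate descent with soft-thresholding.  Each coordinate takes a
Newton step on the smooth part (`g_j = E_pi[f_j] - mean_pres f_j`,
`h_j = Var_pi[f_j]`, floored at 1e-12), applies the soft-threshold operator,
and backtracks (halving, <= 40 steps) until the true objective does not
increase — guaranteeing monotone descent of a convex function.  Weights
`w = exp(eta - max(eta))` are maintained incrementally and re-stabilized
after every accepted step, so `Z` never overflows.  Convergence is declared
when a full pass improves the objective by less than `tol * (|J| + tol)`
with `tol = 1e-7` (default), within 5,000 passes; non-convergence raises an
error carrying the objective trace.  The inner loop is numba-compiled when
numba is importable; a pure-numpy implementation of the identical algorithm
is the fallback.  Correctness is cross-checked against an independent
L-BFGS-B solver on the split-variable smooth equivalent (tests assert
agreement within 1e-5 on random small instances) and against the two-cell
closed form `lambda = ln 3`.

### Output scale

Raw output is `r(x) = exp(lambda . f(x)) / Z` with `Z` summed over the
training background (so raw sums to 1 there).  Reported suitability is the
cloglog transform `1 - exp(-e^H r(x))` with `H` the entropy of the fitted
raw distribution — MaxEnt v3.4's default output, a strictly monotone map of
raw into (0,1); AUC is therefore identical on either scale (tested exactly).

### Evaluation and contributions

AUC uses the Mann–Whitney rank formulation with ties counted 0.5
(via scikit-learn), cross-checked against brute-force pair counting.
Variable contributions are permutation importances: the drop in training AUC
when one variable's raw values are permuted across presence + background
cells jointly (mean of 5 permutations, floored at 0, normalized to sum
to 100).  Variables whose features all carry zero weight contribute exactly
0 without permutation, which preserves the zero-contribution exclusion rule
downstream.  Permutation streams are keyed to variable names, so results do
not depend on layer order.  Degenerate case: if no permutation changes the
AUC, the 100% is split evenly over the active variables so the sum-to-100
invariant holds.  Note that for perfectly collinear duplicate variables the
lasso splits weight arbitrarily between the copies, so their *fitted*
contributions need not be symmetric; the metric itself is symmetric under
exchangeable weights.

### Replicate cross-validation

`cv_replicates` runs 10 random-subsampling replicates, each training on
`floor(0.75 m)` presences and evaluating test AUC of the held-out presences
against the full background.  The species' final map is the per-cell mean of
the 10 cloglog maps (the replicate-mean convention of 10-replicate
cross-validated MaxEnt runs); scenario stacks are projected by the same 10
models and averaged identically.  Species with fewer than 8 thinned
presences raise an explicit skip error.  The background is all valid
unmasked cells — no random background subsample at these grid sizes.

## 2. Variable screening

Per species, two passes: (1) fit a preliminary model on all variables and
drop those with permutation contribution exactly 0; (2) compute pairwise
Pearson correlations over background cells, visit pairs with `|r| >= 0.8`
in descending `|r|` (ties: lexicographic pair order), and within each pair
still alive drop the lower-contribution member (contribution ties drop the
lexicographically later name); then refit on the retained set.  Greedy
descending-`|r|` visitation and the explicit tie rules make the outcome
independent of input variable order.  Zero-contribution exclusion is a
single pass, not iterated to a fixed point.  Correlations use the
background (the larger, stabler sample), not presence points.

## 3. Thresholding, tiers and compositing

* **maxSSS** — candidate thresholds are the sorted unique predicted values;
  sensitivity is the fraction of presences `>= t`, specificity the fraction
  of background `< t` (background as pseudo-absence; presence-background
  data have no true absences).  Scoring uses integer arithmetic over the
  common denominator so exact ties are exact, and the smallest maximizing
  threshold is returned.  Verified against an exhaustive scan on 1,000
  random instances.
* **Tiers** — non-suitable `P < 0.2`, low `0.2 <= P < 0.4`, medium
  `0.4 <= P < 0.6`, high `P >= 0.6`; boundaries left-inclusive.  Habitat
  (grassland) is every tier >= low, i.e. `P >= 0.2`.  The composite
  grassland extent uses this tier rule; per-species maxSSS thresholds are
  computed and reported for sensitivity analysis (pooled held-out test
  predictions vs the mean map's background values).
* **Composite** — per-cell maximum over species; the attaining species
  (ties: catalog order) assigns the cell's functional class (productive or
  wildlife-habitat).  Pointwise max is monotone: adding a species never
  shrinks the composite.
* **Masking** — excluded cells (urban/snow/etc.) are set to nodata before
  any area accounting; masking commutes with aggregation (tested).

## 4. Validation and change detection

The baseline composite grassland is cross-classified against a reference
survey map into concordant grassland / commission / omission / consistent
non-grassland.  Two agreement figures are reported: **overall agreement**
(concordant + consistent-non over valid cells — the headline, the only
definition under which "consistent non-grassland" participates in
validation) and **grassland-union agreement** (concordant over the union of
either map's grassland).

Areas are reported in 10^4 km².  Planar mode: cell count x (cell size in
km)².  Geographic mode: `(cellsize_deg * 111.195 km)² * cos(latitude)` per
cell-center row — the spherical approximation; no reprojection is
performed.  Change percentages are computed from unrounded areas and rounded
to 2 decimals only at report time; the scenario-mean row is the arithmetic
mean of scenario areas.  Functional-class change additionally decomposes
into gained / lost / stable cells with the exact identity
`cells_baseline - cells_lost + cells_gained = cells_scenario`; class areas
partition the scenario grassland exactly (published figures for the real
system do not always satisfy this additivity; the package enforces it).

## 5. The synthetic landscape generator

What it emulates: spatially autocorrelated environmental fields, species
with known niches tied to vegetation types and functional classes,
suitability-biased occurrence sampling, additive climate scenarios, an
exclusion mask, and a noisy reference survey.

* **Fields** — white noise smoothed by a Gaussian kernel of scale
  `autocorr_range` cells (default 5), standardized to mean 0 / sd 1.
  Kernel smoothing is the simplest construction with a controllable
  autocorrelation scale; no attempt is made to match real-world covariance
  structure between layers.
* **Species** — inverse-logit responses `expit(b + w . x)`; each species has
  one dominant climate driver (|w| = 6) plus weak responses to the other
  layers (sd 0.3), intercept uniform in (-9, -7).  These defaults give
  narrow niches (per-species prevalence ~0.1) whose 44-species composite
  covers roughly two thirds of the landscape — the regime of a real
  grassland system.  A quarter of species get hinge-like (rectified)
  responses; these are forced to a rising dominant limb, since a declining
  rectified response with a deeply negative intercept would be uniformly
  unsuitable.  Species are assigned round-robin to vegetation types; the
  last ~30% of types form the wildlife-habitat class.
* **Occurrences** — cells drawn with probability proportional to true
  suitability, points jittered uniformly within the cell.
* **Scenarios** — additive shifts to climate layers only (static layers are
  held at current values, matching the temporally-invariant-soils
  assumption).  The four SSP labels carry warmings of +2 / +3 / +4.1 / +5
  degrees; a degree shifts the temperature-proxy layer by 0.2 standardized
  units (a high-plateau mean-annual-temperature field spans roughly 15
  degrees spatially, so one degree is about a fifth of a spatial sd) and
  precipitation-like layers by +0.05.
* **Survey** — the true composite grassland with each valid pixel flipped
  independently at rate 0.10 (a plausible mapping-error rate for a field
  survey product).
* **Seeds** — a master seed derives every artifact's sub-seed by fixed
  offsets (`subseed`), so all generators are individually and jointly
  reproducible, bit for bit.

What passing tests on these landscapes do **not** show: robustness to
sampling bias, taxonomic error, interpolated-climate artifacts, biotic
interactions, or real covariance between predictors — none of which the
generator emulates.

## 6. The reference demo and problem sizes

`demo_study()` builds the package's reference synthetic study: 44 species /
17 vegetation types on a 64x64 grid (3 climate + 2 static layers), 70
occurrences per species, the four SSP deltas plus a zero-delta control
scenario (SSP000), a 5% exclusion mask and the 10%-noise survey.  The demo
uses 8 hinge knots per layer and direction.  These sizes are the package's
desk-scale reference conditions: large enough for every stage (screening,
10-replicate CV, compositing, validation, change detection) to be exercised
meaningfully, small enough to run in well under a minute.  The
parameter-recovery experiment uses a 48x48 grid, one dominant-driver species
(w = 8, intercept -9) and 200 presences.

## 7. Known limitations

* Coordinate descent visits features cyclically; with exactly collinear
  features the weight split among them is order-dependent (the objective
  value is not).
* The cloglog transform's absolute level depends on background extent and
  entropy; comparisons across models should use ranks or thresholds, not
  raw cloglog magnitudes.
* Geographic areas use the spherical cosine-latitude approximation; no
  ellipsoidal correction or reprojection.
* The `.asc` writer emits 10 significant digits; round-trips are identical
  to that precision, not bit-exact for arbitrary doubles.
* Permutation contributions are a global, not path-based, importance; they
  match MaxEnt's "percent contribution" in spirit, not numerically.
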