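# Methods

`wintrack` quantifies winter-recreation pressure from GPS tracks and
estimates a collared animal's behavioral and space-use response to it.
This note documents the models, the synthetic-scenario generator, the
numerical choices, and what the test suite's synthetic results do and
do not say about field data.

## Recreation-intensity surfaces and trails

Recreation intensity is circular-neighborhood point density: the value
of a cell is the number of recreationist GPS points within radius *r*
of the cell center divided by the neighborhood area in km²
(points/km²).  Radii of 30 m, 100 m, 500 m and 1 km are supported;
downstream covariates default to the 1-km surface, the scale at which
density fields from seasonal track collections are dense enough to
carry information.  Surfaces are computed per activity type
(hybrid, snowmobile, backcountry ski, packed-trail ski) and year, and
joined to animal-years by year exactly — no finer temporal matching is
attempted.  The output cell size defaults to 30 m (configurable; the
density definition does not depend on it).

Trails are derived, not mapped: most dispersed use follows groomed or
user-established routes for which no spatial data exist.  Trail cells
are cells of the 100-m surface whose density is strictly greater than
the 25th percentile of the *nonzero* cell values — with a vast zero
background the percentile of all cells is 0 and a strict ">" test
degenerates, so the nonzero-only pool is the default (an
`include_zero_cells` switch restores the other dialect).  The
trail-cell mask is thinned to a one-cell-wide skeleton
(`skimage.morphology.skeletonize`), and the skeleton is stored as
segments joining 8-connected cell centers with an STRtree for
nearest-distance queries.  Trail proximity enters models either as a
binary within-threshold indicator (250 m, 500 m, 1 km; boundary
inclusive) or as the decay form `exp(-α/d)` (α ∈ {50, 100, 250, 500,
2500} m), which is 0 on a trail and rises toward 1 with distance; the
d = 0 value is the continuous limit 0.  For each activity type, all
eight forms are screened in univariate weighted GLMMs and the
lowest-AICc form is carried into the candidate models.  An activity
type with no extractable trail returns a no-trail sentinel (NaN
distances) and its trail covariates are dropped.

## Behavioral annotation

Step length is the straight-line distance between successive fixes;
the turn angle at fix *t* is the absolute angle between the vectors
(t−1 → t) and (t → t+1), in [0°, 180°].  Gaps longer than 3× the modal
fix interval break a track into bursts; steps and turns are not
computed across bursts (collars miss fixes; the threshold is a design
choice, not data-driven).

A fix is **stationary** when its step is at most the calibrated step
threshold *or* its turn angle falls in the calibrated near-reversal
band, both inclusive; otherwise **active**.  The thresholds come from
stationary test collars: GPS error of a motionless collar makes
consecutive recorded positions jitter, producing short steps whose
lengths are Rayleigh-distributed and back-and-forth direction
reversals concentrated near 180°.  The defaults — step ≤ 27.02 m
(70th percentile of stationary steps) and turns in [174°, 180°] (90th
percentile, band read as a closed interval anchored at 180°) — are the
classical field calibration; fitting `ActivityClassifier` on a user's
own stationary collars replaces them.  The first fix of a burst has no
step and inherits the following fix's state.

Day/night is computed from the NOAA solar-position equations (solar
zenith 90.833° for rise/set); the implementation is cross-checked in
the tests against an independent Spencer-series oracle to ±5 min.  Day
is the half-open interval [sunrise, sunset); a night period runs from
sunset to the next sunrise and is keyed to the date it starts on.

Home ranges are minimum convex polygons: at the 100% level the convex
hull of all fixes; at 95% the hull after removing the ⌈5%⌉ fixes
farthest from the centroid of all fixes (single-pass centroid-distance
peeling — the centroid is not recomputed between removals).  Movement
rate is the mean of per-step speeds (km/hr) over the *active* steps of
a day/night period; a total-distance-over-total-time variant is
exposed as an option.  Tortuosity is net displacement divided by gross
path length over the period's fixes, in [0, 1].  Period summaries
average covariates over the period's fixes and exclude fixes outside
the animal-year's 95% MCP.

## Mixed models

All models share one random structure: a random intercept per animal,
absorbing repeated-measures level differences.  Continuous covariates
are z-scored ((x − x̄)/SD), with the transform stored for prediction.
Candidate designs are screened for collinearity (pairwise |r| < 0.60,
VIF < 2.0).

Gaussian responses (movement rate, tortuosity) use `statsmodels`
MixedLM fitted by ML (not REML, so AICc comparisons across fixed
effects are valid).  When the random variance hits the zero boundary,
statsmodels returns an infinite log-likelihood; the fit then collapses
to the ordinary regression, whose ML log-likelihood is used instead.

Binomial responses (used vs. available, active vs. stationary, inside
vs. outside a ski polygon) use a random-intercept logistic model
fitted here by maximizing the marginal likelihood with Gauss–Hermite
quadrature (25 nodes by default; the integrand is effectively exact
for the small random SDs these designs produce) and analytic
gradients.  Observation weights multiply each observation's
log-likelihood term: used–available designs weight available rows by
n_used/n_available (0.5 at the default 1:2 ratio) so both classes
contribute equal total weight, and the weighted fit is provably
identical to duplicating rows (verified in the tests against a
duplicated-row oracle and against brute-force numerical integration of
the random effect).

AICc = −2·logL + 2k + 2k(k+1)/(n−k−1), with k counting fixed effects
plus the random-intercept variance plus (gaussian only) the residual
variance; mixing k conventions breaks ΔAICc, so one convention is used
everywhere.  Ranking requires fits on identical rows and drops
non-convergent fits with a warning.  Marginal r² for gaussian models
is var(Xβ̂)/(var(Xβ̂) + σ²_random + σ²_resid).  Model fit is assessed
by stratified five-fold cross-validation: refit on four folds, score
the held-out fold with fixed-effects predictions, and compute AUC by
the rank statistic (equal to the pairwise Wilcoxon probability).

Confidence intervals are Wald intervals on the estimation scale.
GPS fixes are serially autocorrelated far beyond what a shared
intercept captures, so model-based SEs for used–available fits are
anticonservative; `fit_mixed(..., cluster_robust=...)` provides the
score-sandwich and delete-one-cluster jackknife estimators clustered
by animal, with t(G−1) critical values.  The jackknife is the default
in the recovery experiments (10 clusters; the plain sandwich is
downward-biased at that few clusters — simulated coverage 84% vs 93%
for the jackknife).

## Used–available selection and functional responses

Used rows are an animal-year's fixes inside its 95% MCP; available
rows are 2× as many uniform points in the same polygon (rejection
sampling), each given a random hour mapped through sunrise/sunset so
temporal terms are estimable.  The default candidate set per
recreation type is reconstructed from the analysis design: a canopy
base model, then additive and interactive combinations of intensity or
trail proximity with canopy, study area, and day/night period
(10 models when trails exist).  Models referencing columns the table
lacks are dropped rather than guessed.

Diel activity is modeled as active(1)/stationary(0) against
standardized 1-km intensity interacted with a combined
area × period stratum (e.g. west-day … east-night), giving each
stratum its own activity–intensity slope; predicted activity curves
per stratum are returned for plotting.

The functional response compares, across individuals, mean intensity
at used fixes with mean intensity at available points (the 2:1 sample
by default; exhaustive raster averaging over the MCP is an option).
Linear and quadratic OLS fits of use on availability are compared with
the exact likelihood-ratio test for nested gaussian models — the
monotone F transform of the LR statistic, used because the χ²(1)
approximation is anticonservative at ~20 individuals — and the linear
slope is additionally tested against 1.  Either signal supports a
functional response.  Selection ratios (mean use / mean availability)
are reported per individual together with a plot-ready (ratio − 1)
vs. relative-availability table; individuals with zero availability
are excluded with a warning, and at least five individuals are
required.  The regression is unweighted (one point per individual).

## Developed-area avoidance

The bootstrap test draws, 1,000 times, n_total uniform points in the
animal's 95% MCP (n_total = the animal's fix count) and counts points
inside the ski polygon.  The 2.5 and 97.5 empirical percentiles are
taken by nearest rank (no interpolation — the reference bounds are
integers, consistent with rank-based quantiles).  An observed inside
count strictly below the lower bound is *avoidance*, strictly above
the upper bound *preference*, otherwise *no difference*.  "Sampling
with replacement" is realized as independent redraws of n_total
uniform points per iteration (standard Monte Carlo), not resampling of
observed fixes.  An empty MCP–ski intersection makes the test
degenerate (expected count 0); classification is forced to
no-difference with a note.  As iterations grow the percentiles
converge to Binomial(n_total, overlap share) quantiles, which the
tests verify against the exact binomial.

The ski-area entry model takes all fixes (January–June), flags each as
inside/outside the polygon, and fits an 11-model candidate set —
canopy in every model, plus additive and interactive combinations of
month, weekend, and night.  Month is coded continuously with
February = 2 … June = 6; because predicted-use ratios depend on this
origin, the coding is config-exposed.  A predicted-use-ratio utility
evaluates P(inside | month a)/P(inside | month b) at fixed stratum
values from the fixed effects.

## The synthetic-scenario generator

The generator's purpose is known-parameter recovery: every effect a
downstream estimator measures is planted with a known coefficient.

**Landscape.** Canopy is smoothed Gaussian noise rescaled to mean 45%,
SD 15%, clipped to [0, 100] (zero SD yields a constant raster);
forest = canopy ≥ 30%.  **Recreation.** Each activity type gets random
smooth trail polylines; 85% of tracks traverse a trail out-and-back at
the type's travel speed (1–6 m/s) with 25-m cross-track jitter, the
rest roam freely; fixes every 5 s.  **Ski polygon.** A square covering
~15% of the extent against one edge.

**Animals.** Two-state trajectories at a 20- or 30-min duty cycle.
The latent state is drawn each fix with P(active) =
logit⁻¹(logit(0.6) + β_act · z_rec · 1[day]), where z_rec is the mean
standardized intensity at the current location — so recreation can
suppress (or boost) daytime activity with a known coefficient.
Stationary fixes add pure GPS jitter (σ = 12.3 m per coordinate,
chosen so the Rayleigh 70th percentile of stationary steps is exactly
27.02 m, matching the classifier's default calibration).  Active fixes
move through several (default 4) movement substeps — the animal moves
continuously between collar fixes — each substep proposing 24 candidate
headings at a gamma step length (mean 100 m/substep, i.e. ~200 m net
per 20-min fix, reproducing realistic daily distances), weighting
candidates by exp(W) where W(x) = Σ β_type·z_type(x) +
β_canopy·z_canopy(x) + γ_ski·1[inside ski], and applying a
Metropolis–Hastings correction (accept with min(1, C(x)/C(y)), the
ratio of candidate-set normalizers).  The correction makes the walk's
stationary density *exactly* ∝ exp(W) restricted to the animal's
home-range circle (radius 1.2 km, centers spread over the extent;
candidates outside are rejected), and animals are initialized from
that stationary density, so every fix is marginally a draw from it —
the used–available estimand equals the generating β with no burn-in.
With all β = 0 the correction is a no-op and the walk is an unbiased
random walk.  Heading persistence is deliberately omitted from the
selection walk (it would make the stationary density unknown); the
separate two-state track generator used for classifier validation does
have persistent active headings, which is what matters for turn-angle
realism there.

What the generator does *not* emulate: terrain and snow physics,
temporally varying recreation within a season, predator–prey dynamics,
fix failures (tracks are gap-free), and home-range shapes beyond
circles.  Passing recovery tests therefore demonstrates estimator
correctness under the generative assumptions, not robustness to the
full messiness of field data.

## Recovery experiments and their design

The experiments in `wintrack.experiments` are run both by the test
suite and by `scripts/acceptance.py`.

* **RSF recovery.** 10 animals × ~1,000 fixes (14 days at 20 min),
  snowmobile β = −1 per SD of extent-standardized intensity.  The
  used–available table is built with availability taken from the
  generator's true home-range circles, making the estimand exactly β:
  estimating the domain with a 95% MCP from 1,000 autocorrelated fixes
  truncates rarely-visited (avoided) habitat and attenuates the
  coefficient by ~0.15–0.2 — a real property of MCP-based designs that
  the package documents rather than hides (the field pipeline default
  remains the MCP).  The test asserts a negative estimate in ≥95 of
  100 seeds and |mean bias| < 0.15; measured: ~100% negative, mean
  bias ≈ 0.03.  Under β = 0, jackknife-clustered 95% CIs cover zero in
  ≥90% of 50 seeds (measured ~93–95%; naive model-based SEs cover only
  ~35%, which is why the robust option exists).
* **Bootstrap operating characteristics.** A uniform user of a square
  home range with 15% ski overlap, 1,000 fixes, 1,000 iterations: the
  avoidance label fires in ~2–2.5% of 200 replicates (the lower-tail
  mass; slightly under 2.5% from the discreteness of nearest-rank
  bounds on binomial counts).  An animal with hard polygon exclusion
  is labelled avoidant in >95% of replicates.
* **Classifier.** Calibration on 5 synthetic stationary collars
  (700 fixes each) recovers the analytic Rayleigh 70th percentile;
  state recovery on a matched two-state track (60% active) is ~93%,
  against an ≥85% bar.  The stationary-state recall ceiling is
  structural: by construction of the percentile rule, 30% of true
  stationary steps exceed the step threshold.
* **Functional response.** 20 individuals, availability uniform on
  [0.1, 1], quadratic truth y = 0.1 + x − 2x² + ε (σ = 0.1): LRT power
  > 0.8 (measured ≈ 1.0).  Linear slope-1 truth: rejection ≈ 5%
  (the exact F version keeps the size nominal where the χ² version
  would inflate it at n = 20).

`scripts/acceptance.py` runs the same experiments at reduced replicate
counts (40/20 recovery seeds, 200/100 bootstrap replicates) — the
package's choice of reporting size — and writes every quantity with
the problem size used.

## Numerical choices and limitations

* Planar projected coordinates in meters throughout; real data must be
  supplied in a metric CRS (one UTM zone).  No geodesy.
* Nearest-cell raster lookup (no interpolation); 30-m cells make the
  discretization error negligible at the 1-km covariate scale.
* Gauss–Hermite quadrature nodes: 25 default, reducible for speed;
  results are insensitive beyond ~9 nodes at the small random SDs of
  balanced designs.
* Empirical percentiles in the bootstrap test are nearest-rank;
  `np.percentile`'s default interpolation is *not* used there.
* Ties: the trail threshold uses strict ">", so a uniform surface
  yields no trails; the binary trail covariate and the classifier's
  thresholds are inclusive.
* The MCP attenuation of RSF coefficients (above) is the main known
  estimator bias; second-order (home-range placement) selection is out
  of scope, and the generator plants none.
* Wald CIs on GLMM fixed effects run a few points below nominal
  coverage in rare-event designs (simulated ~90–93% at ~5% event
  rates); the tests assert against simulated long-run values, and the
  cluster-robust options should be preferred for dependent data.
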