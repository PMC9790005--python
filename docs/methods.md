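# Methods

## The diagonal reference model

For a person with origin class *i* (childhood, age 14) and destination
class *j* (adulthood), both coded on the ordered three-level scale
disadvantaged < intermediate < advantaged, the expected outcome is

    E(Y_ij) = β₀ + p·μ_ii + (1 − p)·μ_jj + X_ij β,

where μ_kk is the mean outcome of the *immobile* group of class *k*
(the diagonal of the origin × destination table), p ∈ [0, 1] is the
relative weight of the origin class, and X_ij collects ordinary
covariates, optionally including mobility dummies.  The model assumes
mobile people's outcomes are a convex combination of the two immobile
benchmarks — there is no separate "mobile mean" unless mobility terms
are placed in X — plus additive covariate effects and homoskedastic
Gaussian noise.

**Identification.**  As written, β₀ and the three diagonal means are
jointly unidentified (adding c to β₀ and subtracting it from every μ_kk
changes nothing).  We parameterize μ_kk = β₀ + δ_k with sum-to-zero
class effects δ (two free parameters, δ₃ = −δ₁ − δ₂).  This matches the
convention of reporting three class effects that sum to ≈ 0 alongside a
constant.  p itself is identified only if at least one person is
mobile; all-immobile data raise an identifiability error.  Immobile
rows contribute total weight 1 to their own class regardless of p, so
they pin down δ while the mobile rows pin down p.

**Estimation.**  At fixed p the model is linear, so the Gaussian
likelihood is profiled: the inner problem is solved in closed form by
least squares (σ̂² = RSS/n, the ML variant), the profile is evaluated on
a grid over p ∈ {0, 0.01, …, 1}, and the best grid point is refined by
bounded scalar minimization (Brent, absolute tolerance 1e−6 on p)
within one grid cell either side.  This is global in p by construction
and immune to local optima in the mixing weight, unlike joint nonlinear
optimization.  Grid ties (flat profile) resolve deterministically to
the smallest p and are flagged.

**Inference.**  The covariance of (p, δ₁, δ₂, β₀, β, σ²) is the inverse
of the central-difference Hessian of the full negative log-likelihood
at the optimum (relative step ε^¼·max(|θ|, 0.05)); confidence intervals
are Wald at 95%.  The standard error of δ₃ follows from the (δ₁, δ₂)
block.  When p̂ sits within 0.005 of either boundary the fit is flagged
and the Wald interval for the weights is reported as not applicable
rather than truncated, since the quadratic approximation is invalid
there.  AIC = −2ℓ + 2k and BIC = −2ℓ + k·log n count
k = p + 2 class effects + constant + covariates + σ²; counting σ² is a
convention choice, consistent across all compared models.  Model
comparison refuses fits on different samples or outcomes.

Under the study-shaped design (n = 3140, class effects spanning one
outcome SD, unit noise) the sampling SD of p̂ is ≈ 0.04 — simulation,
the reported Wald SE, and the known-δ Fisher bound
1/√(Σ_mobile n_ij (δ_i − δ_j)²) all agree — so single-fit point
estimates of the mixing weight should be read with that uncertainty in
mind.

## Epigenetic clocks

A clock is intercept + Σ coef_i · β_ij over its probe set.  Clock
probes absent from the supplied matrix are dropped from the sum with no
rescaling and counted in the result, because published clocks were
trained on older arrays and newer chips omit some probes; the count
keeps such mismatches visible.  A missing (NA) beta for a present probe
drops that term for that sample only — the same policy at sample
granularity.  Beta values outside [0, 1] are an error by default
(downgradable to a warning); they are never silently clipped.
Published coefficient sets are user-supplied files (two-column
delimited text with one reserved `(Intercept)` row); the package ships
only toy clocks, generated in code.

## Cell composition

Whole-blood methylation is modelled as a mixture of reference profiles
R (probes × K cell types): per sample, fractions solve
min ‖b − Rw‖² subject to w ≥ 0 and Σw ≤ 1.  The inequality (not
equality) sum constraint follows the original quadratic-programming
formulation and leaves room for unprofiled cell types.  The solver uses
non-negative least squares first and escalates to an SLSQP quadratic
program only when the sum constraint activates, so interior solutions
equal ordinary least squares exactly.  The constraint set is asserted
after every solve.  Reference probe selection (F-test screening on
sorted-cell data) is out of scope: the reference matrix is taken as
given, and the module is agnostic about which reference is used.

## Age acceleration

Age acceleration per clock is the OLS residual of DNAm age on
[1, chronological age, plate dummies, cell fractions].  Residuals from
an intercept model have mean zero over the fitted sample and are
orthogonal to every regressor, which the tests assert; both properties
hold only for the sample actually fitted, so residualization is
re-run after any sample exclusion (the analytic filter runs first).
Pace-scale clocks are residualized identically; their acceleration is
in pace units, not years.  Plate enters as a categorical with the first
level as reference; residuals are invariant to that choice.

## Class, mobility and covariates

Household class is the maximum by rank over available members (single
available member: that member's class; all missing: missing).  The
analytic sample keeps rows with age ≥ 25 and complete origin,
destination, sex and age; counts removed per reason are logged and
attached to the result.  Mobility dummies come in four nested schemes
(none; any; up/down; one-/two-step by direction) satisfying
upward + downward = mobile and up1 + up2 = upward identities.
Age is standardized with the sample mean and n−1 SD *of the analytic
sample* (or stratum, when stratifying by birth year), and the square is
taken after standardizing.  Birth-cohort stratification defaults to
young = birth year ≥ 1956, with a flag to move the boundary year to
the old stratum; covariates are re-standardized within stratum.

## Descriptives

Cross-tab marginals are count-weighted means of the cell means,
recomputable from (cell means, cell counts) alone.  Display rounding is
half-away-from-zero to 2 decimals; full precision is kept internally.
A marginal reconstructed from cells printed at 2 decimals carries a
worst-case propagated error of 0.005 (cell half-ulp, weights sum to 1)
plus 0.005 on the printed total itself; the validation against the
published panels uses exactly that bound, and 27 of the 28 published
totals reproduce exactly after rounding (the one exception is a
printing-precision artifact of its source table).  Two-group screening
uses the classical pooled-variance t-test (the plain reading of
"two-sample t-test"; only descriptive p-values depend on the choice),
more groups one-way ANOVA.  The restricted contrasts subset to
(downward mobile, stably advantaged) or (upward mobile, stably
disadvantaged) and regress acceleration on the group indicator plus
sex, z-age and z-age², reporting the indicator's Wald 95% CI; the
standardized-age covariates are those of the full analytic sample, not
re-standardized within the restricted subset.

## Synthetic cohorts

The generator reproduces the design the analysis assumes: the 3 × 3
origin × destination table is filled with *exact* cell counts
(defaults: 432/234/302, 467/466/903, 42/76/218; n = 3140) rather than
multinomial draws, so marginal checks are exact; ages are
N(54.5, 14²) truncated below at 25; 55.8% female; eight plate batches;
marital status and education drawn with realistic shares.  The outcome
is generated directly from the DRM equation with configurable truth;
the default truth (p\* = 0.5, δ\* = (1, 0, −1), β₀ = 0, female effect
−1, σ = 1) has magnitudes near those typical of age-acceleration
outcomes and is otherwise arbitrary.  Beta matrices are built by
inverting toy clocks with positive coefficients: every clock probe gets
the base level (target − intercept)/Σcoef, plus zero-sum perturbations
orthogonal to the coefficient vector (shrunk per sample to stay inside
[0, 1]), so the clock recovers its target to machine precision while
betas vary probe to probe.  Reference mixtures are R·w + noise with R
uniform in [0.05, 0.95].

What the generator does *not* emulate: genome-scale beta distributions
and probe-level biology (bimodality, spatial correlation), informative
missingness, measurement error correlated across probes, survey
weights, and any real association between class and age or sex.
Passing tests therefore demonstrate correctness of the estimators and
pipeline under the assumed data-generating process, not robustness to
the messiness of real array data.

## Problem sizes and numerical choices

Simulation-based checks use the full study-shaped n = 3140 per
replicate: 10 replicates for parameter recovery, 100 for the BIC
model-selection study (each fitting the four model variants; standard
errors are skipped there since only point estimates and information
criteria are needed).  The deconvolution check uses 3 cell types on
200 probes with noise SD 0.01, recovered within ±0.05.  Smoke tests of
the file-level pipeline scale the cell counts to ~10% to keep every
cell occupied.  Rank checks name the aliased columns; degenerate inputs
(constant age, empty analytic sample, all-immobile data, all-missing
household class) raise typed errors rather than producing numbers.

## Known limitations

- Gaussian ML only: no survey weights, random effects, bootstrap, or
  non-normal outcomes; inference on p near its boundary is flagged, not
  repaired (no profile-likelihood intervals).
- The DRM assumes the convex-combination structure; genuine interaction
  between origin and destination beyond the diagonal blend is absorbed
  into residual variance.
- The deconvolution takes the reference as given; reference-probe
  selection and array preprocessing (normalization, QC) are upstream of
  this package.
- Clock files are plain linear predictors; clocks requiring
  transformation layers beyond an intercept and per-probe weights are
  not representable.
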