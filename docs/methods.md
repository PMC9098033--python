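# Methods

## Model

`trajmix` fits a finite mixture of linear mixed-effects models to unbalanced
longitudinal data. Subject `i` contributes a stacked outcome vector `y_i`
(`n_i` records, here 1–3 waves), a fixed-effects design `X_i` whose first
column is the intercept and second the integer wave indicator, and a random
intercept (`Z_i = 1`). Conditional on latent cluster `g`,

    y_i = X_i beta_g + b_i + eps_i,
    b_i ~ N(0, sigma_g^2 d_g),  eps_i ~ N(0, sigma_g^2 I),

so marginally `y_i ~ N(X_i beta_g, sigma_g^2 (d_g J + I))` — an exchangeable
within-subject covariance. `d_g` is the random-intercept variance *relative*
to the residual variance (dimensionless); `sigma_g^2` is in squared outcome
units (minutes/day)². The observed-data likelihood is
`prod_i sum_g pi_g phi_g(y_i)`, and the fitted objective is

    L(Theta) = sum_i log sum_g pi_g phi_g(y_i) - lambda1 sum_g ||beta_g||_1,

with the l1 norm taken over the penalized coordinates (everything except the
intercept; the wave indicator *is* penalized so that its selection is
informative). An optional `lambda2` penalty on `d_g` exists behind a config
switch and is off by default: only the fixed effects are penalized in the
tested configuration, which matches the random-intercept (q = 1) application
the package targets.

## Fitting

Alternating EM:

* **E-step** (exact): `w_ig ∝ pi_g phi_g(y_i)` computed with log-sum-exp;
  `pi_g = mean_i w_ig`. A component with `pi_g = 0` receives zero
  responsibility without division errors.
* **M-step** (blockwise ascent per cluster):
  1. `beta_g` given `(d_g, sigma_g^2)`: the weighted GLS problem is reduced
     to its normal-equation pieces `A = sum_i w_ig X_i' C_i^{-1} X_i`,
     `b = sum_i w_ig X_i' C_i^{-1} y_i` using the rank-one inverse
     `C_i^{-1} = I - d/(1 + n_i d) J`; the unpenalized block is solved
     exactly, then cyclic coordinate descent with soft-thresholding at
     `lambda1 * sigma_g^2` runs to a 1e-8 max-update tolerance. (The
     threshold carries `sigma_g^2` because the penalty is applied on the
     log-likelihood scale; see Limitations.)
  2. `(d_g, sigma_g^2)` given `beta_g`: `sigma_g^2` has a closed form for
     each `d`, so a bounded scalar search over `d in [0, 1e3]` on the
     profile likelihood does the joint update. The update is guarded — the
     candidate set always contains the incumbent — so it never decreases
     the objective.

Because the E-step is exact, the mixing update is the exact maximizer, and
both M-step blocks are ascent steps, the penalized observed-data objective
is nondecreasing across iterations up to floating-point noise; the driver
stops on any decrease or when the relative improvement falls below 1e-6
(500 iterations cap) and returns the best iterate. This monotonicity is
asserted (tolerance 1e-8) in the test suite on every recorded trace.

**Initialization.** One start from k-means (G centers on per-subject mean
outcome and OLS slope over wave, slope 0 for single-record subjects) plus
`n_starts - 1` seeded random-responsibility starts; along a lambda path the
previous solution is added as a warm start. Best final objective wins. A
cluster whose effective size `sum_i w_ig` drops below `max(2, 0.005 n)`
(variance parameters are unidentifiable below ~2 subjects) triggers a fresh
restart, up to 3 times, after which the best available model is returned
with a warning flag.

**lambda_max.** The reported `compute_lambda_max(data, G)` runs the EM with
the penalized block pinned at zero and records, at every M-step of every
start, the per-cluster KKT bound `max_j |gradient_j| / sigma_g^2` at the
zero point. Because the same seeded initialization is reused, any
`lambda1 >=` this value reproduces the all-zero trajectory exactly — the
"every penalized coefficient is exactly zero" endpoint holds for mixtures,
not only for the single-component case, where the usual pooled-gradient
bound would not be valid cluster-wise.

## Model selection

`model_search` fits every `(G, lambda1)` pair, each G with its own default
path (7 log-spaced values from `lambda_max` down to `0.01 lambda_max`, plus
0), warm-started in descending lambda, and scores each fit with

    BIC = -2 loglik + df log N,

where `loglik` is the *unpenalized* mixture log-likelihood at the penalized
estimates, `df` = (nonzero fixed effects over all clusters) + 2G variance
parameters + (G - 1) mixing probabilities (the standard lasso df estimate),
and `N` is the total observation count (a config switch uses subjects;
observation count is the default because the Gaussian likelihood is
observation-level). Ties break toward smaller G, then larger lambda. Single
fit failures are recorded and skipped.

`refit_unpenalized` refits each cluster's selected variables by unpenalized
ML on its hard-assigned members and reports Wald z statistics from
`Var(beta) = sigma^2 A^{-1}` at the fitted variance parameters. These are
descriptive: they condition on the selection and the hard labels, and no
multiple-testing correction is applied — post-selection-valid inference for
mixtures is an open problem and out of scope.

## Data conventions

Covariates are z-scored over all pooled rows before fitting (step one of
the standard workflow). The outcome is *not* standardized: the reported
cluster intercepts and back-transformed coefficients then stay in
interpretable outcome units (minutes/day), matching how the motivating
study reports its intercepts (e.g. 14.01 min/day). The wave indicator is standardized
like any other candidate by default (it competes in selection), and
`StandardizationInfo.original_scale_coefs` restores the raw-scale
interpretation exactly (verified against refitting on unstandardized data).
Rows with any missing modeled value are dropped with a logged count;
categorical covariates are reference-coded dummies declared in the schema.

## Synthetic cohorts

`default_taag_spec()` emulates the motivating cohort's structure: 568
subjects, three waves, three clusters with mixing (0.423, 0.509, 0.068),
sparse cluster-specific effects — intercepts (14.01, 32.36, 1.74), wave
coefficients (-1.10, -16.16, 29.11), and 2/6/4 nonzero covariate effects per
cluster among 31 candidates — and wave-monotone dropout whose continuation
probabilities are solved from the observed 428/137/3 record mix. Variance
components were never published for that cohort; the defaults
`sigma_g = (6, 9, 10)` min/day and `d_g = 0.5` are calibrations chosen so
simulated per-wave within-cluster SDs fall in the reported 6–21 min/day
range, and are documented as such, not as ground truth. Covariates default
to iid standard normals redrawn each wave (Bernoulli for dummies,
time-invariant for demographics); per-covariate generators support
cluster-shifted means to reproduce the between-cluster-only-variation
scenario. The generator does **not** emulate real covariate marginals,
covariate correlation structure (available via custom specs but not
defaulted), accelerometer measurement error, or non-monotone missingness —
so passing recovery tests demonstrate correctness of the machinery under
the model's own assumptions, not robustness to real-data violations.

`inflated_separation_spec()` is the stress-test configuration used by the
recovery studies: wave coefficients (-1.10, -30, +30) and
`sigma = (6, 8, 8)`, everything else inherited.

## Problem sizes used in the automated checks

Oracle-equivalence checks run 5 cohorts of 100 subjects against a generic
numerical optimizer on the exact marginal likelihood; EM-monotonicity spans
30 fits over G in {2,3} and lambda in {0, mid, lambda_max} on 150-subject
cohorts; recovery and BIC-selection studies use 10 seeded 568-subject
cohorts; generator fidelity uses 10,000 subjects. These sizes make the whole
suite run in a few minutes while keeping the statistical checks
well-powered.

## Known limitations

* **Penalty scale coupling.** With the l1 penalty on the log-likelihood
  scale (the model's definition), the coordinate-descent threshold is
  `lambda1 * sigma_g^2`: high-residual-variance clusters are penalized much
  harder than low-variance ones, and small clusters harder per observation
  than large ones. On cohorts with a large, steep cluster this can create
  two competing solutions — slope modeled with small `sigma_g`, or slope
  absorbed into `sigma_g` — and the l1 cost of a large wave coefficient can
  make BIC prefer the absorbed solution at coarse grid resolutions, or drag
  the selected lambda low enough that weak spurious covariates enter the
  large clusters. A per-cluster-size penalty scaling is available behind
  `FitConfig.scale_penalty_by_size` for sensitivity analysis.
* **Small effects are unrecoverable by design.** Effects much smaller than
  one coefficient standard error (e.g. a generative 0.019 when the SE is
  ~0.3) cannot be selected by any consistent procedure at these sample
  sizes; support-recovery summaries should be read with that floor in mind.
* **Between-cluster-only covariates are absorbed by intercepts.** A
  covariate with large between-cluster mean differences but little
  within-cluster variation is deliberately not selected — its effect is
  unidentifiable from within-cluster variation. The test suite reproduces
  this omission behavior.
* Penalized point estimates carry no standard errors; the unpenalized
  refits provide descriptive Wald statistics only. General `q > 1`
  random-effect structures are supported by the covariance algebra but not
  by the optimized M-step, and BLUP prediction of individual intercepts is
  not implemented.
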