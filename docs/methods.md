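# Methods

`svypate` estimates the **population average treatment effect (PATE)** of a
binary exposure on a continuous outcome from complex-survey data. This note
records the statistical model behind each component, the defaults and why
they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical choices that a maintainer would otherwise have
to reverse-engineer.

## Estimands and identification

Let `Y` be the outcome (mmHg scale in the reference scenario), `A ∈ {0,1}`
the exposure, `L` the measured confounders, and `Y¹, Y⁰` the potential
outcomes. The sample ATE is `E[Y¹ − Y⁰]` over the study sample; the PATE is
the same contrast over the *target population* the survey represents. When
the sample is drawn with unequal selection probabilities, each unit carries
a survey weight `ω = 1/P(selection)` (composed with an inverse response
propensity under nonresponse), and the two estimands differ whenever the
treatment effect is modified by a variable whose distribution the design
distorts (e.g. minority oversampling).

Identification requires exchangeability given `L`, consistency, and
positivity. The first two are untestable and are assumptions of *any* use
of this package; positivity is monitored operationally: propensity scores
outside a configurable band (default `(0.001, 0.999)`) raise a
`PositivityWarning`, and weighted standardized mean differences
(`balance_smd`) diagnose residual confounder imbalance.

## The three causal estimators

All three share the same propensity model `π(L) = P(A=1|L)` (logistic) and,
where applicable, the same outcome model `Q(A, L) = E[Y|A, L]` (linear), as
comparability demands.

**IPTW.** Treatment weights `t = A/π + (1−A)/(1−π)` create a
pseudo-population with confounders balanced across arms; the PATE estimate
is the difference of `w`-weighted arm means with `w = t·ω`. Implemented as
the exposure coefficient of a `w`-weighted linear regression of `Y` on `A`,
which is algebraically the same thing but delivers the design-robust
sandwich SE as a by-product. Options: stabilized weights (marginal
prevalence in the numerator) and a symmetric quantile cap on `t`
(truncation), both off by default — truncation trades positivity problems
for bias and is deliberately not silent (the capped count is reported).

**G-computation.** Fit `Q` by survey-weighted least squares, predict every
unit's outcome under `a=1` and `a=0`, and average the per-unit differences
with weights `ω`. In this cross-sectional setting the procedure is exactly
standardization with the (weighted) sample as the standard population. Two
Monte-Carlo modes exist because "repeat the prediction over MC iterations"
admits more than one mechanism:

* `parameter_draw` (default, 250 iterations): each iteration draws a
  coefficient vector from `N(β̂, V̂)` (design-robust `V̂`) and predicts —
  this propagates estimation uncertainty into the draws;
* `plugin`: a single deterministic prediction at `β̂`. For a mean contrast
  the two have the same expectation, so `plugin` is what every exact-match
  test and the large simulation studies use; residual-noise simulation was
  rejected because adding outcome noise changes nothing for a mean contrast
  of a continuous outcome.

**TMLE.** Doubly robust combination of both nuisance models. With initial
predictions `Q̂`, the clever covariate
`H = A/π − (1−A)/(1−π)` drives a one-parameter fluctuation: `ε̂` is the
no-intercept WLS coefficient of `Y − Q̂(A,L)` on `H`, and the targeted
predictions are `Q* (a,L) = Q̂(a,L) + ε̂·H(a)`. The PATE estimate is the
`ω`-weighted mean of `Q*(1,L) − Q*(0,L)`. The update solves the
efficient-influence-curve score equation, which is the source of double
robustness (verified by simulation: unbiased when exactly one of `Q̂`, `π̂`
omits a true confounder; biased only when both do).

Two survey-weight placements in the targeting step are shipped, because
both appear in practice and they solve the *same* weighted score equation:

* `plain` (default): `H` is the pure inverse-propensity quantity and `ω`
  enters as the fluctuation regression weight — numerically stabler;
* `weight_embedded`: `H` is multiplied by `ω` and the fluctuation is
  unweighted.

The fluctuation is linear on the identity link. The bounded-logistic
fluctuation used by some implementations for outcomes mapped to `[0,1]` is
out of scope: outcomes here are unbounded continuous measurements and the
method's defining equations are on the identity scale.

The propensity model is fitted *unweighted* by default, with `ω` applied
only in the final analysis weights/fluctuation; a config switch
(`propensity_survey_weighted`) fits it with `ω` instead, and the choice is
recorded in every result's metadata. Published descriptions are split on
this point; both are supported rather than guessing.

## Survey machinery

Weights are always probability weights: they enter the estimating equations
`Σ wᵢ xᵢ (yᵢ − μᵢ) = 0`, never frequency counts. Consequences: point
estimates are invariant to rescaling all weights by a constant, and the
variance must be the sandwich, not the model-based one. The sandwich meat is
the stratified between-PSU covariance of PSU score totals with the
with-replacement first-stage approximation (the standard convention for
public-release health-survey data); without design labels every row is its
own PSU, which reduces to HC0-type robustness (times `n/(n−1)`). A stratum
with a single PSU is a hard, named error — silent centering defaults hide
design problems.

The weighted GLM core (closed-form WLS; logistic IRLS with explicit
separation detection) is implemented directly in `survey_design` because
the stratum/PSU linearization variance is not available in the Python
regression stacks and because the bootstrap layers below refit these models
tens of thousands of times; statsmodels serves as an independent
cross-check in the test suite instead.

**Bootstrap.** Percentile CIs, default level 95%, default scheme `rows`
(records resampled with replacement, weights carried along) — matching the
common practice for these analyses — with the Rao-Wu-Yue rescaling
bootstrap (`n_h − 1` PSUs per stratum, weights scaled by
`n_h/(n_h−1) ×` multiplicity) as the design-aware option. The estimator
modules run the bootstrap over design matrices built once from the full
data (categorical codings frozen), so a resample that drops a factor level
cannot change the parameterization; replicates on which a refit fails
(e.g. separation) are dropped, and more than 50% failures aborts with a
diagnostic. IPTW's default interval is the robust-Wald one from the
sandwich (the conventional presentation for IPTW), with
`ci_method="percentile_bootstrap"` available — and used wherever widths
are *compared across estimators*, so that the comparison reflects estimator
efficiency rather than the difference between Wald and percentile
construction. The influence-curve Wald interval for TMLE is provided as a
fast approximation with a documented caveat: it ignores stratification and
clustering.

## The synthetic-data generator

The generator emulates the features of an NHANES-like design that matter
for PATE estimation, with defaults forming the package's reference
scenario:

* **Superpopulation** of N = 400,000 with four confounders: age-like
  (uniform on 8–12 years), income-to-needs-like (lognormal, sd 0.5 on the
  log scale), sex-like (Bernoulli ½), ethnicity-like (3 levels,
  probabilities 0.55/0.25/0.20).
* **Exposure** by a logistic model on all four (prevalence ≈ 28–33%,
  propensities spanning roughly 0.05–0.6: confounding and realistic weight
  variability without positivity failure).
* **Potential outcomes** on a blood-pressure-like scale: `y0` = linear
  model (intercept 100 mmHg) + Gaussian noise (sd 8); `y1` = the same
  systematic part + `τ₀ + τ_L·L` + an independent noise draw. Only marginal
  means matter for ATE-type estimands, so the noise correlation between
  `y1` and `y0` is irrelevant and independence is the simplest choice.
  Default effect: `τ₀ = 2` mmHg plus `+2`/`+1` in the two minority
  ethnicity levels → PATE = 2.70 analytically.
* **Design**: strata are the ethnicity levels, with inclusion probabilities
  0.0025/0.01/0.0075 — minority oversampling, n ≈ 2,100. Because the
  oversampled strata carry the larger effect, the expected unweighted
  sample ATE (≈ 3.19) exceeds the PATE (≈ 2.66): the package's central
  phenomenon, by construction. Covariate-dependent selection (a logit tilt
  on income) and per-stratum nonresponse (weights composed with inverse
  response rates) are available dials, both off by default; setting all
  stratum probabilities equal collapses the design to a simple random
  sample and makes unweighted estimators unbiased.
* **PSU labels** (12 per stratum) are assigned at random, so the design
  *variance machinery* can be exercised, but there is no real intra-cluster
  correlation.

N = 400,000 is deliberately large relative to n: the finite population's
PATE contains the realized mean of the inestimable noise contrast
`e¹ − e⁰`, whose standard error is `√(2·8²/N)` ≈ 0.025 at this size. At a
smaller N this term is material (≈ 0.05–0.15) and drives a wedge between
the stated truth and what *any* observed-data estimator can target, which
would corrupt bias assessments.

What the generator does **not** emulate — so what passing tests do not
show: real multi-stage cluster sampling (intra-PSU correlation), weight
calibration/raking and post-stratification, measurement error in exposure
(self-report misclassification), item nonresponse patterns, and
non-Gaussian outcome tails. Conclusions about the variance machinery on
genuinely clustered data rest on the correctness of the linearization
formulas, which are tested against hand-expanded algebra, not against a
clustered truth.

## Simulation-study conventions

Performance summaries (bias, Monte-Carlo SE, empirical SE, mean CI width,
coverage) are computed over replicate survey draws from one fixed
superpopulation; the truth is that population's exact PATE. Default
problem sizes: 500 replicates for bias (point estimates only), 30
replicates × B = 300 for CI widths, 400–500 datasets × B = 500 for
bootstrap coverage, n ≈ 600 for the coverage study and ≈ 2,100 elsewhere.
These sizes put the Monte-Carlo SE of a bias estimate near 0.02 mmHg
(1% of the effect) while keeping a full run in minutes on one core.

Where the scenario's effect modification is active, the outcome model used
by G-computation and TMLE in these studies includes the
exposure×ethnicity interaction: weighted regression standardization is
consistent for the PATE only if the outcome model captures the effect
modification (with the no-interaction model, its asymptotic bias here is
≈ +0.10, which TMLE, doubly robust, repairs but plain G-computation does
not). The comparison pipeline's default remains the conventional
no-interaction additive specification.

## Known limitations

* The TMLE-vs-IPTW CI-width gap is small in the reference scenario
  (≈ +0.04 mmHg in expectation, per-replicate sd ≈ 0.29): with outcome
  models explaining a modest share of outcome variance, TMLE's
  residualization removes little of the combined-weight variance, so
  TMLE's interval is only marginally narrower than IPTW's. G-computation's
  advantage (≈ 0.1–0.15 mmHg) is robust. Small replicate sets can show the
  TMLE/IPTW legs reversed.
* The "targeted bootstrap" sometimes cited for TMLE interval estimation is
  not reproduced; a standard percentile bootstrap of the whole procedure is
  substituted and labelled as such in results.
* Percentile intervals are widened, when necessary, to include the point
  estimate, so a skewed replicate distribution cannot produce an interval
  excluding its own estimate.
* The NHANES adapter restructures user-supplied files only (XPT via
  `pandas.read_sas`, or CSV); all variable names, the smoking coding, and
  poverty cutpoints are configuration because they change across survey
  cycles. Reproducing published descriptives requires the actual public
  files, which this package does not download.
* No Super Learner / machine-learning nuisance estimation; no longitudinal
  g-computation; no replicate-weight (BRR/jackknife) variance; no weight
  calibration. Exposure-effect sensitivity analysis for unmeasured
  confounding is out of scope.
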