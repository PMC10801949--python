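# Methods

## Model

A Conditional Survival Bayesian Network (CSBN) is a pair: a discrete
Bayesian network `B(G, Θ)` over categorical clinical covariates, and a
survival node `E` whose parents are the predictors of a multivariable Cox
proportional hazards model. The network factorizes the covariate joint as
the usual product of per-node conditionals; the survival node's conditional
distribution is not a table but the function

    P(E = 1 | parents x, horizon t) = 1 − S0(t) ^ exp(x·β)

with `β` the Cox log-hazard-ratio vector over dummy-encoded predictor
levels and `S0(t) = exp(−H0(t))` the Breslow baseline survival anchored at
the all-reference covariate pattern. Keeping this CPD functional is a
deliberate choice: with twelve parents of two to four levels each the
materialized table would exceed a million rows, while the lazy form is
evaluated in O(p) per query and its memory use is independent of the
parent count.

Prediction for a patient with incomplete predictors is importance
sampling: likelihood weighting fixes the observed covariates as evidence,
forward-samples the rest in topological order, weights each sample by the
product of evidence conditionals, and averages `S0(t)^exp(x·β)` over the
weighted samples. With full parent evidence this collapses to the Cox
formula exactly (the implementation short-circuits the sampling in that
case). Alongside every estimate the weighted-ratio Monte-Carlo standard
error is returned.

Assumptions inherited from the parts: proportional hazards with Breslow
handling of tied event times; covariates discretized to categories
(continuous-as-numeric is out of scope); missingness ignorable at
prediction time (the marginalization is over the *population* conditional
distribution of the unobserved covariates, which is correct under MCAR/MAR
given the evidence, not under informative missingness).

## Training pipeline

`train_from_cohort` reproduces the model-development flow on the
complete-case subset of a cohort:

1. discretization (explicit cut points, e.g. age <45 / 45–59 / 60–74 /
   >74, closed on the right; laboratory variables at empirical tertiles
   learned on training data and re-applied verbatim elsewhere; values at a
   cut point fall in the lower bin);
2. univariate Cox screen at p < 0.05 (smallest Wald p across a variable's
   non-reference levels);
3. Bayesian-network structure over the screened variables: nonparametric
   bootstrap (default B = 200), tabu search per resample, arcs with
   inclusion fraction ≥ 0.5 whitelisted for a final tabu pass;
4. LASSO-Cox over the screened variables, tenfold cross-validation,
   predictors = variables with any nonzero dummy coefficient at the 1-SE
   lambda (fallback to lambda-min if empty);
5. unpenalized multivariable Cox refit on the selected predictors — this
   fit supplies β and S0;
6. survival-node attachment and re-estimation of the network CPTs by
   maximum likelihood.

Domain constraints ship as editable configuration, not code: nothing may
point into age or sex, and smoking → COPD is whitelisted.

## Numerical choices

* **Cox fitting.** Newton–Raphson with step-halving on the Breslow partial
  likelihood; score tolerance 1e-8 *per event* (the score is a sum of one
  O(1) term per event, and the risk-set cumulative sums carry rounding
  noise of the same order, so an absolute 1e-8 is unattainable at N in the
  thousands); 100-iteration cap; |β| > 10 treated as monotone likelihood
  (complete separation) and reported as non-convergence naming the
  covariate. The Hessian is assembled without any N×p×p intermediate: the
  quadratic Breslow term telescopes to `X' diag(w·Λ) X` with `Λ_i` the
  cumulative hazard increments up to `t_i`.
* **Penalized path.** Objective `loglik(β) − λ Σ|β_k|` on the unnormalized
  log-partial-likelihood scale; proximal Newton whose inner problem (the
  exact second-order model plus the L1 term) is solved by cyclic
  coordinate descent on cached cross-products, with step-halving on the
  true objective. Fixed points are exactly the KKT points, which the test
  suite asserts. Grid: 100 (configurable) log-spaced values from λ_max
  (null-model score bound) down to λ_max/1000, warm-started.
* **Cross-validation loss.** Verweij–van Houwelingen partial-likelihood
  deviance, −2·[ll_all(β_fold) − ll_train(β_fold)]; mean and SE across
  folds; folds re-drawn (retry cap 20) until every training fold contains
  an event.
* **Structure search.** BIC for multinomial networks (decomposable,
  consistent); tabu list of the 10 most recent inverse moves; aspiration
  (a tabu move is allowed if it beats the incumbent); stop after 15
  non-improving moves or 10·n² iterations; ties broken lexicographically,
  so the search is deterministic for a given dataset. Family scores are
  cached and counted via `bincount` on ravelled level indices.
* **Model averaging.** If both orientations of an arc reach the strength
  threshold, the majority direction wins; remaining directed cycles are
  broken by dropping the lowest-strength arc on each cycle.
* **CPTs.** Conditional relative frequencies; parent configurations never
  observed get the uniform row (logged). Rows validated to sum to 1 within
  1e-9.
* **Degenerate inputs.** Constant covariates raise identifiability errors;
  a variable whose tertile cut points are undefined (all values equal)
  raises at discretization; evidence with zero probability under the
  network raises rather than returning 0/0.

## Synthetic-cohort generator

The benchmark cannot use the original clinical cohort (not deposited), so
`csbn.benchmark` emulates its structure:

* **Covariates.** 26 categorical variables sampled from a hand-specified
  reference network: 12 survival predictors (gender, age in four bins,
  smoking, drinking, NSCLC, targeted therapy, COPD, pneumonia, stage,
  ILD, respiratory failure, fibrinogen tertile) with realistic
  dependencies (age/gender → smoking → COPD, stage → treatment), 10
  companions correlated with predictors only (so they carry univariate but
  not independent signal), and 4 pure-noise variables.
* **Event times.** log T ~ Normal(μ0 + X·W′, σ²) with W′ = −0.5·β per
  predictor level, β being the published multivariate Cox coefficients
  (sign flipped because longer log-time means lower hazard).
* **Censoring.** Weibull(shape 1.2, scale 3.0 years); observed time and
  status by the min rule.
* **Calibration.** The residual scale σ and the intercept μ0 are free
  parameters that the original study estimated from its own data. They
  were calibrated here once, before any benchmark assertion was frozen, to
  two printed properties of that cohort: σ = 0.5 so that the *true-model*
  3-year AUC on complete data is ≈ 0.89 (the reported discrimination
  level), and μ0 = 3.1 so that ≈ 21% of patients have an observed event
  (median follow-up ≈ 1.9 years). A replicate is regenerated only if a
  half contains no events at all; the no-censoring limit (all events) is a
  legitimate configuration and is kept.
* **Missingness.** MCAR: each test-half covariate cell is removed
  independently with the configured probability; time and status are never
  removed; training data stay complete.

What passing benchmarks do *not* show about real data: the generator's
dependency structure is known and sparse, its missingness is exactly MCAR,
and its effects are exactly proportional-hazards-compatible on the AFT
scale; real EHR cohorts violate all three to unknown degrees, so the
benchmark measures robustness of the *mechanism*, not expected clinical
performance.

## Comparators

Impute-then-Cox baselines share the CSBN's final Cox model and differ only
in how test covariates are completed: KNN (matching distance over observed
categoricals, k = 5, 1/(1+d)-weighted modal level; fully-missing rows get
marginal modes) and MICE (chained equations with multinomial-logistic
conditionals fit on the complete training half, 5 sweeps, m = 10 completed
datasets whose predicted risks are averaged). A random-forest imputer is
an optional adapter hook — any callable `(cohort, reference) → cohort` —
and the experiment runs without it, recording the omission.

## Evaluation

Three-year AUC uses the censoring-exclusion rule: events by the horizon
are cases, patients followed past the horizon are controls, and patients
censored earlier are excluded (IPCW time-dependent AUC is a non-goal).
AUC is Mann–Whitney pair counting with ties at one half; 95% CIs by
percentile bootstrap (1000 resamples). Harrell's C counts comparable pairs
(shorter observed time carries an event), ties in risk at one half.
Calibration is observed-vs-mean-predicted per decile of predicted risk
(degenerate bins merged); decision curves report net benefit
`TP/N − FP/N · pt/(1−pt)` over a 0–0.70 threshold grid with treat-all /
treat-none references and prevalence-standardized versions. "Risk" is
1 − predicted 3-year survival throughout.

## Problem sizes

Defaults reproduce the study design (N = 6000 per replicate, 500
replicates, missing rates 10–40%). The shipped benchmark configuration
(`default_simulation_config`) uses B = 20 bootstrap resamples, a 50-point
lambda grid and 500 weighting samples per patient — at these sizes one
replicate trains and evaluates in seconds, and the acceptance script runs
20 replicates; replicate counts scale down without changing any generator
parameter. The test suite uses 3 replicates for the directional
assertions.

## Known limitations

* Efron/exact tie conventions, stratified or time-varying Cox, competing
  risks and IPCW metrics are out of scope.
* The screen's per-variable Wald p-values use the normal approximation;
  exact small-sample inference is not attempted.
* Likelihood weighting degrades when evidence has very low prior
  probability (few effective samples); the reported MC standard error
  makes this visible but does not fix it.
* Arcs in the learned network are statistical, not causal; the domain
  whitelist/blacklist encodes prior knowledge only.
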