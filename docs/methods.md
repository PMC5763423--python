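# Methods

`ivcea` estimates complier average causal effects (CACEs) of a binary
treatment on *bivariate* cost-effectiveness outcomes — cost and QALYs — in
randomized trials with one-sided non-compliance, and propagates the
cost–QALY correlation into inference for the incremental net benefit (INB).
This note records the models, the synthetic data-generating process, the
numerical choices, and the limits of what the test suite demonstrates.

## Estimands and identification

Random allocation Z instruments treatment received D.  Under the usual IV
conditions (ignorable assignment, a non-null first stage, exclusion
restriction, monotonicity), the CACE for outcome l is identified by the Wald
ratio θ_l = {E[Y_l|Z=1] − E[Y_l|Z=0]} / {E[D|Z=1] − E[D|Z=0]}.  The package
works on a rescaled analysis scale (costs in £1000s, QALYs in 0.1-QALY
units) and reports INB(λ) = λ·ΔQALY − ΔCost and the ICER ΔCost/ΔQALY on the
natural scale, with λ defaulting to £30,000 per QALY.

## Frequentist system estimators

* **2SLS per outcome** (`TwoStageLS`): linear first stage of D on Z (kept
  linear deliberately even though D is binary — OLS residuals orthogonal to
  the instrument suffice for consistency), second stage on the projected
  regressor.  Standard errors use the homoskedastic 2SLS asymptotic
  variance with residuals formed from the *actual* regressors; the residual
  variance divisor is n, not n − k (the difference is O(k/n) and immaterial
  at the study's scales).  The effect covariance across outcomes is set to
  zero by construction: this is the "univariate IV" comparator whose INB
  intervals ignore the cost–QALY correlation, and `inb_from_system` will
  refuse to build an interval from it unless `independence=True` is passed
  explicitly.
* **3SLS** (`ThreeStageLS`): the same first two stages applied to each
  outcome, then a third feasible-GLS stage across the two-equation system
  using the residual covariance estimated from stage two (divisor n,
  two-step FGLS, not iterated).  In this just-identified setting with
  identical instruments the point estimates coincide with 2SLS equation by
  equation and the per-outcome variances are unchanged; what 3SLS adds is
  the 2×2 effect covariance that makes the INB interval correct.
* **SUR** (`SURSystem`): the same FGLS machinery with an exogenous
  regressor — the intention-to-treat analysis.
* **Naive comparators** (`NaiveSystem`): per-protocol (drop subjects whose
  received treatment differs from allocation) and as-treated (regress on D,
  ignore Z).  Under the simulator's confounding structure, subjects with a
  high confounder value are the likeliest to switch *away* from treatment,
  so the treated group is depleted of high-outcome subjects and both naive
  contrasts are biased downward.  They exist to demonstrate that bias.

All intervals are normal-theory Wald intervals (estimate ± z₀.₉₇₅·SE);
t-quantiles are never used.

## Bayesian IV models

All three models put N(0, 10²) priors on regression coefficients
(precision 0.01), N(0, 10²) on Fisher's z-transform of the outcome
correlation ρ, and Uniform(0, 10) on standard deviations.

* **uBN** — normal first stage D ~ N(β₀₀ + β₁₀Z, σ₀²); outcome means are
  linear in the first-stage *linear predictor* μ₀ (not D), with Y₂ modelled
  conditionally on Y₁ through β₂₂ = ρσ₂/σ₁ and conditional variance
  σ₂²(1−ρ²).  The error structure of D is assumed independent of the
  outcome errors — the "unadjusted" assumption whose failure produces the
  documented overcoverage and, at high non-compliance, bias.
* **uBGN** — logistic first stage; its raw residuals r = D − π enter both
  outcome equations (two-stage residual inclusion).  Costs are gamma with a
  single shape ν (prior gamma(0.01, 0.01), plus a +0.01 offset in the
  likelihood to keep the shape away from 0) and per-observation rate ν̃/μ₁ᵢ
  so that the mean follows the linear predictor.  The model statement's
  μ₁ = ν₁/κ₁ with a scalar prior on the shape cannot hold with both
  parameters scalar; the per-observation-rate reading is the standard one
  and is what is implemented.  The conditional-QALY coefficient β₂₂ =
  ρσ₂/σ₁ needs a cost SD under the gamma model: we use the per-observation
  gamma SD σ₁ᵢ = μ₁ᵢ/√ν̃.  The cost-equation intercept has a gamma(0.01,
  0.01) prior (positive support).  Strictly positive costs are required;
  zero costs should be set to missing and imputed externally.
* **BFL** — trivariate normal over (D, Y₁, Y₂) with unstructured 3×3
  covariance Σ and reduced-form means: the allocation coefficient enters
  the outcome means as the product β₁ₗ·β₁₀, so the causal effects β₁₁, β₁₂
  are parameters of the model.  Σ⁻¹ has a Wishart prior with identity scale
  and df = 4 (dimension + 1) by default; df = 6 is available as the
  sensitivity variant, and on simulated data the switch moves posterior
  medians by well under one posterior SD.

### Samplers

No general-purpose MCMC engine is used; each model has a dedicated sampler.

* uBN: Gibbs for the three coefficient blocks (each conditionally Gaussian,
  including the first-stage block, which appears in all three equations)
  and for σ₀² (inverse-gamma truncated by the uniform prior), plus a joint
  random-walk Metropolis step on (log σ₁, log σ₂, z).  Because all
  regressors are linear in [1, X, Z] and the outcomes, every conditional
  and the Metropolis target depend on the data only through one Gram
  matrix, so a sweep costs O(1) in n on complete data.
* BFL: fully conjugate three-block Gibbs — the linear coefficients given
  β₁₀, the scalar β₁₀ given the rest (the product parameterisation is
  linear in each factor separately), and Σ⁻¹ by its conjugate Wishart
  update.  Gram-matrix sufficient statistics again make sweeps O(1).
* uBGN: Metropolis-within-Gibbs.  The first-stage and cost-equation blocks
  use adaptive random-walk proposals (scalar step-size tuning toward ~30%
  acceptance plus an empirical proposal covariance learned during burn-in
  and frozen afterwards); log ν and (z, log σ₂) are further Metropolis
  blocks; the QALY-equation coefficients are conditionally Gaussian and
  Gibbs-sampled.  Without covariates, every likelihood term reduces to
  per-(Z, D)-cell sums, so Metropolis evaluations are O(1); with covariates
  the sampler falls back to vectorised O(n) evaluations.

Outcomes are centred before sampling (costs only under the normal models)
and intercepts shifted back on output; treatment effects are unaffected.
Missing outcome values are sampled as additional nodes from their
conditional normals (uBN, BFL: any pattern across Y₁/Y₂; uBGN: missing
QALYs only — the gamma cost node has no conjugate conditional, and missing
costs should be multiply imputed externally).  Covariates must be complete;
the supported route for incomplete covariates is external multiple
imputation followed by Rubin pooling.

### Protocol and convergence

`McmcProtocol` encodes the fitting policy: 2 chains, 5000 initial
iterations with 1000 burn-in, then 1000-iteration extensions until the
Geweke statistic comparing the first 10% to the last 50% of the retained
window is below 2.5 in absolute value for all monitored parameters
(treatment effects, scales/Σ entries, ρ), then a final 5000-iteration run
per chain pooled into 10,000 kept draws.  The Geweke variance uses
Bartlett-window spectral density estimates at frequency zero with
4·(n/100)^{2/9} lags.  Chains that fail after a configurable cap of
extensions are flagged (`converged=False`) and a warning is emitted —
results are returned but marked.  Posterior summaries are median, SD and
equal-tailed 95% intervals; INB and ICER are computed draw by draw and
summarised the same way.

## Synthetic trials

The generator reproduces the study conditions used throughout the tests:

* Confounder U ~ N(0.50, 0.25²), independent of allocation.
* One-sided switching S ~ Bern(p + 0.1) if u > 0.5, Bern(p − 0.1)
  otherwise, so E[S] = p exactly; D = Z except that active-arm switchers
  receive control.  p ∈ {0.3, 0.7} in the factorial design.
* Outcome means μ₁ = 1.2 + 0.4·D + 0.16(u − 0.5) (£1000s) and
  μ₂ = 0.5 + 0.2·D + 0.04(u − 0.5) (0.1-QALY units), so the true effects
  are £400 and 0.02 QALYs and the true INB at £30,000/QALY is £200.
* Outcomes drawn through a Gaussian copula with latent correlation ρ ∈
  {±0.4, ±0.8}: latent normal pairs mapped through Φ and then through the
  inverse CDF of each marginal.  QALYs are always normal(μ₂, 0.1²); costs
  are normal(μ₁, 0.2²), gamma(shape 4, mean μ₁) — conditional variances
  0.36 (control) and 0.64 (treated) at u = 0.5 — or inverse-Gaussian
  (mean μ₁, shape 4) — conditional variances 0.432 and 1.024.
* Allocation is deterministic 1:1 (rounded counts, randomly permuted),
  which removes binomial noise in arm sizes; the design never states an
  allocation ratio and a parallel 1:1 design is the natural reading.

"Correlation ρ" is implemented as the copula (latent normal) correlation.
For gamma and inverse-Gaussian costs the Pearson correlation of the
realised outcomes is slightly smaller in magnitude; the normal-scores
correlation recovers ρ for all marginals (tested).  The variance
calibrations above are conditional on u = 0.5; the marginal variances
differ by under 1% through the confounder term.

The latent confounder u and switching indicator s are stored on simulated
datasets for oracle checks only — no estimator reads them.  What the
generator does *not* emulate: two-sided or time-varying non-compliance,
censoring, missingness mechanisms (missingness is only introduced
deliberately in tests), covariate structure, or the heavy right tails of
real cost data beyond what gamma/inverse-Gaussian marginals produce.
Passing tests therefore demonstrate estimator behaviour under exactly this
confounded-compliance, copula-linked world, not robustness to real-trial
pathologies beyond it.

## Monte Carlo study

`run_scenario` spawns one RNG substream per replicate from a single seed,
so every estimator sees identical datasets (paired comparisons) and runs
are reproducible bit for bit.  Per-replicate estimator failures are
recorded and excluded from metrics with their count reported.  Metrics per
(scenario, method, estimand): median bias (absolute and % of truth —
median rather than mean because the BFL effect posterior is heavy-tailed),
empirical coverage of 95% intervals with its binomial MC standard error,
median interval width, and RMSE.  A method is flagged "adequate" when
|median bias| ≤ 5% of truth and coverage is within 2.5 points of nominal.

Problem sizes: the least-squares slices of the factorial design run at the
full M = 2500 replicates (a scenario takes ~2 s).  The Bayesian
replications in the test suite run at M = 100 replicates with a shortened
chain protocol (1200 initial iterations, 400 burn-in, 1500 kept per chain,
2 chains) — median-bias and coverage-direction checks are insensitive to
chain length at these sizes, and full-length-chain replication at
M = 2500 is a cluster-scale computation by design.  The package defaults
(`McmcProtocol()`) remain the full protocol.

## Multiple imputation

`rubin_pool` combines per-imputation system estimates in matrix form:
pooled point = mean of points, total covariance T = W̄ + (1 + 1/m)B, with
per-parameter small-sample degrees of freedom by the classical formula.
Keeping the matrix form means pooled INB inference retains the cost–QALY
cross-covariance; pooling increments first and then forming INB/ICER is
exactly equivalent to pooling per-imputation INBs at fixed λ (tested).
ICERs are reported without intervals, and the package convention is to
pool the increments first and then take the ratio.  The imputation engine
itself is out of scope — any chained-equations/PMM implementation can feed
this interface.

## Known limitations

* The homoskedasticity-robust 2SLS variance is not currently exposed; the
  homoskedastic asymptotic variance is the study's convention and the
  default everywhere.
* uBGN mixes by Metropolis steps; for very small samples or near-boundary
  shapes the Geweke loop may exhaust its extension cap and flag
  non-convergence rather than fail.
* The uBGN misspecification bias under inverse-Gaussian costs (gamma model
  fitted to IG data) reproduces in direction and exceeds the 5% adequacy
  threshold, but its magnitude depends on the β₂₂/σ₁ᵢ convention above,
  for which the model statement leaves room for interpretation.
* Weak-instrument regimes are out of scope: with one-sided binary
  non-compliance the first stage is strong for any realistic
  non-compliance rate.
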