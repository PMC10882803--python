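# Methods

## Model and estimand

A hybrid-control trial pools a two-armed RCT (treatment `T ∈ {0,1}`) with a
single historical control dataset whose participants are all controls. For
participant `i` we observe covariates `X_i ∈ ℝ⁴`, the data-source indicator
`X_{ir} ∈ {+1, −1}` (+1 = RCT), treatment `T_i` and a binary outcome `Y_i`.
The target is the average treatment effect (ATE) on the odds-ratio scale in
the entire pooled population, estimated by inverse probability of treatment
weighting (IPTW):

1. fit a logistic propensity model for `T` — either on `X` alone
   (*conventional*) or on `(X, X_r)` (*extended*);
2. weight each participant by `w = T/e + (1−T)/(1−e)` where `e` is the
   fitted propensity score;
3. fit a weighted logistic regression of `Y` on `T` (intercept + slope);
   the slope is the estimated marginal log odds ratio.

The source indicator is coded ±1 rather than 0/1 so that the fitted
coefficient of `X_r` is directly comparable with the generator's true
coefficient `b_r`.

Because every historical participant is a control, the extended fit is
quasi-completely separated in the `X_r` direction: the likelihood pushes the
historical-side intercept toward −∞ while all other coefficients remain
identified. The IRLS fit (deviance tolerance 1e-10, iteration cap 100)
terminates with historical propensity scores numerically at zero, which is
the statistically meaningful limit — historical controls receive weight
`1/(1−e) ≈ 1` and the RCT is weighted by an RCT-only propensity model. The
convergence flag reports how each fit terminated; non-penalized maximum
likelihood is used throughout (a Firth-type penalty was considered and
rejected because the drifting coordinate does not affect the weights in the
limit).

A consequence worth stating: treated-arm positivity holds only inside the
RCT, so the extended method's treated pseudo-population is the RCT
population rather than the full pooled sample. With a source effect in the
outcome model this leaves a small non-vanishing offset in the extended
estimate (≈ +0.04 at n = 900, ≈ +0.07 as n → ∞ in the dissimilar design) —
far smaller than the conventional model's confounding bias (≈ +0.17), which
is the comparison of interest.

## Variance estimator

The variance of the weighted slope uses a robust HC0 sandwich with the
weights treated as fixed and known,
`B⁻¹ M B⁻¹` with `B = Σ wᵢ μᵢ(1−μᵢ) xᵢxᵢᵀ` and `M = Σ wᵢ²(Yᵢ−μᵢ)² xᵢxᵢᵀ`,
with 95% Wald intervals and a matching two-sided p-value (so "p < 0.05" and
"CI excludes 0" coincide exactly). A 600-replicate diagnostic at n = 900
shows the mean sandwich SE matches the empirical sampling standard
deviation of the estimator within 1%. The model-based variance
(`variance="model"`) is retained for sensitivity analyses only; with ATE
weights it is strongly anticonservative (it treats the ≈2n pseudo-population
as real observations). Power and coverage are sensitive to even 1–2%
differences in the SE in the steep region of the power curve, which bounds
how closely any reimplementation can match a third party's published
percentages without knowing their exact variance estimator.

## Synthetic-data generator

The generator emulates a hybrid design with total size `n` split
deterministically by the allocation ratio (RCT-treatment : RCT-control :
historical), default 1:1:2 — e.g. n = 900 gives 450 RCT and 450 historical
participants. All randomness flows from one master seed through
per-replicate `SeedSequence` substreams, with separate child streams for
covariates, treatment, noise and outcomes so that design variants stay
coupled across runs; replaying a stored trace reproduces `T` and `Y`
exactly.

**Covariates.** Four standard-normal covariates per participant. In the
*similar* regime (scenario I) both arms use them untransformed. In the
*dissimilar* regime (scenario II) the RCT rows are transforms of the same
underlying draw `X′`: `X₁ = X′₁ − 1`, `X₂ = 0.7·X′₂`, `X₃ = ln|X′₃|`,
`X₄ = X′₄` (historical rows stay untransformed). `E[ln|Z|] = −(γ + ln 2)/2 ≈
−0.635` is used as an analytic cross-check of the third transform. A
variant replaces one covariate by a Bernoulli(0.5) {0,1} draw in both arms
(the transform skips that column; its coefficient is unchanged) — the
dichotomization rule is a package choice since only the fact of a binary
covariate is specified.

**Treatment.** RCT participants draw `T ~ Bernoulli(expit(b₀ + Xβ))` with
true slopes `β = (1.00, −0.50, 0.25, 0.10)`; historical participants have
`T = 0` with probability one. A fully randomized variant assigns
`T ~ Bernoulli(t/(t+c))` independent of covariates.

**Outcome.** `logit Pr(Y=1) = a₀ + β_treat·T + Xα [+ α_r X_r] + ε/100`
with `α = (0.274, 0.137, −0.137, 0.137)`, `α_r = 0.137` present only in the
dissimilar regime (making the data source a true confounder there), and
`ε ~ N(0,1)` drawn once per participant. `β_treat` is the true conditional
log odds ratio.

What the generator does **not** emulate: multiple heterogeneous historical
datasets, missing data, measurement drift between study periods, or
non-binary endpoints. Passing tests therefore demonstrate the estimator's
behaviour under a clean, known confounding structure, not robustness to
real-world data pathologies.

## Calibration of b₀, a₀, b_r

Three constants anchor a design cell; all are solved numerically rather
than tabulated, so any allocation ratio and event rate is supported.

- `b₀` solves `E[expit(b₀ + Xβ)] = t/(t+c)` over the RCT covariate law
  (similar: 0 by symmetry for 1:1; dissimilar 1:1: ≈ 1.157, compensating
  `E[X₁] = −1` and `E[X₃] ≈ −0.635`).
- `b_r` (dissimilar only): writing the true extended model's intercept as
  `b₀ − b_r`, the model must reduce to the RCT-only model at `X_r = +1` and
  have mean-zero logit over the historical covariate law at `X_r = −1`,
  giving `b_r = (b₀ + E_HC[X]·β)/2 = b₀/2` for zero-mean historical
  covariates.
- `a₀` solves for the marginal event probability among controls (pooled
  RCT controls + historical controls at the design ratio) equal to the
  target event rate, by simulating the full generative chain. Anchoring
  the control arm makes the realized event rate invariant to the true odds
  ratio, which keeps a rate-by-OR design grid coherent.

Numerics: Brent root-finding on [−20, 20] over a common-random-number
Monte-Carlo estimate of the anchored probability (default 2×10⁶ draws,
fixed calibration seed, `xtol` 1e-10); an unbracketed target raises a
calibration error. The expectation is strictly increasing in the intercept,
so the root is unique. Quadrature was rejected because the `ln|·|`
transform makes the linear predictor non-Gaussian. Closed-loop tests
confirm that simulating 10⁶ participants recovers the treated fraction and
control event rate within 3 combined Monte-Carlo standard errors.
Constants are cached per design (they do not depend on the odds ratio).

## Operating characteristics

Per design cell, `n_reps` independent replicates are simulated and
analyzed with both propensity-score variants; summaries are on the
log-odds-ratio scale:

- bias `= mean(log ÔR) − ln(OR_true)`,
- MSE `= mean[(log ÔR − ln OR_true)²]`,
- coverage `= %` of 95% CIs containing `ln OR_true`,
- rejection `= %` of p-values < 0.05 (type I error at OR 1, power
  otherwise),

with Monte-Carlo standard errors (`√(p(1−p)/R)` for proportions, sample-SD
based for bias). Replicates whose fits are degenerate (an arm with no
events or no non-events) or non-convergent are excluded and counted — at
event rate 50% and n = 900 this is essentially never; at n = 200 and rate
5% unstable fits are expected and the exclusion count matters. Cells are
reproducible from `(seed, replicate index)` and independent of execution
order; studies run serially (a single weighted-GLM replicate costs ~15 ms,
so a 10,000-replicate cell is minutes, not hours).

Reference runs in the test suite use 6,000 replicates per cell at n = 900
(2,000 for the randomized-assignment variant), chosen to keep Monte-Carlo
standard errors on percentage measurements near 0.3 points; the acceptance
script uses 5,000.

## Known limitations

- The dissimilar-regime reference cells (bias, coverage, type I error,
  power orderings) reproduce published hybrid-design results closely, but
  percentage-scale quantities in steep power regions can differ by ~1–2
  points across equally defensible variance estimators; the directional
  conclusions (conventional model's type I inflation under dissimilarity,
  extended model's near-nominal behaviour) are insensitive to this.
- In the similar regime the conventional model's MSE here is smaller than
  some published analogues (~0.03 vs ~0.045 at OR 1, rate 50%); the fitted
  pooled propensity model is intrinsically misspecified in a hybrid design
  (true pooled `Pr(T=1|X)` is bounded by the RCT fraction), and published
  accounts do not specify the fitting details needed to close that gap.
- ATT estimation, propensity-score matching, Bayesian borrowing, multiple
  historical datasets, and survival/continuous endpoints are out of scope.
- Extremely skewed allocation ratios (e.g. a near-empty RCT control arm)
  are rejected with an estimation error rather than estimated unstably.
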