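# hybridps

Propensity-score IPTW estimation of a treatment odds ratio for clinical
trials that augment a randomized controlled trial (RCT) with historical
control data, plus a Monte-Carlo framework for the operating
characteristics of such hybrid designs.

## The problem

In trials on rare or intractable diseases it can be unethical or
infeasible to randomize enough participants to a control arm, so the
concurrent control group is supplemented with historical control data
(a registry, natural-history study, or earlier trial). Pooling the two
data sources naively ignores that "being in the RCT" may itself be a
confounder: historical patients can differ systematically in both baseline
characteristics and outcome level.

`hybridps` implements and evaluates two propensity-score models for a
binary outcome `Y`, treatment indicator `T`, covariates `X₁..Xₖ` and a
data-source indicator `X_r` (+1 = RCT participant, −1 = historical
control):

- **conventional**:  `logit Pr(T=1 | X) = β₀ + β₁X₁ + … + βₖXₖ`
- **extended**:      `logit Pr(T=1 | X, X_r) = β₀ + β₁X₁ + … + βₖXₖ + β_r X_r`

Each participant is weighted by the inverse probability of the treatment
actually received, `w = T/e + (1−T)/(1−e)` with `e` the fitted propensity
score (ATE weights over the pooled sample), and the marginal log odds
ratio is the treatment coefficient of a weighted logistic regression of
`Y` on `T`. Confidence intervals use a robust sandwich (HC0) variance with
the weights treated as fixed.

The simulator generates hybrid trials under two regimes: covariate
distributions that are **similar** between RCT and historical data
(scenario I) and **dissimilar** (scenario II, where the RCT covariates are
shifted, rescaled and log-|·|-transformed versions of standard-normal
draws). Design constants — the treatment-allocation intercept `b₀`, the
event-rate intercept `a₀`, and the source-indicator coefficient `b_r` —
are calibrated numerically so that any allocation ratio and control-arm
event rate can be targeted exactly.

## Worked example

Calibrate a dissimilar-covariates design (event rate 50%, true OR 2,
allocation 1:1:2), simulate one 900-participant trial, and estimate the
treatment effect with both propensity models:

```bash
hybridps calibrate --scenario II --event-rate 0.5 --or 2.0 --out constants.json
# wrote constants.json: b0=1.158036 a0=0.136513 br=0.579018
hybridps simulate --scenario II --n 900 --event-rate 0.5 --or 2.0 \
    --seed 7 --constants constants.json --out trial.csv
# wrote trial.csv (n=900, RCT=450, HC=450)
hybridps estimate --data trial.csv
```

```json
{
  "conventional": {
    "log_or": 0.9059954961622447,
    "or": 2.474393947064606,
    "se": 0.1622901679078627,
    "ci_95": [0.5879126120178757, 1.2240783803066138],
    "p_value": 2.3699627652965626e-08,
    "converged": true
  },
  "extended": {
    "log_or": 0.9395080751671137,
    "or": 2.558722409592088,
    "se": 0.18604245610298145,
    "ci_95": [0.574871561609896, 1.3041445887243313],
    "p_value": 4.4188874098846863e-07,
    "converged": true
  }
}
```

Both models detect the effect in this replicate (true log OR = ln 2 ≈
0.693); over many replicates the conventional model is systematically
biased upward under dissimilar covariates (~+0.17 at the null) while the
extended model stays close to the truth with near-nominal type I error —
run a study to see this:

```bash
hybridps study --config grid.yaml --out-dir results/
```

with a YAML grid such as

```yaml
scenarios: [II]
n_totals: [900]
ratios: [[1, 1, 2]]
event_rates: [0.5]
odds_ratios: [1.0, 2.0]
n_reps: 5000
seed: 1
```

which writes one CSV per scenario/sample size with bias, MSE, 95%-CI
coverage and rejection rate (type I error at OR 1, power otherwise) per
propensity-score variant, event rate and odds ratio, plus a manifest with
the calibrated constants and convergence counts.

The same estimator runs on your own data: a CSV with columns
`id,x1,…,xk,source,treatment,outcome` where `source` may be coded
`RCT`/`HC`, `1`/`0`, or `1`/`-1`.

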