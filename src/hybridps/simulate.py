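"""Synthetic hybrid-trial generator.

Generates participant-level datasets in which a two-armed RCT is pooled with
a historical control dataset.  Two scenarios are supported: similar covariate
distributions between the two sources (scenario I: all four covariates are
standard normal in both arms) and dissimilar distributions (scenario II: the
RCT covariates are deterministic transforms of an underlying standard-normal
draw — a location shift, a scale change, and a log-absolute-value — while the
historical covariates stay untransformed).

Treatment within the RCT is Bernoulli with probability expit of the true
propensity linear predictor (or covariate-independent under the fully
randomized variant); historical participants are controls with probability
one.  The binary outcome is Bernoulli with logit equal to the true outcome
model, which includes a small participant-level perturbation ``eps/100``
with ``eps ~ N(0, 1)``, and — in the dissimilar scenario — a source-indicator
term, making the data source a genuine confounder.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from .calibration import CovariateLaw
from .model_types import (
    CalibrationConstants,
    ConfigurationError,
    DesignConfig,
    TrialDataset,
)

__all__ = [
    "GenerationTrace",
    "generate_covariates",
    "assign_source",
    "assign_treatment",
    "generate_outcomes",
    "make_binary_covariate",
    "simulate_trial",
    "replicate_seed_sequence",
]


@dataclass(frozen=True)
class GenerationTrace:
    """Everything needed to replay one simulated trial exactly.

    ``(u < expit(lp))`` on the stored uniforms and linear predictors
    regenerates the realized treatment and outcome vectors bit for bit.
    """

    linear_predictor_ps: np.ndarray  # per RCT participant
    uniforms_treatment: np.ndarray  # per RCT participant
    linear_predictor_outcome: np.ndarray  # per participant, incl. eps/100
    uniforms_outcome: np.ndarray  # per participant
    noise: np.ndarray  # eps per participant (before /100)
    covariates_underlying: np.ndarray | None  # X' (scenario II), else None
    constants_used: CalibrationConstants
    seed_chain: tuple[int, ...]


def replicate_seed_sequence(
    master_seed: int, replicate_index: int
) -> np.random.SeedSequence:
    """Per-replicate seed substream: independent across replicates,
    reproducible from (master seed, replicate index)."""
    return np.random.SeedSequence([int(master_seed), int(replicate_index)])


def generate_covariates(
    n: int,
    law: CovariateLaw,
    rng: np.random.Generator,
    return_underlying: bool = False,
):
    """Draw an ``n x 4`` covariate matrix under the given arm law."""
    return law.sample(n, rng, return_underlying=return_underlying)


def assign_source(n_total: int, ratio: tuple[int, int, int]) -> np.ndarray:
    """Deterministic source split: the first ``round(n*(t+c)/(t+c+h))``
    participants are RCT (+1), the remainder historical (-1).

    The split is not sampled: the design fixes the allocation ratio and the
    total sample size exactly.
    """
    t, c, h = ratio
    if t <= 0 or c <= 0 or h <= 0:
        raise ConfigurationError("all ratio components must be positive")
    n_rct = int(round(n_total * (t + c) / (t + c + h)))
    source = np.full(n_total, -1, dtype=np.int64)
    source[:n_rct] = 1
    return source


def assign_treatment(
    covariates: np.ndarray,
    source: np.ndarray,
    constants: CalibrationConstants,
    scenario: str,
    rng: np.random.Generator,
    randomized_rct: bool = False,
    treat_fraction_rct: float = 0.5,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli treatment assignment within the RCT; historical rows get 0.

    For RCT participants the success probability is expit of the true
    propensity linear predictor ``b0 + X @ beta`` (identical in both
    scenarios once the intercept is written on the RCT side: the
    source-indicator term of the scenario II true model cancels into the
    intercept when ``X_r = +1``).  Under ``randomized_rct`` the probability
    is the constant design fraction ``t/(t+c)`` instead.

    Returns ``(treatment, linear_predictor_rct, uniforms_rct)``.
    """
    is_rct = source == 1
    n_rct = int(np.sum(is_rct))
    if randomized_rct:
        lp = np.full(n_rct, float(np.log(treat_fraction_rct / (1 - treat_fraction_rct))))
    else:
        lp = constants.b0 + covariates[is_rct] @ np.asarray(constants.beta)
    u = rng.random(n_rct)
    treatment = np.zeros(len(source), dtype=np.int64)
    treatment[is_rct] = (u < expit(lp)).astype(np.int64)
    return treatment, lp, u


def generate_outcomes(
    covariates: np.ndarray,
    source: np.ndarray,
    treatment: np.ndarray,
    constants: CalibrationConstants,
    scenario: str,
    rng: np.random.Generator,
    rng_noise: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Bernoulli outcomes from the true outcome model.

    The logit is ``a0 + beta_treat*T + X @ alpha (+ alpha_r * X_r) + eps/100``
    with ``eps ~ N(0,1)`` drawn once per participant; the source-indicator
    term is present only in the dissimilar-covariates scenario.  A separate
    ``rng_noise`` stream may feed the perturbation draws.

    Returns ``(outcome, linear_predictor, eps, uniforms)``.
    """
    n = len(source)
    eps = (rng_noise or rng).standard_normal(n)
    lp = (
        constants.a0
        + constants.beta_treat * treatment
        + covariates @ np.asarray(constants.alpha)
        + eps / 100.0
    )
    if scenario == "II":
        lp = lp + constants.alpha_r * source
    u = rng.random(n)
    outcome = (u < expit(lp)).astype(np.int64)
    return outcome, lp, eps, u


def make_binary_covariate(
    dataset: TrialDataset, index: int, rng: np.random.Generator
) -> TrialDataset:
    """Replace one covariate with a fresh Bernoulli(0.5) {0,1} column.

    The binary covariate has the same law in both arms and keeps its
    coefficient; in generated data the replacement happens inside
    :class:`~hybridps.calibration.CovariateLaw` before the dissimilar-arm
    transforms touch the other columns.
    """
    if not (1 <= index <= dataset.k):
        raise ConfigurationError(f"covariate index {index} out of range 1..{dataset.k}")
    cov = dataset.covariates.copy()
    cov[:, index - 1] = (rng.random(dataset.n) < 0.5).astype(float)
    return TrialDataset(
        covariates=cov,
        source=dataset.source,
        treatment=dataset.treatment,
        outcome=dataset.outcome,
        participant_id=dataset.participant_id,
    )


def simulate_trial(
    config: DesignConfig,
    constants: CalibrationConstants,
    replicate_index: int = 0,
) -> tuple[TrialDataset, GenerationTrace]:
    """Generate one trial dataset for a design cell.

    Separate RNG substreams feed covariates, treatment, noise and outcomes,
    so variant toggles (e.g. ``randomized_rct``) leave the other draws
    coupled across configurations.
    """
    ss = replicate_seed_sequence(config.seed, replicate_index)
    rng_cov, rng_treat, rng_noise, rng_out = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    source = assign_source(config.n_total, config.ratio)
    n_rct = int(np.sum(source == 1))
    n_hc = config.n_total - n_rct
    rct_law = CovariateLaw(
        config.scenario, "RCT", binary_covariate_index=config.binary_covariate_index
    )
    hc_law = CovariateLaw(
        config.scenario, "HC", binary_covariate_index=config.binary_covariate_index
    )
    x_rct, xp_rct = rct_law.sample(n_rct, rng_cov, return_underlying=True)
    parts = [x_rct]
    xp_parts = [xp_rct]
    if n_hc:
        x_hc, xp_hc = hc_law.sample(n_hc, rng_cov, return_underlying=True)
        parts.append(x_hc)
        xp_parts.append(xp_hc)
    covariates = np.vstack(parts)

    treatment, lp_ps, u_treat = assign_treatment(
        covariates,
        source,
        constants,
        config.scenario,
        rng_treat,
        randomized_rct=config.randomized_rct,
        treat_fraction_rct=config.treat_fraction_rct,
    )
    outcome, lp_out, eps, u_out = generate_outcomes(
        covariates,
        source,
        treatment,
        constants,
        config.scenario,
        rng_out,
        rng_noise=rng_noise,
    )

    dataset = TrialDataset(
        covariates=covariates,
        source=source,
        treatment=treatment,
        outcome=outcome,
    )
    trace = GenerationTrace(
        linear_predictor_ps=lp_ps,
        uniforms_treatment=u_treat,
        linear_predictor_outcome=lp_out,
        uniforms_outcome=u_out,
        noise=eps,
        covariates_underlying=np.vstack(xp_parts) if config.scenario == "II" else None,
        constants_used=constants,
        seed_chain=(config.seed, replicate_index),
    )
    return dataset, trace
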