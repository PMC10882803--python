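"""Numerical calibration of the true-model intercepts and indicator slope.

The generative model for a simulated hybrid trial has three free constants
that pin the design down to its targets:

``b0``
    intercept of the true propensity model within the RCT, chosen so that
    the expected treated fraction among RCT participants equals the design
    allocation (e.g. 1/2 for a 1:1 RCT split);
``a0``
    intercept of the true outcome model, chosen so that the marginal event
    rate among control participants (pooled RCT controls and historical
    controls at the design ratio) equals the target event rate — anchoring
    the control arm makes the rate invariant to the true odds ratio;
``br``
    coefficient of the source indicator ``X_r`` in the true propensity model
    of the dissimilar-covariates scenario.  Writing its intercept as
    ``b0 - br``, the model reduces to the RCT-only model when ``X_r = +1``,
    and ``br`` is fixed by requiring the linear predictor to have mean zero
    over the historical covariate law when ``X_r = -1`` — with zero-mean
    historical covariates this gives ``br = b0 / 2``.

The intercepts are found by bisection (Brent) on a Monte-Carlo estimate of
the anchored probability, using common random numbers across root-finder
iterations so the solve is deterministic given its seed.  Quadrature is not
used because the ``ln|Z|`` covariate transform makes the linear-predictor
distribution non-Gaussian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from .model_types import (
    BETA_TRUE,
    CalibrationConstants,
    ConfigurationError,
    DesignConfig,
)

__all__ = [
    "CovariateLaw",
    "CalibrationTargets",
    "CalibrationError",
    "LN_ABS_NORMAL_MEAN",
    "solve_b0",
    "solve_br",
    "solve_a0",
    "calibrate_design",
]

#: E[ln|Z|] for Z ~ N(0,1): -(Euler-Mascheroni + ln 2) / 2.
LN_ABS_NORMAL_MEAN: float = -(np.euler_gamma + np.log(2.0)) / 2.0

_BRACKET = (-20.0, 20.0)


class CalibrationError(RuntimeError):
    """The calibration target cannot be bracketed or met."""


@dataclass(frozen=True)
class CovariateLaw:
    """Distribution of the four baseline covariates in one arm.

    Historical-control covariates are standard normal in both scenarios.
    RCT covariates in the dissimilar scenario are transforms of a common
    underlying standard-normal draw ``X'``:
    ``X1 = X'1 - 1``, ``X2 = 0.7 X'2``, ``X3 = ln|X'3|``, ``X4 = X'4``.
    An optional covariate (1-based index) is replaced by a Bernoulli(0.5)
    {0,1} draw in both arms, exempt from the transforms.
    """

    scenario: Literal["I", "II"]
    arm: Literal["RCT", "HC"]
    k: int = 4
    binary_covariate_index: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("I", "II"):
            raise ConfigurationError("scenario must be 'I' or 'II'")
        if self.arm not in ("RCT", "HC"):
            raise ConfigurationError("arm must be 'RCT' or 'HC'")
        if self.binary_covariate_index is not None and not (
            1 <= self.binary_covariate_index <= self.k
        ):
            raise ConfigurationError("binary_covariate_index out of range")

    @property
    def transformed(self) -> bool:
        return self.scenario == "II" and self.arm == "RCT"

    def sample(
        self, n: int, rng: np.random.Generator, return_underlying: bool = False
    ):
        """Draw ``n`` covariate rows; optionally return the underlying X'."""
        if n < 1:
            raise ConfigurationError("n must be >= 1")
        x_prime = rng.standard_normal((n, self.k))
        x = self._transform(x_prime)
        if self.binary_covariate_index is not None:
            j = self.binary_covariate_index - 1
            x[:, j] = (rng.random(n) < 0.5).astype(float)
        return (x, x_prime) if return_underlying else x

    def _transform(self, x_prime: np.ndarray) -> np.ndarray:
        x = x_prime.copy()
        if self.transformed:
            x[:, 0] = x_prime[:, 0] - 1.0
            x[:, 1] = x_prime[:, 1] * 0.7
            with np.errstate(divide="ignore"):
                x[:, 2] = np.log(np.abs(x_prime[:, 2]))
            # column 4 unchanged
        return x

    def mean(self) -> np.ndarray:
        """Closed-form covariate mean vector under this law."""
        m = np.zeros(self.k)
        if self.transformed:
            m[0] = -1.0
            m[2] = LN_ABS_NORMAL_MEAN
        if self.binary_covariate_index is not None:
            m[self.binary_covariate_index - 1] = 0.5
        return m


@dataclass(frozen=True)
class CalibrationTargets:
    """Design anchors and Monte-Carlo settings for the intercept solves."""

    treat_fraction_rct: float
    event_rate: float
    rct_fraction: float = 0.5
    mc_draws: int = 2_000_000
    tolerance: float = 1e-4
    seed: int = 20240222

    def __post_init__(self) -> None:
        if not (0.0 < self.treat_fraction_rct < 1.0):
            raise ConfigurationError("treat_fraction_rct must lie in (0,1)")
        if not (0.0 < self.event_rate < 1.0):
            raise ConfigurationError("event_rate must lie in (0,1)")
        if not (0.0 < self.rct_fraction <= 1.0):
            raise ConfigurationError("rct_fraction must lie in (0,1]")
        if self.tolerance <= 0:
            raise ConfigurationError("tolerance must be positive")
        if self.mc_draws < 10_000:
            raise ConfigurationError("mc_draws must be at least 10,000")

    @classmethod
    def from_config(
        cls, config: DesignConfig, mc_draws: int = 2_000_000, seed: int | None = None
    ) -> "CalibrationTargets":
        return cls(
            treat_fraction_rct=config.treat_fraction_rct,
            event_rate=config.event_rate,
            rct_fraction=config.rct_fraction,
            mc_draws=mc_draws,
            seed=config.seed if seed is None else seed,
        )


def _solve_intercept(lp_without_intercept: np.ndarray, target: float) -> float:
    """Root of mean(expit(c + lp)) = target over a fixed Monte-Carlo sample.

    The mean is strictly increasing in ``c``, so a sign change over the
    bracket guarantees a unique root.
    """

    def f(c: float) -> float:
        return float(np.mean(expit(c + lp_without_intercept))) - target

    lo, hi = _BRACKET
    flo, fhi = f(lo), f(hi)
    if not (flo < 0.0 < fhi):
        raise CalibrationError(
            f"target {target} not bracketed on [{lo}, {hi}] "
            f"(f({lo})={flo:.3g}, f({hi})={fhi:.3g})"
        )
    return float(brentq(f, lo, hi, xtol=1e-10))


def solve_b0(
    law: CovariateLaw,
    beta: np.ndarray | tuple[float, ...] = BETA_TRUE,
    targets: CalibrationTargets | None = None,
) -> float:
    """Treatment-allocation intercept for the true propensity model.

    Returns ``b0`` such that ``E[expit(b0 + X @ beta)]`` over the RCT
    covariate law equals ``targets.treat_fraction_rct``.  Deterministic
    given ``targets.seed`` (common random numbers across iterations).
    """
    if law.arm != "RCT":
        raise ConfigurationError("b0 is defined over the RCT covariate law")
    if targets is None:
        targets = CalibrationTargets(treat_fraction_rct=0.5, event_rate=0.5)
    rng = np.random.default_rng(targets.seed)
    x = law.sample(targets.mc_draws, rng)
    lp = x @ np.asarray(beta, dtype=float)
    return _solve_intercept(lp, targets.treat_fraction_rct)


def solve_br(
    b0: float,
    hc_law: CovariateLaw,
    beta: np.ndarray | tuple[float, ...] = BETA_TRUE,
) -> float:
    """Source-indicator coefficient of the true propensity model.

    With the true-model intercept written as ``b0 - br``, ``br`` is the
    unique value for which the linear predictor (i) reduces to the RCT-only
    model when ``X_r = +1`` and (ii) has expectation zero over the
    historical covariate law when ``X_r = -1``:

        E[(b0 - br) + X @ beta - br] = 0  =>  br = (b0 + E[X] @ beta) / 2.

    Only defined for the dissimilar-covariates scenario; the similar
    scenario has no source indicator in its true model.
    """
    if hc_law.scenario != "II":
        raise ConfigurationError(
            "br is only defined for scenario II (no X_r in the scenario I true model)"
        )
    if hc_law.arm != "HC":
        raise ConfigurationError("br is anchored on the historical covariate law")
    beta = np.asarray(beta, dtype=float)
    return float((b0 + hc_law.mean() @ beta) / 2.0)


def solve_a0(
    rct_law: CovariateLaw,
    hc_law: CovariateLaw,
    constants: CalibrationConstants,
    targets: CalibrationTargets,
    scenario: Literal["I", "II"],
    randomized_rct: bool = False,
) -> float:
    """Event-rate intercept for the true outcome model.

    Simulates the full generative chain (source split at the design ratio,
    covariate draw per arm, treatment assignment from the true propensity
    model) and returns ``a0`` such that the marginal event probability among
    control participants (``T = 0``) equals ``targets.event_rate``.  The
    treatment term drops out on the control pool, so the calibrated rate is
    invariant to the true odds ratio.
    """
    rng = np.random.default_rng(np.random.SeedSequence([targets.seed, 7]))
    n = targets.mc_draws
    n_rct = int(round(n * targets.rct_fraction))
    n_hc = n - n_rct

    x_rct = rct_law.sample(n_rct, rng)
    # treatment assignment within the RCT (historical draws are all controls)
    if randomized_rct:
        p_treat = np.full(n_rct, targets.treat_fraction_rct)
    else:
        p_treat = expit(constants.b0 + x_rct @ np.asarray(constants.beta))
    treated = rng.random(n_rct) < p_treat

    alpha = np.asarray(constants.alpha, dtype=float)
    lp_parts = [x_rct[~treated] @ alpha]
    if n_hc:
        x_hc = hc_law.sample(n_hc, rng)
        lp_parts.append(x_hc @ alpha)
    lp = np.concatenate(lp_parts)
    if scenario == "II":
        x_r = np.concatenate(
            [np.ones(np.sum(~treated)), -np.ones(n_hc)]
        )
        lp = lp + constants.alpha_r * x_r
    lp = lp + rng.standard_normal(lp.shape[0]) / 100.0
    return _solve_intercept(lp, targets.event_rate)


def calibrate_design(
    config: DesignConfig,
    mc_draws: int = 2_000_000,
    seed: int | None = None,
) -> CalibrationConstants:
    """Solve (b0, br, a0) for one design cell and bundle the true coefficients.

    ``seed`` defaults to a fixed calibration seed independent of the
    simulation seed, so the same design always yields the same constants.
    """
    targets = CalibrationTargets.from_config(
        config, mc_draws=mc_draws, seed=20240222 if seed is None else seed
    )
    rct_law = CovariateLaw(
        config.scenario, "RCT", binary_covariate_index=config.binary_covariate_index
    )
    hc_law = CovariateLaw(
        config.scenario, "HC", binary_covariate_index=config.binary_covariate_index
    )
    b0 = solve_b0(rct_law, BETA_TRUE, targets)
    br = solve_br(b0, hc_law, BETA_TRUE) if config.scenario == "II" else 0.0
    constants = CalibrationConstants(b0=b0, a0=0.0, br=br, beta_treat=config.log_or)
    a0 = solve_a0(
        rct_law,
        hc_law,
        constants,
        targets,
        config.scenario,
        randomized_rct=config.randomized_rct,
    )
    return CalibrationConstants(b0=b0, a0=a0, br=br, beta_treat=config.log_or)
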