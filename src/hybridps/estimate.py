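"""Treatment-effect estimation by propensity-score IPTW.

Two propensity-score model variants are compared throughout:

``conventional``
    logistic regression of treatment on the baseline covariates only,
    ``logit Pr(T=1|X) = b0 + b1 X1 + ... + bk Xk``;
``extended``
    the same model plus the data-source indicator ``X_r`` (+1 RCT,
    -1 historical) as an additional covariate.

Each participant is weighted by the inverse probability of the treatment
actually received, ``w = T/e + (1-T)/(1-e)`` with ``e`` the fitted
propensity score (ATE weights over the pooled sample), and the treatment
log odds ratio is the slope of a weighted logistic regression of the
outcome on treatment alone.  The default variance is a robust sandwich
(HC0) treating the weights as fixed — standard IPTW practice; the
model-based variance is available for sensitivity analyses.

Because every historical participant is a control, the extended fit is
subject to quasi-complete separation on ``X_r``: the likelihood drives the
historical-side intercept toward minus infinity while all other
coefficients stay identified.  The iteratively reweighted least-squares fit
stops when the deviance stabilizes, leaving the historical propensity
scores near zero (so historical controls receive weight near one); the
convergence flag reports how the fit terminated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit
from statsmodels.tools.sm_exceptions import PerfectSeparationWarning

from .model_types import EffectEstimate, TrialDataset, ValidationError

__all__ = [
    "EstimationError",
    "PSFit",
    "WeightVector",
    "PS_CLIP",
    "fit_ps",
    "iptw_weights",
    "estimate_effect",
    "analyze",
]

#: Propensity scores are clipped to [PS_CLIP, 1 - PS_CLIP] before weighting.
#: This guards numerical overflow only; no weight trimming is applied.
PS_CLIP: float = 1e-6

_MAX_ITER = 100
_Z975 = float(stats.norm.ppf(0.975))


class EstimationError(RuntimeError):
    """The dataset does not support the requested estimation."""


@dataclass(frozen=True)
class PSFit:
    """Fitted propensity-score model."""

    coefficients: np.ndarray  # intercept, slopes[, source indicator]
    ps: np.ndarray  # fitted Pr(T=1|...) per participant, clipped into (0,1)
    variant: str
    converged: bool
    max_abs_score: float  # largest ML score-equation residual


@dataclass(frozen=True)
class WeightVector:
    """Inverse-probability-of-treatment weights (ATE)."""

    w: np.ndarray
    variant: str
    clipped_count: int


def _design_matrix(dataset: TrialDataset, variant: str) -> np.ndarray:
    cols = [np.ones(dataset.n), dataset.covariates]
    if variant == "extended":
        cols.append(dataset.source[:, None].astype(float))
    elif variant != "conventional":
        raise ValueError(f"unknown PS variant {variant!r}")
    return np.column_stack(cols)


def fit_ps(dataset: TrialDataset, variant: str = "conventional") -> PSFit:
    """Maximum-likelihood logistic propensity-score fit.

    Raises :class:`EstimationError` when the sample has no treated or no
    control participants; otherwise always returns a fit, flagging
    non-convergence instead of failing.
    """
    t = dataset.treatment.astype(float)
    n_treated = int(t.sum())
    if n_treated == 0 or n_treated == dataset.n:
        raise EstimationError(
            "propensity model needs at least one treated and one control participant"
        )
    exog = _design_matrix(dataset, variant)
    model = sm.GLM(t, exog, family=sm.families.Binomial())
    try:
        with warnings.catch_warnings():
            # quasi-complete separation on X_r is expected and handled:
            # the drifting coordinate leaves the weights at their limit
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(maxiter=_MAX_ITER, tol=1e-10)
        params = np.asarray(res.params)
        converged = bool(getattr(res, "converged", True))
    except Exception:  # singular IRLS step under extreme separation
        params = np.zeros(exog.shape[1])
        converged = False
    if not np.all(np.isfinite(params)):
        params = np.nan_to_num(params, nan=0.0, posinf=0.0, neginf=0.0)
        converged = False
    ps_raw = expit(exog @ params)
    score = exog.T @ (t - ps_raw)
    return PSFit(
        coefficients=params,
        ps=np.clip(ps_raw, PS_CLIP, 1.0 - PS_CLIP),
        variant=variant,
        converged=converged,
        max_abs_score=float(np.max(np.abs(score))),
    )


def iptw_weights(treatment: np.ndarray, ps: np.ndarray, variant: str = "conventional") -> WeightVector:
    """ATE weights ``w = T/e + (1-T)/(1-e)`` with overflow-guard clipping.

    Every weight is >= 1: a treated participant gets ``1/e``, a control
    ``1/(1-e)``.
    """
    treatment = np.asarray(treatment)
    ps = np.asarray(ps, dtype=float)
    if treatment.shape != ps.shape:
        raise ValidationError("treatment and propensity-score vectors differ in length")
    clipped = int(np.sum((ps < PS_CLIP) | (ps > 1.0 - PS_CLIP)))
    e = np.clip(ps, PS_CLIP, 1.0 - PS_CLIP)
    w = treatment / e + (1 - treatment) / (1.0 - e)
    return WeightVector(w=w, variant=variant, clipped_count=clipped)


def _sandwich_se(
    exog: np.ndarray, y: np.ndarray, mu: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """HC0 sandwich standard errors for a weighted logistic fit,
    treating the weights as fixed and known."""
    info = exog.T @ (exog * (w * mu * (1.0 - mu))[:, None])
    meat = exog.T @ (exog * (w**2 * (y - mu) ** 2)[:, None])
    bread = np.linalg.inv(info)
    return np.sqrt(np.diag(bread @ meat @ bread))


def estimate_effect(
    dataset: TrialDataset,
    weights: WeightVector,
    variance: str = "sandwich",
) -> EffectEstimate:
    """Weighted logistic regression of outcome on treatment (intercept only
    otherwise); the slope is the estimated marginal log odds ratio.

    The 95% CI is Wald (estimate +/- z_{0.975} * SE) with a matching
    two-sided p-value, so rejection at the 5% level and CI exclusion of
    zero coincide exactly.  ``variance`` selects the robust sandwich
    (default) or the model-based estimator.
    """
    if variance not in ("sandwich", "model"):
        raise ValueError("variance must be 'sandwich' or 'model'")
    w = np.asarray(weights.w, dtype=float)
    if w.shape[0] != dataset.n:
        raise ValidationError("weights are not aligned with the dataset")
    y = dataset.outcome.astype(float)
    t = dataset.treatment.astype(float)
    exog = np.column_stack([np.ones(dataset.n), t])

    # a weighted logistic fit is degenerate if an arm has no events or no
    # non-events; flag rather than fail
    degenerate = any(
        y[t == arm].min(initial=1.0) == 1.0 or y[t == arm].max(initial=0.0) == 0.0
        for arm in (0.0, 1.0)
    )
    converged = not degenerate
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = sm.GLM(y, exog, family=sm.families.Binomial(), var_weights=w).fit(
                maxiter=_MAX_ITER, tol=1e-10
            )
        params = np.asarray(res.params)
        converged = converged and bool(getattr(res, "converged", True))
        mu = np.asarray(res.fittedvalues)
        model_se = float(np.asarray(res.bse)[1])
    except Exception:
        params = np.array([0.0, 0.0])
        mu = np.full(dataset.n, 0.5)
        model_se = float("nan")
        converged = False
    if not np.all(np.isfinite(params)):
        params = np.nan_to_num(params, nan=0.0, posinf=0.0, neginf=0.0)
        converged = False
    if variance == "sandwich":
        se = float(_sandwich_se(exog, y, mu, w)[1])
    else:
        se = model_se
    log_or = float(params[1])
    zstat = log_or / se if se > 0 else np.inf * np.sign(log_or)
    p_value = float(2.0 * stats.norm.sf(abs(zstat)))
    return EffectEstimate(
        log_or_hat=log_or,
        se=se,
        ci_low=log_or - _Z975 * se,
        ci_high=log_or + _Z975 * se,
        p_value=p_value,
        converged=converged,
        ps_variant=weights.variant,
    )


def analyze(
    dataset: TrialDataset,
    variants: tuple[str, ...] = ("conventional", "extended"),
    variance: str = "sandwich",
) -> dict[str, EffectEstimate]:
    """Full pipeline — PS fit, IPTW weights, weighted effect estimate —
    for each requested PS-model variant on the same data."""
    rct_controls = int(np.sum((dataset.source == 1) & (dataset.treatment == 0)))
    if rct_controls == 0:
        raise EstimationError(
            "the RCT control arm is empty; the design is too skewed to estimate"
        )
    out: dict[str, EffectEstimate] = {}
    for variant in variants:
        ps_fit = fit_ps(dataset, variant)
        weights = iptw_weights(dataset.treatment, ps_fit.ps, variant)
        est = estimate_effect(dataset, weights, variance=variance)
        if not ps_fit.converged:
            est = EffectEstimate(
                log_or_hat=est.log_or_hat,
                se=est.se,
                ci_low=est.ci_low,
                ci_high=est.ci_high,
                p_value=est.p_value,
                converged=False,
                ps_variant=variant,
            )
        out[variant] = est
    return out
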