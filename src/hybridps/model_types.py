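"""Shared domain types, validation, and file I/O.

A hybrid-control trial pools a new two-armed RCT with a single historical
control dataset.  Each participant carries baseline covariates ``X``, a data
source indicator ``X_r`` coded +1 (RCT) / -1 (historical control), a binary
treatment indicator ``T`` and a binary outcome ``Y``.  Historical participants
are controls by construction (``T = 0``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ConfigurationError",
    "TrialDataset",
    "DesignConfig",
    "CalibrationConstants",
    "EffectEstimate",
    "PerformanceSummary",
    "BETA_TRUE",
    "ALPHA_TRUE",
    "ALPHA_R_TRUE",
    "read_trial_table",
    "write_trial_table",
    "write_results_table",
    "read_results_table",
]


class ValidationError(ValueError):
    """Participant-level data violate a structural invariant."""


class ConfigurationError(ValueError):
    """A design or file configuration is not usable."""


#: True propensity-score slopes on the four baseline covariates.
BETA_TRUE: tuple[float, ...] = (1.00, -0.50, 0.25, 0.10)
#: True outcome-model slopes on the four baseline covariates.
ALPHA_TRUE: tuple[float, ...] = (0.274, 0.137, -0.137, 0.137)
#: True outcome-model coefficient on the source indicator (dissimilar scenario).
ALPHA_R_TRUE: float = 0.137


@dataclass(frozen=True)
class TrialDataset:
    """Participant-level data for one (real or simulated) hybrid trial.

    Parameters
    ----------
    covariates
        ``(n, k)`` float matrix of baseline covariates, no missing values.
    source
        ``(n,)`` vector coded +1 for RCT participants, -1 for historical
        controls.
    treatment
        ``(n,)`` vector of 0/1 treatment indicators.
    outcome
        ``(n,)`` vector of 0/1 event indicators.
    participant_id
        Optional integer ids; generated sequentially (1..n) when absent.
    """

    covariates: np.ndarray
    source: np.ndarray
    treatment: np.ndarray
    outcome: np.ndarray
    participant_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        cov = np.asarray(self.covariates, dtype=float)
        if cov.ndim != 2 or cov.shape[0] < 1 or cov.shape[1] < 1:
            raise ValidationError("covariates must be a non-empty 2-D matrix")
        if not np.all(np.isfinite(cov)):
            raise ValidationError("covariates contain missing or non-finite entries")
        n = cov.shape[0]
        src = np.asarray(self.source, dtype=np.int64).ravel()
        trt = np.asarray(self.treatment, dtype=np.int64).ravel()
        out = np.asarray(self.outcome, dtype=np.int64).ravel()
        if not (len(src) == len(trt) == len(out) == n):
            raise ValidationError("column lengths disagree with the covariate matrix")
        if not np.all(np.isin(src, (-1, 1))):
            raise ValidationError("source must be coded +1 (RCT) or -1 (historical)")
        if not np.all(np.isin(trt, (0, 1))):
            raise ValidationError("treatment must be binary 0/1")
        if not np.all(np.isin(out, (0, 1))):
            raise ValidationError("outcome must be binary 0/1")
        bad = np.flatnonzero((src == -1) & (trt == 1))
        if bad.size:
            raise ValidationError(
                f"historical participant at row {bad[0]} has treatment=1; "
                "historical data are controls"
            )
        pid = self.participant_id
        if pid is None:
            pid = np.arange(1, n + 1, dtype=np.int64)
        else:
            pid = np.asarray(pid, dtype=np.int64).ravel()
            if len(pid) != n:
                raise ValidationError("participant_id length mismatch")
        object.__setattr__(self, "covariates", cov)
        object.__setattr__(self, "source", src)
        object.__setattr__(self, "treatment", trt)
        object.__setattr__(self, "outcome", out)
        object.__setattr__(self, "participant_id", pid)

    @property
    def n(self) -> int:
        return self.covariates.shape[0]

    @property
    def k(self) -> int:
        return self.covariates.shape[1]

    @property
    def n_rct(self) -> int:
        return int(np.sum(self.source == 1))

    @property
    def n_historical(self) -> int:
        return int(np.sum(self.source == -1))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, TrialDataset):
            return NotImplemented
        return (
            np.array_equal(self.covariates, other.covariates)
            and np.array_equal(self.source, other.source)
            and np.array_equal(self.treatment, other.treatment)
            and np.array_equal(self.outcome, other.outcome)
            and np.array_equal(self.participant_id, other.participant_id)
        )


@dataclass(frozen=True)
class DesignConfig:
    """One cell of the simulation design grid.

    ``ratio`` is (RCT treatment : RCT control : historical control); the
    default study design is 1:1:2 with ``n_total`` of 900 or 200.
    ``scenario`` selects similar ("I") or dissimilar ("II") covariate
    distributions between the RCT and the historical data.
    """

    scenario: str
    n_total: int
    ratio: tuple[int, int, int] = (1, 1, 2)
    event_rate: float = 0.50
    true_or: float = 1.0
    n_reps: int = 1
    seed: int = 0
    randomized_rct: bool = False
    binary_covariate_index: int | None = None

    def __post_init__(self) -> None:
        if self.scenario not in ("I", "II"):
            raise ConfigurationError("scenario must be 'I' or 'II'")
        if self.n_total < 1:
            raise ConfigurationError("n_total must be positive")
        if len(self.ratio) != 3 or any(r <= 0 for r in self.ratio):
            raise ConfigurationError("ratio must be three positive integers")
        if not (0.0 < self.event_rate < 1.0):
            raise ConfigurationError("event_rate must lie in (0, 1)")
        if self.true_or <= 0:
            raise ConfigurationError("true_or must be strictly positive")
        if self.n_reps < 1:
            raise ConfigurationError("n_reps must be positive")
        if self.binary_covariate_index is not None and not (
            1 <= self.binary_covariate_index <= 4
        ):
            raise ConfigurationError("binary_covariate_index must be in 1..4")

    @property
    def rct_fraction(self) -> float:
        """Fraction of the total sample drawn from the RCT."""
        t, c, h = self.ratio
        return (t + c) / (t + c + h)

    @property
    def treat_fraction_rct(self) -> float:
        """Target treated fraction within the RCT, t/(t+c)."""
        t, c, _ = self.ratio
        return t / (t + c)

    @property
    def n_rct(self) -> int:
        return int(round(self.n_total * self.rct_fraction))

    @property
    def n_historical(self) -> int:
        return self.n_total - self.n_rct

    @property
    def log_or(self) -> float:
        """True conditional log odds ratio of treatment."""
        return math.log(self.true_or)


@dataclass(frozen=True)
class CalibrationConstants:
    """True-model coefficients after design calibration.

    ``b0`` anchors the treated fraction within the RCT, ``a0`` anchors the
    control-arm event rate, and ``br`` (dissimilar scenario only) is the
    source-indicator coefficient in the true propensity model, fixed by
    requiring that the model reduce to the RCT-only model on RCT data and
    have mean-zero logit on historical data.
    """

    b0: float
    a0: float
    beta_treat: float
    br: float = 0.0
    beta: tuple[float, ...] = BETA_TRUE
    alpha: tuple[float, ...] = ALPHA_TRUE
    alpha_r: float = ALPHA_R_TRUE

    def with_log_or(self, log_or: float) -> "CalibrationConstants":
        """Same design constants with a different true treatment effect."""
        return replace(self, beta_treat=log_or)


@dataclass(frozen=True)
class EffectEstimate:
    """IPTW-weighted logistic estimate of the treatment log odds ratio."""

    log_or_hat: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    converged: bool
    ps_variant: str

    def __post_init__(self) -> None:
        if self.ps_variant not in ("conventional", "extended"):
            raise ConfigurationError("ps_variant must be conventional|extended")

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or_hat)

    @property
    def significant(self) -> bool:
        """Two-sided Wald test at the 5% level."""
        return self.p_value < 0.05


@dataclass(frozen=True)
class PerformanceSummary:
    """Monte-Carlo operating characteristics for one design cell & PS variant.

    bias and MSE are on the log-odds-ratio scale; coverage and rejection are
    percentages.  ``rejection_pct`` is the type I error rate when the true OR
    is 1 and power otherwise.
    """

    bias: float
    mse: float
    coverage_pct: float
    rejection_pct: float
    n_effective_reps: int
    mc_se_rejection: float
    n_nonconverged: int = 0
    mc_se_bias: float = float("nan")
    mc_se_coverage: float = float("nan")


# ---------------------------------------------------------------------------
# participant-table I/O

_DEFAULT_COLUMNS = {
    "id": "id",
    "source": "source",
    "treatment": "treatment",
    "outcome": "outcome",
}

def _normalize_source(values: pd.Series) -> np.ndarray:
    """Map any of the accepted codings {RCT,HC}, {1,0}, {1,-1} to {+1,-1}."""
    raw = values.astype(str).str.strip()
    uniq = set(raw.unique())
    if uniq <= {"RCT", "HC"}:
        return np.where(raw == "RCT", 1, -1)
    nums = pd.to_numeric(raw, errors="coerce")
    if nums.isna().any():
        raise ValidationError(f"unrecognized source coding: {sorted(uniq)}")
    vals = set(nums.unique())
    if vals <= {1, -1}:
        return nums.astype(np.int64).to_numpy()
    if vals <= {0, 1}:
        return np.where(nums == 1, 1, -1)
    raise ValidationError(f"unrecognized source coding: {sorted(vals)}")


def read_trial_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> TrialDataset:
    """Read a participant-level CSV into a validated :class:`TrialDataset`.

    Covariate columns are all columns named ``x1..xk`` unless ``column_map``
    provides a ``covariates`` entry (list of column names).  Source codings
    ``{"RCT","HC"}``, ``{1,0}`` and ``{1,-1}`` are all normalized to +1/-1.
    """
    path = Path(path)
    # round_trip parsing so 17-significant-digit output reads back bit-exact
    df = pd.read_csv(path, float_precision="round_trip")
    cmap = dict(_DEFAULT_COLUMNS)
    cov_cols: Sequence[str] | None = None
    if column_map:
        cov_cols = column_map.get("covariates")  # type: ignore[assignment]
        cmap.update({k: v for k, v in column_map.items() if k != "covariates"})
    if cov_cols is None:
        cov_cols = sorted(
            (c for c in df.columns if c.startswith("x") and c[1:].isdigit()),
            key=lambda c: int(c[1:]),
        )
    missing = [c for c in (*cov_cols, cmap["source"], cmap["treatment"], cmap["outcome"]) if c not in df.columns]
    if missing:
        raise ConfigurationError(f"{path.name}: missing column(s) {missing}")
    if not cov_cols:
        raise ConfigurationError(f"{path.name}: no covariate columns found")
    pid = (
        df[cmap["id"]].to_numpy(dtype=np.int64)
        if cmap["id"] in df.columns
        else None
    )
    out = df[cmap["outcome"]]
    if not out.isin((0, 1)).all():
        raise ValidationError(f"{path.name}: outcome column is not binary 0/1")
    return TrialDataset(
        covariates=df[list(cov_cols)].to_numpy(dtype=float),
        source=_normalize_source(df[cmap["source"]]),
        treatment=df[cmap["treatment"]].to_numpy(),
        outcome=out.to_numpy(),
        participant_id=pid,
    )


def write_trial_table(dataset: TrialDataset, path: str | Path) -> Path:
    """Write a participant CSV (``id,x1..xk,source,treatment,outcome``).

    Covariates are printed with 17 significant digits so that a read-back
    reproduces the matrix bit for bit.
    """
    path = Path(path)
    cols = {"id": dataset.participant_id}
    for j in range(dataset.k):
        cols[f"x{j + 1}"] = dataset.covariates[:, j]
    cols["source"] = dataset.source
    cols["treatment"] = dataset.treatment
    cols["outcome"] = dataset.outcome
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")
    return path


# ---------------------------------------------------------------------------
# results-table I/O (layout of the operating-characteristics tables)

_MEASUREMENTS = ("bias", "mse", "coverage_pct", "rejection_pct")


def write_results_table(
    summaries: Mapping[tuple[str, float, float], PerformanceSummary],
    path: str | Path,
) -> Path:
    """Write performance summaries as a wide CSV.

    ``summaries`` maps ``(ps_variant, event_rate, true_or)`` to a
    :class:`PerformanceSummary`.  The output has one row per
    (measurement, variant, event rate) and one ``or_<value>`` column per
    odds ratio, mirroring the standard operating-characteristics table
    layout.
    """
    if not summaries:
        raise ConfigurationError("no summaries to write")
    keys = list(summaries)
    if len(set(keys)) != len(keys):
        raise ConfigurationError("duplicate summary keys")
    variants = sorted({k[0] for k in keys})
    rates = sorted({k[1] for k in keys}, reverse=True)
    ors = sorted({k[2] for k in keys})
    rows = []
    for meas in _MEASUREMENTS:
        for variant in variants:
            for rate in rates:
                row: dict[str, object] = {
                    "measurement": meas,
                    "ps_variant": variant,
                    "event_rate": rate,
                }
                for or_ in ors:
                    cell = summaries.get((variant, rate, or_))
                    row[f"or_{or_:g}"] = (
                        getattr(cell, meas) if cell is not None else float("nan")
                    )
                rows.append(row)
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")
    return path


def read_results_table(path: str | Path) -> pd.DataFrame:
    """Read back a results CSV written by :func:`write_results_table`."""
    return pd.read_csv(path)
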