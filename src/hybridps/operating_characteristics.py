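"""Monte-Carlo study runner and performance metrics.

For each design cell (scenario x sample size x allocation ratio x event
rate x odds ratio) the runner simulates ``n_reps`` independent trials,
estimates the treatment log odds ratio with both propensity-score variants,
and summarizes four operating characteristics on the log-odds-ratio scale:

* bias      — mean(estimate) - log(true OR)
* MSE       — mean((estimate - log(true OR))^2)
* coverage  — % of 95% Wald CIs containing log(true OR)
* rejection — % of two-sided Wald p-values below 5%
              (type I error when the true OR is 1, power otherwise)

Calibration constants are solved once per design (they do not depend on
the odds ratio) and cached; replicates use pre-assigned seed substreams,
so results are reproducible and independent of execution order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .calibration import calibrate_design
from .estimate import EstimationError, analyze
from .model_types import (
    CalibrationConstants,
    ConfigurationError,
    DesignConfig,
    EffectEstimate,
    PerformanceSummary,
    write_results_table,
)
from .simulate import simulate_trial

__all__ = [
    "ReplicateRecord",
    "StudyGrid",
    "run_cell",
    "summarize",
    "summarize_cell",
    "run_study",
]


@dataclass(frozen=True)
class ReplicateRecord:
    """Estimates from one simulated trial (both PS variants)."""

    replicate_index: int
    estimates: Mapping[str, EffectEstimate]
    constants_used: CalibrationConstants
    seed: int


@dataclass(frozen=True)
class StudyGrid:
    """Design grid for a full study run."""

    scenarios: Sequence[str] = ("I", "II")
    n_totals: Sequence[int] = (900,)
    ratios: Sequence[tuple[int, int, int]] = ((1, 1, 2),)
    event_rates: Sequence[float] = (0.50, 0.10, 0.05)
    odds_ratios: Sequence[float] = (1.0, 2.0, 5.0, 10.0)
    n_reps: int = 10_000
    seed: int = 0
    variants: Sequence[str] = ("conventional", "extended")
    randomized_rct: bool = False
    binary_covariate_index: int | None = None

    @classmethod
    def from_dict(cls, spec: Mapping) -> "StudyGrid":
        kwargs = dict(spec)
        if "ratios" in kwargs:
            kwargs["ratios"] = [tuple(r) for r in kwargs["ratios"]]
        return cls(**kwargs)


def _design_key(config: DesignConfig) -> tuple:
    """Cache key for calibration constants: everything but the odds ratio,
    replicate count and seed."""
    return (
        config.scenario,
        config.ratio,
        config.event_rate,
        config.randomized_rct,
        config.binary_covariate_index,
    )


def run_cell(
    config: DesignConfig,
    constants: CalibrationConstants | None = None,
    variants: Sequence[str] = ("conventional", "extended"),
    calibration_draws: int = 2_000_000,
) -> list[ReplicateRecord]:
    """Simulate and analyze ``config.n_reps`` independent replicates.

    Each replicate draws from its own seed substream derived from
    ``(config.seed, replicate_index)``, so a rerun with the same seed is
    bit-identical and replicates may be computed in any order.
    """
    if constants is None:
        try:
            constants = calibrate_design(config, mc_draws=calibration_draws)
        except Exception as exc:  # pragma: no cover - defensive
            raise ConfigurationError(f"calibration failed for {config}: {exc}") from exc
    constants = constants.with_log_or(config.log_or)
    records: list[ReplicateRecord] = []
    for rep in range(config.n_reps):
        dataset, _ = simulate_trial(config, constants, replicate_index=rep)
        estimates = analyze(dataset, variants=tuple(variants))
        records.append(
            ReplicateRecord(
                replicate_index=rep,
                estimates=estimates,
                constants_used=constants,
                seed=config.seed,
            )
        )
    return records


def summarize(
    records: Iterable[ReplicateRecord],
    true_or: float,
    variant: str,
) -> PerformanceSummary:
    """Operating characteristics for one PS variant over a cell's replicates.

    Non-converged replicates are excluded from the averages and counted in
    ``n_nonconverged``.  Monte-Carlo standard errors accompany the
    proportions (sqrt(p(1-p)/R)) and the bias (sd/sqrt(R)).
    """
    truth = math.log(true_or)
    ests = [r.estimates[variant] for r in records]
    if not ests:
        raise ConfigurationError("no replicates to summarize")
    kept = [e for e in ests if e.converged]
    n_bad = len(ests) - len(kept)
    if not kept:
        raise ConfigurationError("no converged replicates to summarize")
    log_ors = np.array([e.log_or_hat for e in kept])
    covered = np.array([e.ci_low <= truth <= e.ci_high for e in kept])
    rejected = np.array([e.p_value < 0.05 for e in kept])
    r = len(kept)
    err = log_ors - truth
    p_cov = covered.mean()
    p_rej = rejected.mean()
    return PerformanceSummary(
        bias=float(err.mean()),
        mse=float(np.mean(err**2)),
        coverage_pct=100.0 * float(p_cov),
        rejection_pct=100.0 * float(p_rej),
        n_effective_reps=r,
        mc_se_rejection=100.0 * math.sqrt(p_rej * (1.0 - p_rej) / r),
        n_nonconverged=n_bad,
        mc_se_bias=float(err.std(ddof=1) / math.sqrt(r)) if r > 1 else float("nan"),
        mc_se_coverage=100.0 * math.sqrt(p_cov * (1.0 - p_cov) / r),
    )


def summarize_cell(
    records: Iterable[ReplicateRecord],
    true_or: float,
    variants: Sequence[str] = ("conventional", "extended"),
) -> dict[str, PerformanceSummary]:
    records = list(records)
    return {v: summarize(records, true_or, v) for v in variants}


def run_study(grid: StudyGrid, out_dir: str | Path) -> dict[str, Path]:
    """Run the full design grid and write one results CSV per
    (scenario, n_total), plus a JSON manifest of constants, seeds and
    convergence counts.  Cell failures are recorded and do not abort the
    study."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": grid.seed, "n_reps": grid.n_reps, "cells": []}
    outputs: dict[str, Path] = {}
    constants_cache: dict[tuple, CalibrationConstants] = {}
    for scenario in grid.scenarios:
        for n_total in grid.n_totals:
            for ratio in grid.ratios:
                summaries: dict[tuple[str, float, float], PerformanceSummary] = {}
                for rate in grid.event_rates:
                    for or_ in grid.odds_ratios:
                        config = DesignConfig(
                            scenario=scenario,
                            n_total=n_total,
                            ratio=ratio,
                            event_rate=rate,
                            true_or=or_,
                            n_reps=grid.n_reps,
                            seed=grid.seed,
                            randomized_rct=grid.randomized_rct,
                            binary_covariate_index=grid.binary_covariate_index,
                        )
                        key = _design_key(config)
                        cell_info: dict = {
                            "scenario": scenario,
                            "n_total": n_total,
                            "ratio": list(ratio),
                            "event_rate": rate,
                            "true_or": or_,
                        }
                        try:
                            if key not in constants_cache:
                                constants_cache[key] = calibrate_design(config)
                            constants = constants_cache[key]
                            records = run_cell(
                                config, constants=constants, variants=grid.variants
                            )
                            cell = summarize_cell(records, or_, grid.variants)
                        except (ConfigurationError, EstimationError) as exc:
                            cell_info["error"] = str(exc)
                            manifest["cells"].append(cell_info)
                            continue
                        for variant, summ in cell.items():
                            summaries[(variant, rate, or_)] = summ
                        cell_info.update(
                            {
                                "constants": {
                                    "b0": constants.b0,
                                    "a0": constants.a0,
                                    "br": constants.br,
                                },
                                "n_nonconverged": {
                                    v: cell[v].n_nonconverged for v in cell
                                },
                            }
                        )
                        manifest["cells"].append(cell_info)
                if not summaries:
                    continue
                ratio_tag = "-".join(map(str, ratio))
                name = f"results_scenario{scenario}_n{n_total}_ratio{ratio_tag}.csv"
                path = write_results_table(summaries, out_dir / name)
                outputs[name] = path
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    outputs["manifest.json"] = manifest_path
    return outputs
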