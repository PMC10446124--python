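"""Percentile bootstrap confidence intervals for all three estimators.

Individuals (rows) are resampled with replacement, keeping each row's
replicates and covariates together, and the full estimation pipeline is
re-run on every resample.  When the error variance was estimated from
replicates it is re-estimated inside each resample so the interval
reflects that extra uncertainty; a user-supplied (known) tau2 is held
fixed, mirroring what information each mode actually has.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._fit import FitError
from ._rng import as_rng, spawn
from .calibration import (
    CalibrationError,
    CorrectionResult,
    ErrorModel,
    estimate_tau2_replicates,
    fit_naive,
    rc_correct,
)
from .datagen import StudyData
from .simex import SimexConfig, simex_correct

__all__ = ["BootstrapConfig", "BootstrapError", "bootstrap_ci", "point_estimate"]

logger = logging.getLogger(__name__)


class BootstrapError(RuntimeError):
    """Too many resamples failed for the interval to be trustworthy."""


@dataclass(frozen=True)
class BootstrapConfig:
    n_boot: int = 999
    ci_level: float = 0.95
    ci_type: str = "percentile"
    seed: int | None = None
    re_estimate_tau2: bool = True

    def __post_init__(self):
        if self.n_boot < 1:
            raise ValueError(f"n_boot must be >= 1, got {self.n_boot}")
        if not 0 < self.ci_level < 1:
            raise ValueError(f"ci_level must be in (0, 1), got {self.ci_level}")
        if self.ci_type != "percentile":
            raise ValueError("only percentile intervals are implemented")


def point_estimate(
    data: StudyData,
    method: str,
    error_model: ErrorModel | None = None,
    simex_config: SimexConfig | None = None,
    seed=None,
) -> CorrectionResult:
    """Dispatch one estimator by name ("naive", "rc", "simex")."""
    if method == "naive":
        return fit_naive(data)
    if error_model is None:
        raise ValueError(f"method {method!r} requires an error model")
    if method == "rc":
        return rc_correct(data, error_model)
    if method == "simex":
        return simex_correct(data, error_model, simex_config, seed=seed)
    raise ValueError(f"unknown method {method!r}")


def bootstrap_ci(
    data: StudyData,
    method: str,
    error_model: ErrorModel | None = None,
    config: BootstrapConfig | None = None,
    simex_config: SimexConfig | None = None,
    seed=None,
) -> CorrectionResult:
    """Percentile bootstrap CI around the full-data point estimate.

    Resamples where the estimator fails (e.g. a non-positive calibration
    factor, or a one-class logistic resample) are dropped and counted in
    the diagnostics when they are at most 10% of resamples; beyond that
    the interval is refused with an error naming the failure mode.
    """
    config = config or BootstrapConfig()
    seed = seed if seed is not None else config.seed
    rng = as_rng(seed)
    # separate deterministic streams for the SIMEX noise of the full-data
    # fit and of each resample
    if method == "simex":
        streams = spawn(rng, config.n_boot + 1)
        full_seed, simex_seeds = streams[0], streams[1:]
    else:
        full_seed, simex_seeds = None, [None] * config.n_boot

    full = point_estimate(data, method, error_model, simex_config, seed=full_seed)

    re_estimate = (
        config.re_estimate_tau2
        and error_model is not None
        and error_model.source == "replicates"
        and data.k >= 2
    )
    estimates = np.empty(config.n_boot)
    n_failed = 0
    last_error: Exception | None = None
    for b in range(config.n_boot):
        idx = rng.integers(0, data.n, data.n)
        boot = data.resample(idx)
        try:
            em = estimate_tau2_replicates(boot) if re_estimate else error_model
            res = point_estimate(boot, method, em, simex_config, seed=simex_seeds[b])
            estimates[b] = res.estimate
        except (CalibrationError, FitError, ValueError) as exc:
            estimates[b] = np.nan
            n_failed += 1
            last_error = exc
    if n_failed > 0.1 * config.n_boot:
        raise BootstrapError(
            f"{n_failed}/{config.n_boot} bootstrap resamples failed "
            f"(last failure: {last_error})"
        )
    if n_failed:
        logger.warning("bootstrap: dropped %d failed resamples", n_failed)
    kept = estimates[~np.isnan(estimates)]
    alpha = 1.0 - config.ci_level
    lo, hi = np.quantile(kept, [alpha / 2.0, 1.0 - alpha / 2.0])
    diagnostics = dict(full.diagnostics)
    diagnostics.update(
        ci_type="percentile",
        ci_level=config.ci_level,
        n_boot=config.n_boot,
        n_failed=n_failed,
        se=float(kept.std(ddof=1)) if len(kept) > 1 else 0.0,
    )
    return CorrectionResult(
        estimate=full.estimate,
        method=method,
        n_used=data.n,
        ci_low=float(min(lo, full.estimate)),
        ci_high=float(max(hi, full.estimate)),
        diagnostics=diagnostics,
    )
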