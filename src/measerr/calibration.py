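"""Naive fitting, error-variance estimation, and regression calibration.

Regression calibration (RC) divides the uncorrected exposure coefficient
by the estimated attenuation factor

    lambda-hat = (s2_W|C - tau2) / s2_W|C,

where s2_W|C is the residual variance of the error-prone measurement
given the covariates and tau2 is the measurement-error variance.  For a
linear outcome model this is exact under classical error; for a logistic
model the same ratio correction of the log-odds coefficient is the
Rosner-style calibration, which is approximate (valid for small-to-
moderate effects and/or small error variance).

tau2 can be supplied as a known quantity (sensitivity-analysis mode) or
estimated from replicate measurements as the pooled within-individual
variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from . import _fit
from .datagen import StudyData

__all__ = [
    "ErrorModel",
    "CorrectionResult",
    "CalibrationError",
    "FitFailureError",
    "fit_naive",
    "estimate_tau2_replicates",
    "conditional_variance",
    "rc_correct",
    "nagelkerke_r2",
]

logger = logging.getLogger(__name__)

FitFailureError = _fit.FitError
nagelkerke_r2 = _fit.nagelkerke_r2


class CalibrationError(RuntimeError):
    """Regression calibration is undefined (non-positive calibration factor)."""


@dataclass(frozen=True)
class ErrorModel:
    """The assumed measurement-error variance and its provenance.

    source is "known" when tau2 comes from external knowledge (the
    sensitivity-analysis setting) and "replicates" when estimated as the
    pooled within-individual variance of replicate measurements.
    """

    tau2: float
    source: str = "known"
    tau2_se: float | None = None

    def __post_init__(self):
        if self.tau2 < 0:
            raise ValueError(f"tau2 must be >= 0, got {self.tau2}")
        if self.source not in ("known", "replicates"):
            raise ValueError(f"unknown tau2 source {self.source!r}")


@dataclass
class CorrectionResult:
    """Point estimate of the exposure coefficient on the model's natural
    scale (slope for linear, log-odds for logistic), with optional CI
    and method-specific diagnostics."""

    estimate: float
    method: str
    n_used: int
    ci_low: float | None = None
    ci_high: float | None = None
    diagnostics: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.estimate <= self.ci_high):
                raise ValueError(
                    "confidence interval must bracket the point estimate"
                )


def fit_naive(data: StudyData, ci_level: float = 0.95) -> CorrectionResult:
    """Uncorrected analysis: regress the outcome on the first replicate
    and the covariates; Wald confidence interval.

    OLS for a continuous outcome, maximum-likelihood logistic regression
    for a binary one.
    """
    X = data.design()
    if data.outcome_family == "linear":
        beta, cov = _fit.ols(X, data.outcome)
    else:
        beta, cov = _fit.logit(X, data.outcome)
    est = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return CorrectionResult(
        estimate=est,
        method="naive",
        n_used=data.n,
        ci_low=est - z * se,
        ci_high=est + z * se,
        diagnostics={"se": se, "ci_type": "wald", "ci_level": ci_level},
    )


def estimate_tau2_replicates(data: StudyData) -> ErrorModel:
    """Measurement-error variance from replicates: the within-individual
    sample variance (denominator k-1), averaged over individuals."""
    if data.k < 2:
        raise ValueError(
            f"need >= 2 replicate columns to estimate tau2, got k={data.k}"
        )
    row_vars = data.exposure_replicates.var(axis=1, ddof=1)
    tau2 = float(row_vars.mean())
    se = float(row_vars.std(ddof=1) / np.sqrt(data.n)) if data.n > 1 else None
    logger.debug("tau2 estimated from %d replicates: %.4g (se %.3g)",
                 data.k, tau2, se if se is not None else float("nan"))
    return ErrorModel(tau2=tau2, source="replicates", tau2_se=se)


def conditional_variance(data: StudyData) -> float:
    """Variance of the error-prone measurement given the covariates:
    residual variance of an OLS of the first replicate on the covariates
    (denominator n - c - 1).  With no covariates this is the sample
    variance of the first replicate."""
    n, c = data.n, data.n_covariates
    if n <= c + 1:
        raise ValueError(f"need n > c + 1 observations (n={n}, c={c})")
    w = data.first_replicate
    if c == 0:
        return float(w.var(ddof=1))
    Z = np.column_stack([np.ones(n), data.covariates])
    beta, _ = _fit.ols(Z, w)
    resid = w - Z @ beta
    return float(resid @ resid / (n - c - 1))


def rc_correct(data: StudyData, error_model: ErrorModel) -> CorrectionResult:
    """Regression calibration: naive estimate divided by the estimated
    attenuation factor.

    Applied identically to the linear slope and the logistic log-odds
    coefficient (the logistic case is the approximate Rosner-style
    correction).  Covariate coefficients are not corrected.  Raises
    CalibrationError when s2_W|C - tau2 <= 0 rather than clipping: a
    near-null calibration factor is exactly the instability the method
    is known for and must surface.
    """
    naive = fit_naive(data)
    s2_w = conditional_variance(data)
    denom = s2_w - error_model.tau2
    if denom <= 0:
        raise CalibrationError(
            "non-positive calibration factor: conditional variance "
            f"{s2_w:.4g} <= tau2 {error_model.tau2:.4g}"
        )
    lam = denom / s2_w
    estimate = naive.estimate / lam
    logger.debug(
        "rc: tau2=%.4g (%s), attenuation=%.4g, naive=%.4g, corrected=%.4g",
        error_model.tau2, error_model.source, lam, naive.estimate, estimate,
    )
    return CorrectionResult(
        estimate=float(estimate),
        method="rc",
        n_used=data.n,
        diagnostics={
            "attenuation": lam,
            "conditional_variance": s2_w,
            "tau2": error_model.tau2,
            "tau2_source": error_model.source,
            "naive_estimate": naive.estimate,
        },
    )
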