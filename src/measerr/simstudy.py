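"""Monte Carlo simulation study over the scenario grids.

For each scenario, n_reps datasets are generated and each requested
estimator is applied; performance is summarised as bias, percentage
bias, mean squared error and (optionally) bootstrap-CI coverage, each
with its Monte Carlo standard error:

    MCSE(bias)     = sd(estimates) / sqrt(R)
    MCSE(MSE)      = sqrt( sum(((e_i - theta)^2 - MSE)^2) / (R (R - 1)) )
    MCSE(coverage) = sqrt( cov (1 - cov) / R )

Coverage is opt-in because bootstrap-inside-Monte-Carlo dominates the
cost; bias/MSE runs never pay for it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._fit import FitError
from ._rng import spawn
from .bootstrap import BootstrapConfig, BootstrapError, bootstrap_ci, point_estimate
from .calibration import CalibrationError, estimate_tau2_replicates
from .datagen import generate, scenario_grid
from .simex import SimexConfig

__all__ = [
    "PerformanceSummary",
    "ScenarioResult",
    "compute_metrics",
    "run_scenario",
    "run_grid",
    "summarize_study",
    "tidy_summaries",
    "plot_performance",
]

METHODS = ("naive", "rc", "simex")


@dataclass
class PerformanceSummary:
    """Bias / MSE / coverage of one estimator in one scenario, with
    Monte Carlo standard errors."""

    scenario_label: str
    family: str
    method: str
    n_reps: int
    bias: float
    pct_bias: float
    mse: float
    mcse_bias: float
    mcse_mse: float
    mean_estimate: float
    coverage: float | None = None
    mcse_coverage: float | None = None
    n_failed: int = 0


@dataclass
class ScenarioResult:
    """All per-repetition estimates (kept for audit) plus the summaries."""

    scenario: object
    summaries: dict[str, PerformanceSummary]
    estimates: dict[str, np.ndarray]
    ci_bounds: dict[str, np.ndarray] = field(default_factory=dict)


def compute_metrics(
    estimates: np.ndarray,
    truth: float,
    ci_pairs: np.ndarray | None = None,
    scenario_label: str = "",
    family: str = "",
    method: str = "",
    n_failed: int = 0,
) -> PerformanceSummary:
    """Aggregate repetition-level estimates into performance measures.

    ci_pairs, when given, is an (R, 2) array of interval bounds; NaN
    rows (failed repetitions) are excluded from every measure.
    """
    estimates = np.asarray(estimates, dtype=float)
    keep = np.isfinite(estimates)
    estimates = estimates[keep]
    r = len(estimates)
    if r < 2:
        raise ValueError(f"need >= 2 successful repetitions, got {r}")
    if not np.isfinite(truth):
        raise ValueError("truth must be finite")
    if truth == 0:
        raise ValueError("percentage bias is undefined for truth = 0")
    bias = float(estimates.mean() - truth)
    sq_err = (estimates - truth) ** 2
    mse = float(sq_err.mean())
    mcse_bias = float(estimates.std(ddof=1) / np.sqrt(r))
    mcse_mse = float(np.sqrt(np.sum((sq_err - mse) ** 2) / (r * (r - 1))))
    coverage = mcse_coverage = None
    if ci_pairs is not None:
        ci_pairs = np.asarray(ci_pairs, dtype=float)[keep]
        covered = (ci_pairs[:, 0] <= truth) & (truth <= ci_pairs[:, 1])
        coverage = float(covered.mean())
        mcse_coverage = float(np.sqrt(coverage * (1.0 - coverage) / r))
    return PerformanceSummary(
        scenario_label=scenario_label,
        family=family,
        method=method,
        n_reps=r,
        bias=bias,
        pct_bias=100.0 * bias / truth,
        mse=mse,
        mcse_bias=mcse_bias,
        mcse_mse=mcse_mse,
        mean_estimate=float(estimates.mean()),
        coverage=coverage,
        mcse_coverage=mcse_coverage,
        n_failed=n_failed,
    )


def run_scenario(
    scenario,
    methods=METHODS,
    n_reps: int = 1000,
    seed=0,
    simex_config: SimexConfig | None = None,
    bootstrap_config: BootstrapConfig | None = None,
    compute_coverage: bool = False,
) -> ScenarioResult:
    """Generate n_reps datasets from one scenario and apply each method.

    Each repetition gets its own deterministic seed stream (master seed
    spawned per repetition), so any single repetition can be reproduced
    in isolation.  tau2 is re-estimated from the replicates of each
    generated dataset.  Failed repetitions are recorded as NaN and
    counted.
    """
    if n_reps < 2:
        raise ValueError(f"n_reps must be >= 2, got {n_reps}")
    methods = tuple(methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    rep_seeds = spawn(seed, n_reps)
    estimates = {m: np.full(n_reps, np.nan) for m in methods}
    ci_bounds = {m: np.full((n_reps, 2), np.nan) for m in methods}
    failures = {m: 0 for m in methods}
    for i, rep_seed in enumerate(rep_seeds):
        data_seed, method_seed, boot_seed = rep_seed.spawn(3)
        data = generate(scenario, data_seed)
        error_model = (
            estimate_tau2_replicates(data) if data.k >= 2 else None
        )
        for m in methods:
            try:
                if compute_coverage:
                    res = bootstrap_ci(
                        data, m, error_model,
                        config=bootstrap_config,
                        simex_config=simex_config,
                        seed=boot_seed.spawn(1)[0],
                    )
                    ci_bounds[m][i] = (res.ci_low, res.ci_high)
                else:
                    res = point_estimate(
                        data, m, error_model, simex_config, seed=method_seed
                    )
                estimates[m][i] = res.estimate
            except (CalibrationError, FitError, BootstrapError, ValueError):
                failures[m] += 1
    summaries = {
        m: compute_metrics(
            estimates[m],
            truth=scenario.beta_true,
            ci_pairs=ci_bounds[m] if compute_coverage else None,
            scenario_label=scenario.label,
            family=scenario.family,
            method=m,
            n_failed=failures[m],
        )
        for m in methods
    }
    return ScenarioResult(
        scenario=scenario,
        summaries=summaries,
        estimates=estimates,
        ci_bounds=ci_bounds if compute_coverage else {},
    )


def run_grid(
    family: str,
    methods=METHODS,
    n_reps: int = 1000,
    seed=0,
    simex_config: SimexConfig | None = None,
    bootstrap_config: BootstrapConfig | None = None,
    compute_coverage: bool = False,
    include_heavy: bool = False,
    scenarios=None,
) -> list[ScenarioResult]:
    """Run every scenario of one family's published grid.

    The n = 10,000 scenario is excluded unless include_heavy is set.
    """
    if scenarios is None:
        scenarios = scenario_grid(family)
        if not include_heavy:
            scenarios = [s for s in scenarios if s.n < 10_000]
    scen_seeds = spawn(seed, len(scenarios))
    return [
        run_scenario(
            s,
            methods=methods,
            n_reps=n_reps,
            seed=scen_seed,
            simex_config=simex_config,
            bootstrap_config=bootstrap_config,
            compute_coverage=compute_coverage,
        )
        for s, scen_seed in zip(scenarios, scen_seeds)
    ]


def _median_iqr(values: pd.Series) -> dict:
    v = values.dropna()
    if v.empty:
        return {"median": np.nan, "q25": np.nan, "q75": np.nan}
    return {
        "median": float(v.median()),
        "q25": float(v.quantile(0.25)),
        "q75": float(v.quantile(0.75)),
    }


def summarize_study(summaries) -> pd.DataFrame:
    """Study-level median and IQR of percentage bias, MSE and coverage
    per method, pooled over all scenarios and split by family."""
    rows = []
    df = pd.DataFrame(
        {
            "family": s.family,
            "method": s.method,
            "pct_bias": s.pct_bias,
            "mse": s.mse,
            "coverage": s.coverage,
        }
        for s in summaries
    )
    scopes = [("pooled", df)] + [(fam, g) for fam, g in df.groupby("family")]
    for scope, sub in scopes:
        for method, g in sub.groupby("method"):
            row = {"scope": scope, "method": method, "n_scenarios": len(g)}
            for metric in ("pct_bias", "mse", "coverage"):
                stats = _median_iqr(g[metric])
                row.update({f"{metric}_{k}": v for k, v in stats.items()})
            rows.append(row)
    return pd.DataFrame(rows)


def tidy_summaries(summaries) -> pd.DataFrame:
    """One row per scenario x method x metric, ready for CSV export."""
    rows = []
    for s in summaries:
        base = {
            "scenario": s.scenario_label,
            "family": s.family,
            "method": s.method,
            "n_reps": s.n_reps,
            "n_failed": s.n_failed,
        }
        for metric, value, mcse in (
            ("bias", s.bias, s.mcse_bias),
            ("pct_bias", s.pct_bias, None),
            ("mse", s.mse, s.mcse_mse),
            ("coverage", s.coverage, s.mcse_coverage),
            ("mean_estimate", s.mean_estimate, s.mcse_bias),
        ):
            if value is None:
                continue
            rows.append({**base, "metric": metric, "value": value, "mcse": mcse})
    return pd.DataFrame(rows)


def plot_performance(summaries, path, title: str = ""):
    """Three-panel figure (A: percentage bias, B: MSE, C: coverage) with
    one line per method across the given scenarios."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = tidy_summaries(summaries)
    panels = [("pct_bias", "A) percentage bias"),
              ("mse", "B) mean squared error"),
              ("coverage", "C) coverage")]
    fig, axes = plt.subplots(1, 3, figsize=(12, 3.5), sharex=True)
    for ax, (metric, label) in zip(axes, panels):
        sub = df[df.metric == metric]
        for method, g in sub.groupby("method"):
            ax.plot(g.scenario, g.value, marker="o", label=method)
        ax.set_title(label)
        ax.tick_params(axis="x", rotation=60)
        if metric == "coverage":
            ax.axhline(0.95, color="grey", ls=":")
    axes[0].legend()
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
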