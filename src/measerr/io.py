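"""Tabular I/O: CSV study data in and out, JSON results and manifests.

A study CSV has one outcome column, one or more error-prone exposure
replicate columns, and zero or more covariate columns; column roles are
declared by the caller.  Generated datasets are written with a sidecar
JSON recording the scenario parameters and seed so any dataset can be
regenerated exactly.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .calibration import CorrectionResult
from .datagen import StudyData

__all__ = [
    "ColumnRoles",
    "load_study_csv",
    "write_study_csv",
    "result_to_dict",
    "write_result_json",
]


@dataclass(frozen=True)
class ColumnRoles:
    outcome: str
    replicates: tuple[str, ...]
    covariates: tuple[str, ...] = ()

    def __post_init__(self):
        if not self.replicates:
            raise ValueError("at least one exposure replicate column is required")


def load_study_csv(
    path, roles: ColumnRoles, family: str = "linear"
) -> StudyData:
    """Read a study CSV into typed StudyData with validation.

    Errors name the offending columns or rows: missing columns,
    non-numeric cells, missing values, and non-0/1 outcomes for the
    logistic family are all rejected.
    """
    df = pd.read_csv(path)
    wanted = [roles.outcome, *roles.replicates, *roles.covariates]
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    sub = df[wanted].apply(pd.to_numeric, errors="coerce")
    bad = sub.isna() & ~df[wanted].isna()
    if bad.any().any():
        rows = sorted(set(bad.index[bad.any(axis=1)] + 2))  # 1-based + header
        raise ValueError(f"{path}: non-numeric cells in file rows {rows[:10]}")
    if sub.isna().any().any():
        rows = sorted(set(sub.index[sub.isna().any(axis=1)] + 2))
        raise ValueError(f"{path}: missing values in file rows {rows[:10]}")
    if family == "logistic":
        y = sub[roles.outcome]
        bad_vals = sorted(set(y[~y.isin([0, 1])]))
        if bad_vals:
            raise ValueError(
                f"{path}: logistic outcome must be 0/1, found {bad_vals[:5]}"
            )
    return StudyData(
        outcome=sub[roles.outcome].to_numpy(),
        exposure_replicates=sub[list(roles.replicates)].to_numpy(),
        covariates=sub[list(roles.covariates)].to_numpy()
        if roles.covariates
        else np.empty((len(sub), 0)),
        outcome_family=family,
        covariate_names=tuple(roles.covariates),
    )


def write_study_csv(
    data: StudyData,
    path,
    scenario=None,
    seed=None,
    include_true: bool = False,
) -> Path:
    """Write a dataset as CSV (columns outcome, w1..wk, covariates and,
    when requested, x_true) with a sidecar JSON of provenance."""
    path = Path(path)
    cols = {"outcome": data.outcome}
    for j in range(data.k):
        cols[f"w{j + 1}"] = data.exposure_replicates[:, j]
    for name, col in zip(data.covariate_names, data.covariates.T):
        cols[name] = col
    if include_true and data.true_exposure is not None:
        cols["x_true"] = data.true_exposure
    pd.DataFrame(cols).to_csv(path, index=False)
    sidecar = {
        "family": data.outcome_family,
        "n": data.n,
        "k": data.k,
        "covariates": list(data.covariate_names),
        "seed": seed,
    }
    if scenario is not None:
        sidecar["scenario"] = dataclasses.asdict(scenario)
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2, default=_jsonify)
    )
    return path


def result_to_dict(result: CorrectionResult) -> dict:
    return {
        "method": result.method,
        "estimate": result.estimate,
        "ci_low": result.ci_low,
        "ci_high": result.ci_high,
        "n_used": result.n_used,
        "diagnostics": result.diagnostics,
    }


def write_result_json(result: CorrectionResult, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(result_to_dict(result), indent=2, default=_jsonify))
    return path


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")
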