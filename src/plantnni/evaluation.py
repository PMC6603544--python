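"""Validation and scenario evaluation of NNI predictions.

Goodness of fit is summarised by the adjusted determination coefficient
of the linear regression of measured on simulated NNI, plus RMSE and
MAE of the raw predictions.  Scenario agreement uses two regression-based
criteria: the relative standard error RE (residual standard error of
that regression divided by the mean measured value, in percent) and the
accuracy (Pearson correlation between simulated and measured values).
The test set can be stratified by N status (measured NNI above/below 1)
and by growth stage (seedling vs harvest dates); narrowing the measured
range in a stratum attenuates R² and accuracy even when predictions
remain close, which is the expected signature under N surplus.
"""

from __future__ import annotations

import json
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "compute_metrics",
    "agreement_metrics",
    "stratify",
    "evaluation_report",
    "default_stage_map",
]


def _pair(measured, simulated):
    y = np.asarray(measured, dtype=float).reshape(-1)
    yhat = np.asarray(simulated, dtype=float).reshape(-1)
    if y.shape != yhat.shape:
        raise ValueError("measured and simulated must have equal length")
    if y.size < 3:
        raise ValueError("need at least 3 samples")
    return y, yhat


def compute_metrics(measured, simulated) -> dict:
    """Adjusted R² (measured ~ simulated, one predictor), RMSE and MAE."""
    y, yhat = _pair(measured, simulated)
    n = y.size
    resid = y - yhat
    rmse = float(np.sqrt(np.mean(resid**2)))
    mae = float(np.mean(np.abs(resid)))
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: R² undefined, reported as 0")
        r2adj = 0.0
    else:
        r = stats.linregress(yhat, y).rvalue
        r2 = r * r
        r2adj = float(1.0 - (1.0 - r2) * (n - 1) / (n - 2))
    return {"r2": r2adj, "rmse": rmse, "mae": mae}


def agreement_metrics(measured, simulated) -> dict:
    """RE (%) and accuracy of the measured-vs-simulated regression.

    RE = 100 * s_e / mean(measured), where s_e is the residual standard
    error (n - 2 denominator) of the linear regression of measured on
    simulated; accuracy is the Pearson correlation.  Both are invariant
    under affine transformations of the simulated vector.
    """
    y, yhat = _pair(measured, simulated)
    mean_y = float(y.mean())
    if mean_y == 0:
        raise ValueError("mean of measured values must be nonzero")
    if np.ptp(yhat) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance: accuracy undefined, reported as nan")
        resid = y - y.mean()
        se = float(np.sqrt((resid @ resid) / (y.size - 2)))
        return {"re_pct": 100.0 * se / mean_y, "accuracy": float("nan")}
    fit = stats.linregress(yhat, y)
    resid = y - (fit.intercept + fit.slope * yhat)
    se = float(np.sqrt((resid @ resid) / (y.size - 2)))
    return {"re_pct": 100.0 * se / mean_y, "accuracy": float(fit.rvalue)}


def default_stage_map(days) -> dict:
    """Final sampling date = harvest, all earlier dates = seedling."""
    days = sorted(set(days))
    return {d: ("harvest" if d == days[-1] else "seedling") for d in days}


def stratify(predictions: pd.DataFrame, stage_map: dict | None = None) -> dict:
    """Split a prediction table into evaluation scopes.

    ``predictions`` needs columns ``measured_nni``, ``simulated_nni``
    and ``day``.  Returns scopes ``overall``, ``excessive`` (measured
    NNI > 1), ``deficient`` (< 1) and one scope per stage label.
    Samples with measured NNI exactly 1.00 belong to neither status
    scope (flagged with a warning).
    """
    if stage_map is None:
        stage_map = default_stage_map(predictions["day"])
    missing = set(predictions["day"]) - set(stage_map)
    if missing:
        raise ValueError(f"stage_map does not cover days: {sorted(missing)}")
    m = predictions["measured_nni"]
    if (m == 1.0).any():
        warnings.warn(
            f"{int((m == 1.0).sum())} sample(s) with measured NNI exactly 1.00 "
            "excluded from both status scopes"
        )
    scopes = {
        "overall": predictions,
        "excessive": predictions[m > 1.0],
        "deficient": predictions[m < 1.0],
    }
    stages = predictions["day"].map(stage_map)
    for stage in dict.fromkeys(stage_map.values()):
        scopes[stage] = predictions[stages == stage]
    return scopes


def _scope_row(scope_df: pd.DataFrame, overall: bool) -> dict:
    n = len(scope_df)
    row: dict = {"n": int(n)}
    if n == 0:
        row.update({k: None for k in
                    ("measured_range", "simulated_range", "r2", "re_pct",
                     "accuracy", "rmse", "mae")})
        return row
    y = scope_df["measured_nni"].to_numpy(dtype=float)
    yhat = scope_df["simulated_nni"].to_numpy(dtype=float)
    row["measured_range"] = [float(y.min()), float(y.max())]
    row["simulated_range"] = [float(yhat.min()), float(yhat.max())]
    if n < 3:
        row.update({k: None for k in ("r2", "re_pct", "accuracy", "rmse", "mae")})
        return row
    fit = compute_metrics(y, yhat)
    agree = agreement_metrics(y, yhat)
    row.update({"r2": fit["r2"], "re_pct": agree["re_pct"],
                "accuracy": agree["accuracy"]})
    row["rmse"] = fit["rmse"] if overall else None
    row["mae"] = fit["mae"] if overall else None
    return row


def evaluation_report(predictions_by_model: dict, stage_map: dict | None = None) -> dict:
    """Scenario evaluation table for one or more models.

    ``predictions_by_model`` maps a model name to a prediction table
    (columns ``measured_nni``, ``simulated_nni``, ``day``).  Each scope
    row reports n, measured/simulated ranges, R², RE % and accuracy;
    the overall scope adds RMSE and MAE.
    """
    report: dict = {}
    for name, preds in predictions_by_model.items():
        scopes = stratify(preds, stage_map)
        report[name] = {
            scope: _scope_row(df, overall=(scope == "overall"))
            for scope, df in scopes.items()
        }
    return report


def report_to_json(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=True)
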