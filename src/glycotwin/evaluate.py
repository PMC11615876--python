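"""Model and glycemia evaluation metrics.

Regression accuracy (MSE, RMSE, MAE, R²) of predicted vs observed glucose
peaks, rank-based AUC for spike/non-spike discrimination, the fraction of
predictions within a clinical tolerance, and CGM summary statistics
(time-in-range, daily-SD glycemic variability, % time above range).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .errors import (InsufficientDataError, InvalidConfigError,
                     InvalidInputError, UndefinedAUCError)


class RegressionMetrics(NamedTuple):
    mse: float
    rmse: float
    mae: float
    r2: float          # NaN when undefined (zero target variance)
    r2_defined: bool


@dataclass(frozen=True)
class SpikeDefinition:
    """What counts as a glucose spike.

    Default: a rise of more than 40 mg/dL above the adjusted baseline
    (``delta_above_threshold``); an absolute-level rule
    (``peak_above_absolute``, conventionally 180 mg/dL) is available.
    """

    rule: str = "delta_above_threshold"
    threshold_mgdl: float = 40.0

    def __post_init__(self):
        if self.threshold_mgdl <= 0:
            raise InvalidConfigError("spike threshold must be positive")
        if self.rule not in ("delta_above_threshold", "peak_above_absolute"):
            raise InvalidConfigError(f"unknown spike rule '{self.rule}'")

    def labels(self, observed: np.ndarray) -> np.ndarray:
        """Binary spike labels from observed impacts (deltas) or peaks."""
        return np.asarray(observed, dtype=float) > self.threshold_mgdl


def _check_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    yhat = np.asarray(yhat, dtype=float)
    if y.shape != yhat.shape or y.ndim != 1 or len(y) == 0:
        raise InvalidInputError(
            f"y and yhat must be equal-length nonempty 1-d arrays "
            f"(got {y.shape} vs {yhat.shape})")
    return y, yhat


def regression_metrics(y, yhat) -> RegressionMetrics:
    """MSE, RMSE, MAE and R² in their standard closed forms."""
    y, yhat = _check_pair(y, yhat)
    err = y - yhat
    mse = float(np.mean(err ** 2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot > 0:
        r2, defined = 1.0 - float(np.sum(err ** 2)) / ss_tot, True
    else:
        r2, defined = float("nan"), False
    return RegressionMetrics(mse, float(np.sqrt(mse)), mae, r2, defined)


def spike_auc(observed, scores,
              spike_def: SpikeDefinition | None = None) -> float:
    """Rank-based AUC (Mann-Whitney, midranks for ties) for spike detection."""
    spike_def = spike_def or SpikeDefinition()
    observed, scores = _check_pair(observed, scores)
    labels = spike_def.labels(observed)
    if labels.all() or not labels.any():
        raise UndefinedAUCError(
            "AUC undefined: only one class present under the spike rule")
    return float(roc_auc_score(labels, scores))


def within_tolerance(y, yhat, tol_mgdl: float = 40.0) -> float:
    """Fraction of predictions with absolute error <= tol_mgdl."""
    y, yhat = _check_pair(y, yhat)
    return float(np.mean(np.abs(y - yhat) <= tol_mgdl))


def cgm_summary(trace: pd.DataFrame, low: float = 70.0,
                high: float = 180.0) -> tuple[float, float, float]:
    """(TIR %, glycemic variability, % time above range) for one trace.

    TIR counts samples inside ``[low, high]`` inclusive. Glycemic
    variability is the SD of glucose computed per calendar day and averaged
    across days. Sample-weighted percentages assume the equal-interval grid
    produced by cleaning.
    """
    if trace is None or len(trace) == 0:
        raise InsufficientDataError("empty CGM trace")
    g = trace["glucose_mgdl"].to_numpy(float)
    tir = float(np.mean((g >= low) & (g <= high)) * 100.0)
    above = float(np.mean(g > high) * 100.0)
    days = trace["timestamp"].dt.normalize()
    daily_sd = trace.groupby(days)["glucose_mgdl"].std(ddof=0)
    return tir, float(daily_sd.mean()), above


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


REPORT_REQUIRED_KEYS = ("metrics", "confidence_intervals", "spike_rule",
                        "n_predictions", "seed", "config_hash",
                        "registry_hash", "per_fold")


def validate_report(report: dict) -> dict:
    """Schema check for a validation report (raises SchemaError on failure)."""
    from .errors import SchemaError
    missing = [k for k in REPORT_REQUIRED_KEYS if k not in report]
    if missing:
        raise SchemaError(f"validation report missing keys: {missing}")
    for k in ("mse", "rmse", "mae", "r2", "auc", "within_tolerance_pct"):
        if k not in report["metrics"]:
            raise SchemaError(f"validation report metrics missing '{k}'")
    return report


def validation_report(model, spike_def: SpikeDefinition | None = None,
                      out: str | Path | None = None, bootstrap_b: int = 500,
                      seed: int = 0, tol_mgdl: float = 40.0) -> dict:
    """Out-of-fold validation report for a trained PPGR model.

    All metrics are computed on the model's pooled outer-fold predictions —
    never on rows the ensemble was fit on. Percentile bootstrap confidence
    intervals (B resamples) accompany each metric. The report embeds the
    seeds and config/registry hashes needed to reproduce it, and round-trips
    through :func:`validate_report`.
    """
    spike_def = spike_def or SpikeDefinition()
    preds = model.outer_predictions
    y = preds["observed_peak_mgdl"].to_numpy(float)
    yhat = preds["predicted_peak_mgdl"].to_numpy(float)
    d = preds["observed_delta_mgdl"].to_numpy(float)
    dhat = preds["predicted_delta_mgdl"].to_numpy(float)

    def all_metrics(idx: np.ndarray) -> dict:
        m = regression_metrics(y[idx], yhat[idx])
        out = {"mse": m.mse, "rmse": m.rmse, "mae": m.mae, "r2": m.r2,
               "within_tolerance_pct":
                   within_tolerance(y[idx], yhat[idx], tol_mgdl) * 100.0}
        obs = d[idx] if spike_def.rule == "delta_above_threshold" else y[idx]
        try:
            out["auc"] = spike_auc(obs, dhat[idx], spike_def)
        except UndefinedAUCError:
            out["auc"] = float("nan")
        return out

    idx_all = np.arange(len(y))
    metrics = all_metrics(idx_all)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    boot = {k: [] for k in metrics}
    for _ in range(bootstrap_b):
        idx = rng.integers(0, len(y), size=len(y))
        for k, v in all_metrics(idx).items():
            boot[k].append(v)
    cis = {k: [float(np.nanpercentile(v, 2.5)),
               float(np.nanpercentile(v, 97.5))] for k, v in boot.items()}

    resid = y - yhat
    order = np.argsort(preds["meal_timestamp"].to_numpy())
    r = resid[order]
    diagnostics = {
        "residual_normality_p": float(stats.normaltest(resid).pvalue),
        "residual_lag1_autocorr": float(np.corrcoef(r[:-1], r[1:])[0, 1]),
        "residual_mean": float(resid.mean()),
    }

    report = {
        "metrics": metrics,
        "confidence_intervals": cis,
        "bootstrap_b": bootstrap_b,
        "spike_rule": {"rule": spike_def.rule,
                       "threshold_mgdl": spike_def.threshold_mgdl},
        "n_predictions": int(len(y)),
        "seed": seed,
        "model_seed": model.seed,
        "config_hash": config_hash(model.config_dict()),
        "registry_hash": model.registry_hash,
        "per_fold": model.report.get("per_fold", []),
        "residual_diagnostics": diagnostics,
        "model_version": model.version,
    }
    validate_report(report)
    if out is not None:
        with open(out, "w") as fh:
            json.dump(report, fh, indent=1)
    return report
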