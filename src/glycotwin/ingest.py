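"""Reading and repairing the standard tables.

Loads the CSV/JSON dialects written by the simulator (or any source matching
the schemas), flags sensor outliers with a robust rolling score, and fills
short CGM gaps by linear interpolation. Cleaning never alters observed,
unflagged values: outliers are flagged rather than deleted, and imputed
samples carry an ``imputed`` flag.

The multiple-imputation machinery (MICE, Rubin pooling, sensitivity suite)
lives in :mod:`glycotwin.imputation` and is re-exported here.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InvalidConfigError, SchemaError
from .imputation import (ImputationResult, mice_impute, rubin_pool,  # noqa: F401
                         sensitivity_suite)

CGM_COLUMNS = ("patient_id", "timestamp", "glucose_mgdl")
MEAL_COLUMNS = ("patient_id", "timestamp", "meal_type", "calories_kcal",
                "carbs_g", "protein_g", "fat_g", "fiber_g",
                "glycemic_index", "glycemic_load")
ACTIVITY_COLUMNS = ("patient_id", "timestamp", "steps", "active_minutes",
                    "sedentary_minutes")
SLEEP_COLUMNS = ("patient_id", "date", "sleep_minutes", "sleep_efficiency")


@dataclass
class PatientProfile:
    """Static clinical profile consumed as model features."""

    patient_id: str
    age: float
    sex: str
    bmi: float
    hba1c: float
    homa: float
    waist_cm: float
    medications: list = field(default_factory=list)

    def validate(self) -> "PatientProfile":
        if not (18 <= self.age <= 70):
            raise SchemaError(f"{self.patient_id}: age {self.age} outside [18, 70]")
        if not (3 <= self.hba1c <= 20):
            raise SchemaError(f"{self.patient_id}: HbA1c {self.hba1c} outside [3, 20]")
        return self


@dataclass
class RawDataset:
    """Typed tables plus a row-level error report from loading."""

    cgm: pd.DataFrame
    meals: pd.DataFrame
    activity: pd.DataFrame
    sleep: pd.DataFrame
    profiles: pd.DataFrame
    truth_ppgr: pd.DataFrame | None = None
    row_errors: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["table", "row", "error"]))

    def copy(self) -> "RawDataset":
        return RawDataset(
            self.cgm.copy(), self.meals.copy(), self.activity.copy(),
            self.sleep.copy(), self.profiles.copy(),
            None if self.truth_ppgr is None else self.truth_ppgr.copy(),
            self.row_errors.copy())


def _parse_table(df: pd.DataFrame, name: str, required: tuple,
                 time_col: str | None, errors: list) -> pd.DataFrame:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{name}: missing required column '{col}'")
    if time_col is not None:
        parsed = pd.to_datetime(df[time_col], errors="coerce", format="mixed")
        bad = parsed.isna() & df[time_col].notna()
        for i in df.index[bad]:
            errors.append({"table": name, "row": int(i),
                           "error": f"unparseable {time_col}: {df.loc[i, time_col]!r}"})
        df = df[~bad].copy()
        df[time_col] = parsed[~bad]
    return df


def load_dataset(path: str | Path) -> RawDataset:
    """Load a dataset directory (cgm/meals/activity/sleep + profiles.json).

    Missing columns raise :class:`SchemaError` naming the column; rows with
    unparseable timestamps are reported in ``row_errors`` and skipped while
    the rest of the table loads.
    """
    p = Path(path)
    errors: list[dict] = []
    cgm = _parse_table(pd.read_csv(p / "cgm.csv"), "cgm", CGM_COLUMNS,
                       "timestamp", errors)
    meals = _parse_table(pd.read_csv(p / "meals.csv"), "meals", MEAL_COLUMNS,
                         "timestamp", errors)
    activity = _parse_table(pd.read_csv(p / "activity.csv"), "activity",
                            ACTIVITY_COLUMNS, "timestamp", errors)
    sleep = _parse_table(pd.read_csv(p / "sleep.csv"), "sleep", SLEEP_COLUMNS,
                         "date", errors)
    with open(p / "profiles.json") as fh:
        profiles = pd.DataFrame(json.load(fh))
    for col in ("patient_id", "age", "sex", "bmi", "hba1c", "homa", "waist_cm"):
        if col not in profiles.columns:
            raise SchemaError(f"profiles: missing required column '{col}'")
    truth = None
    if (p / "truth_ppgr.csv").exists():
        truth = pd.read_csv(p / "truth_ppgr.csv",
                            parse_dates=["meal_timestamp"])
    return RawDataset(cgm=cgm, meals=meals, activity=activity, sleep=sleep,
                      profiles=profiles, truth_ppgr=truth,
                      row_errors=pd.DataFrame(
                          errors, columns=["table", "row", "error"]))


def flag_outliers(trace: pd.DataFrame, window: int = 9,
                  z_threshold: float = 4.0) -> pd.DataFrame:
    """Flag CGM samples deviating from the local trend; never deletes.

    The score is a robust z: |glucose - rolling median| / (1.4826 * rolling
    MAD), centered window of ``window`` samples. Samples above
    ``z_threshold`` get ``flag='outlier'``; everything else keeps its flag
    (or ``ok``). Lowering the threshold flags a superset. Median/MAD are
    used instead of mean/SD so the statistic is not dragged by the very
    spikes being detected.
    """
    if window < 3:
        raise InvalidConfigError("outlier window must be >= 3 samples")
    out = trace.sort_values("timestamp").reset_index(drop=True).copy()
    g = out["glucose_mgdl"].astype(float)
    med = g.rolling(window, center=True, min_periods=1).median()
    mad = (g - med).abs().rolling(window, center=True, min_periods=1).median()
    scale = np.maximum(1.4826 * mad.to_numpy(), 1.0)  # floor: sub-mg/dL MAD
    z = np.abs(g.to_numpy() - med.to_numpy()) / scale
    if "flag" not in out.columns:
        out["flag"] = "ok"
    out.loc[z > z_threshold, "flag"] = "outlier"
    out.loc[(z <= z_threshold) & (out["flag"] == "outlier"), "flag"] = "ok"
    return out


def interpolate_gaps(trace: pd.DataFrame, max_gap: float = 30.0,
                     interval_min: float | None = None) -> pd.DataFrame:
    """Fill interior CGM gaps up to ``max_gap`` minutes by linear interpolation.

    Inserted samples are flagged ``imputed``. Longer gaps are left missing
    (downstream feature assembly drops the affected meals), and endpoints are
    never extrapolated.
    """
    if trace.empty:
        return trace.copy()
    out = trace.sort_values("timestamp").reset_index(drop=True).copy()
    if "flag" not in out.columns:
        out["flag"] = "ok"
    ts = out["timestamp"]
    if interval_min is None:
        diffs = ts.diff().dt.total_seconds().dropna() / 60.0
        interval_min = float(diffs.median()) if len(diffs) else 5.0
    new_rows = []
    gaps = ts.diff().dt.total_seconds() / 60.0
    for i in np.flatnonzero((gaps > interval_min + 1e-9)
                            & (gaps <= max_gap + 1e-9)):
        t0, t1 = ts.iloc[i - 1], ts.iloc[i]
        g0 = float(out["glucose_mgdl"].iloc[i - 1])
        g1 = float(out["glucose_mgdl"].iloc[i])
        n_fill = int(round((t1 - t0).total_seconds() / 60.0 / interval_min)) - 1
        for j in range(1, n_fill + 1):
            tj = t0 + pd.Timedelta(minutes=j * interval_min)
            frac = (tj - t0).total_seconds() / (t1 - t0).total_seconds()
            row = {c: out[c].iloc[i - 1] for c in out.columns}
            row.update({"timestamp": tj,
                        "glucose_mgdl": g0 + frac * (g1 - g0),
                        "flag": "imputed"})
            new_rows.append(row)
    if not new_rows:
        return out
    filled = pd.concat([out, pd.DataFrame(new_rows)], ignore_index=True)
    return filled.sort_values("timestamp").reset_index(drop=True)


def clean_dataset(dataset, window: int = 9, z_threshold: float = 4.0,
                  max_gap: float = 30.0):
    """Flag outliers and fill short gaps for every patient trace.

    Returns ``(cleaned_dataset, report)`` where report counts flagged and
    imputed cells per patient (serializable as ``cleaning_report.json``).
    """
    out = dataset.copy()
    parts, report = [], {"patients": {}, "total_outliers": 0, "total_imputed": 0}
    for pid, trace in out.cgm.groupby("patient_id", sort=False):
        flagged = flag_outliers(trace, window, z_threshold)
        filled = interpolate_gaps(flagged, max_gap)
        n_out = int((filled["flag"] == "outlier").sum())
        n_imp = int((filled["flag"] == "imputed").sum())
        report["patients"][pid] = {"outliers_flagged": n_out,
                                   "samples_imputed": n_imp,
                                   "n_samples": int(len(filled))}
        report["total_outliers"] += n_out
        report["total_imputed"] += n_imp
        parts.append(filled)
    out.cgm = pd.concat(parts, ignore_index=True)
    return out, report


def write_cleaning_report(report: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=1)
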