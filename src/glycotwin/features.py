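"""Feature engineering: from cleaned streams to predictor rows.

Implements the Glucose Impact model's inputs: glucoseMax extraction from the
post-meal window, the medication-penalized pre-meal baseline, meal nutrition
features (carb-to-protein ratio, glycemic load reconciliation, meal spacing),
and the temporal context (trailing glucose trend, activity, prior-night
sleep) that stands in for the recurrent state h_t. Rows are assembled in the
order fixed by the 37-entry feature registry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (InsufficientDataError, InvalidInputError,
                     InvalidMealError, SchemaError)
from .registry import FeatureRegistry, load_registry

# Per-class baseline depression in mg/dL attributed to glucose-lowering
# agents. These magnitudes are configuration defaults chosen from typical
# fasting-glucose effects of each class; they are not trial-derived values.
DEFAULT_MED_PENALTIES: dict[str, float] = {
    "metformin": 6.0,
    "sulfonylurea": 8.0,
    "sglt2_inhibitor": 7.0,
    "glp1_agonist": 9.0,
}

MEAL_TYPES = ("breakfast", "lunch", "dinner", "snack")


@dataclass
class MealRecord:
    """One logged eating event with its nutrient composition."""

    patient_id: str
    timestamp: pd.Timestamp
    meal_type: str
    items: list[tuple[str, float]]  # (food_id, grams or portions)
    calories_kcal: float
    carbs_g: float
    protein_g: float
    fat_g: float
    fiber_g: float
    glycemic_index: float
    glycemic_load: float

    def validate(self) -> "MealRecord":
        macros = (self.calories_kcal, self.carbs_g, self.protein_g,
                  self.fat_g, self.fiber_g)
        if any(v < 0 for v in macros):
            raise InvalidMealError(
                f"meal at {self.timestamp} has negative nutrient totals")
        if not (0 <= self.glycemic_index <= 110):
            raise InvalidMealError(
                f"glycemic index {self.glycemic_index} outside [0, 110]")
        return self


@dataclass
class TemporalContext:
    """Trailing-window summary of glucose, activity and sleep at meal time."""

    premeal_slope_mgdl_min: float
    trail1h_mean_mgdl: float
    trail1h_sd_mgdl: float
    trail6h_mean_mgdl: float
    trail6h_sd_mgdl: float
    trail24h_mean_mgdl: float
    trail24h_sd_mgdl: float
    steps_prev_1h: float
    steps_prev_24h: float
    active_min_prev_24h: float
    sedentary_min_prev_24h: float
    sleep_minutes_prev_night: float
    sleep_efficiency_prev_night: float


@dataclass
class FeatureConfig:
    """Tunable windows and conventions for feature extraction."""

    premeal_window_min: float = 30.0
    min_premeal_samples: int = 3
    peak_window_min: float = 120.0
    slope_window_min: float = 30.0
    eps_protein_g: float = 1.0
    time_since_last_meal_cap_min: float = 960.0
    penalty_table: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_MED_PENALTIES))


def _clean_samples(trace: pd.DataFrame) -> pd.DataFrame:
    """Drop outlier-flagged samples; imputed and ok samples are usable."""
    if "flag" in trace.columns:
        return trace[trace["flag"] != "outlier"]
    return trace


def baseline_glucose(trace: pd.DataFrame, meal_time: pd.Timestamp,
                     medications: Sequence[Mapping] | Sequence[str],
                     penalty_table: Mapping[str, float] | None = None,
                     window_min: float = 30.0,
                     min_samples: int = 3) -> float:
    """Medication-penalized pre-meal baseline.

    Median glucose over the ``window_min`` minutes ending at ``meal_time``,
    plus the configured penalty for each active glucose-lowering agent. The
    penalty compensates for pharmacologically depressed baselines so that
    normalized impacts remain comparable across medicated patients.
    """
    penalty_table = dict(DEFAULT_MED_PENALTIES if penalty_table is None
                         else penalty_table)
    clean = _clean_samples(trace)
    lo = meal_time - pd.Timedelta(minutes=window_min)
    window = clean[(clean["timestamp"] >= lo) & (clean["timestamp"] <= meal_time)]
    if len(window) < max(1, min_samples):
        raise InsufficientDataError(
            f"only {len(window)} pre-meal samples in the {window_min}-min "
            f"window before {meal_time} (need {min_samples})")
    penalty = 0.0
    for med in medications:
        name = med["name"] if isinstance(med, Mapping) else str(med)
        penalty += max(0.0, float(penalty_table.get(name, 0.0)))
    return float(window["glucose_mgdl"].median()) + penalty


def glucose_max(trace: pd.DataFrame, meal_time: pd.Timestamp,
                window_minutes: float = 120.0) -> tuple[float, float]:
    """Peak glucose in the post-meal window and its offset in minutes.

    The window is ``(meal_time, meal_time + window_minutes]``; ties are broken
    by the earliest sample.
    """
    clean = _clean_samples(trace).sort_values("timestamp")
    hi = meal_time + pd.Timedelta(minutes=window_minutes)
    window = clean[(clean["timestamp"] > meal_time) & (clean["timestamp"] <= hi)]
    if window.empty:
        raise InsufficientDataError(
            f"no CGM samples within {window_minutes} min after {meal_time}")
    glucose = window["glucose_mgdl"].to_numpy()
    i = int(np.argmax(glucose))  # argmax returns the first maximum
    offset = (window["timestamp"].iloc[i] - meal_time).total_seconds() / 60.0
    return float(glucose[i]), float(offset)


def normalized_impact(peak_mgdl: float,
                      adjusted_baseline_mgdl: float) -> tuple[float, float]:
    """Glucose impact as (delta, relative fraction) vs the adjusted baseline."""
    if adjusted_baseline_mgdl <= 0:
        raise InvalidInputError("adjusted baseline must be positive")
    delta = peak_mgdl - adjusted_baseline_mgdl
    return delta, delta / adjusted_baseline_mgdl


def meal_features(meal: MealRecord,
                  meal_history: Iterable[pd.Timestamp],
                  config: FeatureConfig | None = None) -> dict:
    """Meal-level engineered features.

    carb_to_protein_ratio uses a small epsilon floor on protein; the glycemic
    load is recomputed as GI/100 x carbs and reconciled against the logged
    value (recomputed value wins when they disagree beyond rounding).
    time_since_last_meal is capped for the first meal on record and flagged.
    """
    config = config or FeatureConfig()
    meal.validate()
    ratio = meal.carbs_g / max(meal.protein_g, config.eps_protein_g)
    gl = meal.glycemic_index / 100.0 * meal.carbs_g
    gl_mismatch = abs(gl - meal.glycemic_load) > 0.5
    prior = [t for t in meal_history if t < meal.timestamp]
    if prior:
        gap = (meal.timestamp - max(prior)).total_seconds() / 60.0
        tsl = min(gap, config.time_since_last_meal_cap_min)
        first = False
    else:
        tsl = config.time_since_last_meal_cap_min
        first = True
    return {
        "carb_to_protein_ratio": float(ratio),
        "glycemic_load": float(gl),
        "glycemic_load_reconciled": bool(gl_mismatch),
        "time_since_last_meal_min": float(tsl),
        "first_meal_on_record": first,
    }


def temporal_context(trace: pd.DataFrame, activity: pd.DataFrame,
                     sleep: pd.DataFrame, meal_time: pd.Timestamp,
                     config: FeatureConfig | None = None) -> TemporalContext:
    """Trailing glucose trend plus wearable context at meal time.

    The pre-meal slope is the least-squares slope (mg/dL per minute) over the
    trailing ``slope_window_min`` window and requires at least two samples;
    the longer trailing means/SDs use whatever samples the window holds
    (at least two) so that early-study meals remain usable.
    """
    config = config or FeatureConfig()
    clean = _clean_samples(trace)
    ts = clean["timestamp"]

    def _window_stats(minutes: float) -> tuple[float, float, np.ndarray, np.ndarray]:
        lo = meal_time - pd.Timedelta(minutes=minutes)
        sel = clean[(ts >= lo) & (ts <= meal_time)]
        g = sel["glucose_mgdl"].to_numpy(float)
        t = (sel["timestamp"] - meal_time).dt.total_seconds().to_numpy() / 60.0
        if len(g) < 2:
            raise InsufficientDataError(
                f"fewer than 2 glucose samples in trailing {minutes}-min window")
        return float(g.mean()), float(g.std(ddof=0)), t, g

    _, _, t_sl, g_sl = _window_stats(config.slope_window_min)
    slope = float(np.polyfit(t_sl, g_sl, 1)[0])
    m1, s1, _, _ = _window_stats(60.0)
    m6, s6, _, _ = _window_stats(360.0)
    m24, s24, _, _ = _window_stats(1440.0)

    a = activity[(activity["timestamp"] >= meal_time - pd.Timedelta(hours=24))
                 & (activity["timestamp"] < meal_time)]
    a1 = a[a["timestamp"] >= meal_time - pd.Timedelta(hours=1)]

    night = sleep[sleep["date"] <= meal_time.normalize()]
    if night.empty:
        raise InsufficientDataError("no sleep record before meal")
    night = night.iloc[-1]

    return TemporalContext(
        premeal_slope_mgdl_min=slope,
        trail1h_mean_mgdl=m1, trail1h_sd_mgdl=s1,
        trail6h_mean_mgdl=m6, trail6h_sd_mgdl=s6,
        trail24h_mean_mgdl=m24, trail24h_sd_mgdl=s24,
        steps_prev_1h=float(a1["steps"].sum()),
        steps_prev_24h=float(a["steps"].sum()),
        active_min_prev_24h=float(a["active_minutes"].sum()),
        sedentary_min_prev_24h=float(a["sedentary_minutes"].sum()),
        sleep_minutes_prev_night=float(night["sleep_minutes"]),
        sleep_efficiency_prev_night=float(night["sleep_efficiency"]),
    )


def assemble_features(profile: Mapping, meal: MealRecord,
                      context: TemporalContext, baseline_mgdl: float,
                      registry: FeatureRegistry,
                      config: FeatureConfig | None = None,
                      meal_history: Iterable[pd.Timestamp] = ()) -> np.ndarray:
    """Assemble one predictor row in registry order.

    Pure function of its inputs; raises SchemaError if the registry does not
    match the bundled 37-feature contract this builder implements.
    """
    config = config or FeatureConfig()
    mf = meal_features(meal, meal_history, config)
    meds = profile.get("medications", [])
    med_names = [m["name"] if isinstance(m, Mapping) else str(m) for m in meds]
    penalty_total = sum(max(0.0, float(config.penalty_table.get(n, 0.0)))
                        for n in med_names)
    hour = meal.timestamp.hour + meal.timestamp.minute / 60.0
    values = {
        "age_years": float(profile["age"]),
        "sex_male": 1.0 if str(profile["sex"]).upper().startswith("M") else 0.0,
        "bmi_kg_m2": float(profile["bmi"]),
        "hba1c_pct": float(profile["hba1c"]),
        "homa_index": float(profile["homa"]),
        "waist_cm": float(profile["waist_cm"]),
        "calories_kcal": float(meal.calories_kcal),
        "carbs_g": float(meal.carbs_g),
        "protein_g": float(meal.protein_g),
        "fat_g": float(meal.fat_g),
        "fiber_g": float(meal.fiber_g),
        "glycemic_index": float(meal.glycemic_index),
        "glycemic_load": mf["glycemic_load"],
        "carb_to_protein_ratio": mf["carb_to_protein_ratio"],
        "time_since_last_meal_min": mf["time_since_last_meal_min"],
        "meal_breakfast": 1.0 if meal.meal_type == "breakfast" else 0.0,
        "meal_lunch": 1.0 if meal.meal_type == "lunch" else 0.0,
        "meal_dinner": 1.0 if meal.meal_type == "dinner" else 0.0,
        "meal_snack": 1.0 if meal.meal_type == "snack" else 0.0,
        "hour_sin": float(np.sin(2 * np.pi * hour / 24.0)),
        "hour_cos": float(np.cos(2 * np.pi * hour / 24.0)),
        "premeal_baseline_mgdl": float(baseline_mgdl),
        "premeal_slope_mgdl_min": context.premeal_slope_mgdl_min,
        "trail1h_mean_mgdl": context.trail1h_mean_mgdl,
        "trail1h_sd_mgdl": context.trail1h_sd_mgdl,
        "trail6h_mean_mgdl": context.trail6h_mean_mgdl,
        "trail6h_sd_mgdl": context.trail6h_sd_mgdl,
        "trail24h_mean_mgdl": context.trail24h_mean_mgdl,
        "trail24h_sd_mgdl": context.trail24h_sd_mgdl,
        "steps_prev_1h": context.steps_prev_1h,
        "steps_prev_24h": context.steps_prev_24h,
        "active_min_prev_24h": context.active_min_prev_24h,
        "sedentary_min_prev_24h": context.sedentary_min_prev_24h,
        "sleep_minutes_prev_night": context.sleep_minutes_prev_night,
        "sleep_efficiency_prev_night": context.sleep_efficiency_prev_night,
        "n_glucose_lowering_meds": float(len(med_names)),
        "med_penalty_total_mgdl": penalty_total,
    }
    missing = [n for n in registry.names if n not in values]
    if missing:
        raise SchemaError(f"registry names not produced by assembler: {missing}")
    vec = np.array([values[n] for n in registry.names], dtype=float)
    if not np.all(np.isfinite(vec)):
        bad = [n for n, v in zip(registry.names, vec) if not np.isfinite(v)]
        raise InsufficientDataError(f"non-finite feature values: {bad}")
    return vec


_EPOCH = pd.Timestamp("2000-01-01")


def _minutes(ts: pd.Series) -> np.ndarray:
    return ((ts - _EPOCH).dt.total_seconds() / 60.0).to_numpy()


def build_feature_table(dataset, registry: FeatureRegistry | None = None,
                        config: FeatureConfig | None = None
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build the full predictor table for every meal in a dataset.

    ``dataset`` is any object exposing ``cgm``, ``meals``, ``activity``,
    ``sleep`` and ``profiles`` DataFrames (the simulator's output or a loaded
    directory). Returns ``(features, exclusions)``: one feature row per meal
    with targets (observed peak, delta, relative impact, adjusted baseline)
    alongside, and a table of excluded meals with the reason for each.

    This is a vectorized fast path over sorted per-patient arrays; its
    conventions are identical to the per-operation functions (pre-meal window
    ``[t-30, t]``, peak window ``(t, t+120]``, outlier samples excluded) and
    the test suite asserts row-level agreement with op-by-op assembly.
    """
    registry = registry or load_registry()
    config = config or FeatureConfig()
    names = list(registry.names)
    profiles = dataset.profiles.set_index("patient_id")
    rows, meta, excluded = [], [], []

    for pid, meals in dataset.meals.groupby("patient_id", sort=False):
        trace = dataset.cgm[dataset.cgm["patient_id"] == pid]
        trace = _clean_samples(trace).sort_values("timestamp")
        t = _minutes(trace["timestamp"])
        g = trace["glucose_mgdl"].to_numpy(float)

        act = dataset.activity[dataset.activity["patient_id"] == pid]
        act = act.sort_values("timestamp")
        ta = _minutes(act["timestamp"])
        cum_steps = np.concatenate([[0.0], np.cumsum(act["steps"].to_numpy(float))])
        cum_active = np.concatenate([[0.0], np.cumsum(act["active_minutes"].to_numpy(float))])
        cum_sed = np.concatenate([[0.0], np.cumsum(act["sedentary_minutes"].to_numpy(float))])

        slp = dataset.sleep[dataset.sleep["patient_id"] == pid].sort_values("date")
        t_sleep = _minutes(pd.to_datetime(slp["date"]))
        sleep_min = slp["sleep_minutes"].to_numpy(float)
        sleep_eff = slp["sleep_efficiency"].to_numpy(float)

        profile = profiles.loc[pid].to_dict()
        profile["medications"] = profile.get("medications") or []
        med_names = [m["name"] if isinstance(m, Mapping) else str(m)
                     for m in profile["medications"]]
        penalty_total = sum(max(0.0, float(config.penalty_table.get(n, 0.0)))
                            for n in med_names)
        static = {
            "age_years": float(profile["age"]),
            "sex_male": 1.0 if str(profile["sex"]).upper().startswith("M") else 0.0,
            "bmi_kg_m2": float(profile["bmi"]),
            "hba1c_pct": float(profile["hba1c"]),
            "homa_index": float(profile["homa"]),
            "waist_cm": float(profile["waist_cm"]),
            "n_glucose_lowering_meds": float(len(med_names)),
            "med_penalty_total_mgdl": penalty_total,
        }

        meals = meals.sort_values("timestamp")
        tm_all = _minutes(meals["timestamp"])

        def glucose_window(lo: float, hi: float, lo_open: bool = False,
                           ) -> tuple[np.ndarray, np.ndarray]:
            i = np.searchsorted(t, lo, side="right" if lo_open else "left")
            j = np.searchsorted(t, hi, side="right")
            return t[i:j], g[i:j]

        def activity_sum(cum: np.ndarray, lo: float, hi: float) -> float:
            i = np.searchsorted(ta, lo, side="left")
            j = np.searchsorted(ta, hi, side="left")
            return float(cum[j] - cum[i])

        for k, (_, m) in enumerate(meals.iterrows()):
            tm = tm_all[k]
            stamp = m["timestamp"]

            t_pre, g_pre = glucose_window(tm - config.premeal_window_min, tm)
            if len(g_pre) < max(1, config.min_premeal_samples):
                excluded.append({"patient_id": pid, "meal_timestamp": stamp,
                                 "reason": "no baseline"})
                continue
            t_pk, g_pk = glucose_window(tm, tm + config.peak_window_min,
                                        lo_open=True)
            if len(g_pk) == 0:
                excluded.append({"patient_id": pid, "meal_timestamp": stamp,
                                 "reason": "no post-meal samples"})
                continue

            ok = True
            trail = {}
            for label, wmin in (("trail1h", 60.0), ("trail6h", 360.0),
                                ("trail24h", 1440.0)):
                _, gw = glucose_window(tm - wmin, tm)
                if len(gw) < 2:
                    ok = False
                    break
                trail[f"{label}_mean_mgdl"] = float(gw.mean())
                trail[f"{label}_sd_mgdl"] = float(gw.std(ddof=0))
            t_sl, g_sl = glucose_window(tm - config.slope_window_min, tm)
            if not ok or len(g_sl) < 2:
                excluded.append({"patient_id": pid, "meal_timestamp": stamp,
                                 "reason": "insufficient trailing glucose"})
                continue
            x = t_sl - tm
            slope = float(np.polyfit(x, g_sl, 1)[0])

            i_night = np.searchsorted(t_sleep, tm, side="right") - 1
            if i_night < 0:
                excluded.append({"patient_id": pid, "meal_timestamp": stamp,
                                 "reason": "no sleep record"})
                continue

            base = float(np.median(g_pre)) + penalty_total
            ipk = int(np.argmax(g_pk))
            peak, tpeak = float(g_pk[ipk]), float(t_pk[ipk] - tm)
            delta, rel = normalized_impact(peak, base)

            ratio = m["carbs_g"] / max(m["protein_g"], config.eps_protein_g)
            gl = m["glycemic_index"] / 100.0 * m["carbs_g"]
            tsl = (min(tm - tm_all[k - 1], config.time_since_last_meal_cap_min)
                   if k > 0 else config.time_since_last_meal_cap_min)
            hour = stamp.hour + stamp.minute / 60.0

            values = dict(static)
            values.update(trail)
            values.update({
                "calories_kcal": float(m["calories_kcal"]),
                "carbs_g": float(m["carbs_g"]),
                "protein_g": float(m["protein_g"]),
                "fat_g": float(m["fat_g"]),
                "fiber_g": float(m["fiber_g"]),
                "glycemic_index": float(m["glycemic_index"]),
                "glycemic_load": float(gl),
                "carb_to_protein_ratio": float(ratio),
                "time_since_last_meal_min": float(tsl),
                "meal_breakfast": 1.0 if m["meal_type"] == "breakfast" else 0.0,
                "meal_lunch": 1.0 if m["meal_type"] == "lunch" else 0.0,
                "meal_dinner": 1.0 if m["meal_type"] == "dinner" else 0.0,
                "meal_snack": 1.0 if m["meal_type"] == "snack" else 0.0,
                "hour_sin": float(np.sin(2 * np.pi * hour / 24.0)),
                "hour_cos": float(np.cos(2 * np.pi * hour / 24.0)),
                "premeal_baseline_mgdl": base,
                "premeal_slope_mgdl_min": slope,
                "steps_prev_1h": activity_sum(cum_steps, tm - 60.0, tm),
                "steps_prev_24h": activity_sum(cum_steps, tm - 1440.0, tm),
                "active_min_prev_24h": activity_sum(cum_active, tm - 1440.0, tm),
                "sedentary_min_prev_24h": activity_sum(cum_sed, tm - 1440.0, tm),
                "sleep_minutes_prev_night": float(sleep_min[i_night]),
                "sleep_efficiency_prev_night": float(sleep_eff[i_night]),
            })
            try:
                rows.append([values[n] for n in names])
            except KeyError as err:
                raise SchemaError(f"registry name not produced: {err}") from err
            meta.append({"patient_id": pid, "meal_timestamp": stamp,
                         "observed_peak_mgdl": peak,
                         "minutes_to_peak": tpeak,
                         "adjusted_baseline_mgdl": base,
                         "observed_delta_mgdl": delta,
                         "observed_relative_impact": rel})

    feat = pd.DataFrame(rows, columns=names, dtype=float)
    meta_df = pd.DataFrame(meta, columns=list(META_COLUMNS))
    out = pd.concat([meta_df.reset_index(drop=True),
                     feat.reset_index(drop=True)], axis=1)
    excl = pd.DataFrame(excluded,
                        columns=["patient_id", "meal_timestamp", "reason"])
    return out, excl


META_COLUMNS = ("patient_id", "meal_timestamp", "observed_peak_mgdl",
                "minutes_to_peak", "adjusted_baseline_mgdl",
                "observed_delta_mgdl", "observed_relative_impact")
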