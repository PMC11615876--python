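"""Virtual T2D cohort simulator with a known meal-response mechanism.

Every downstream stage of the pipeline (cleaning, feature engineering,
prediction, recommendation) is validated against this generator, whose
ground truth is available in closed form.

Mechanism
---------
Each virtual patient carries a basal glucose level, a circadian modulation,
and linear sensitivities to meal composition. A meal raises glucose by a
piecewise-linear rise followed by an exponential decay; the noiseless peak
rise is the closed-form kernel

    rise = carb_sensitivity * carbs * GI/100 * (1 - activity_damping * recent_kilosteps)
           - fiber_damping * fiber
           - protein_fat_damping * (protein + fat)
           + sleep_penalty * max(0, 7h - sleep),   floored at 0.

Carbohydrate sensitivity is tied to the patient's HbA1c (plus a small
idiosyncratic term), so that individual responsiveness is largely visible to
a model through observable labs — the premise of the digital-twin approach.
Sensor noise is iid Gaussian per CGM sample. Patients enroll staggered over
a configurable span, as cohorts accrue in practice; this is what makes
temporal-gap cross-validation feasible on a 30-day wear.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidConfigError, InvalidMealError
from .features import DEFAULT_MED_PENALTIES, MealRecord

# Documented parameter distributions for the virtual cohort. Chosen to yield
# medicated-T2D-like traces: basal ~110 mg/dL, HbA1c ~7.5%, post-meal rises
# mostly 20-140 mg/dL with wide between-meal and between-patient spread.
BASAL_MEAN, BASAL_SD, BASAL_LO, BASAL_HI = 110.0, 15.0, 80.0, 180.0
HBA1C_MEAN, HBA1C_SD, HBA1C_LO, HBA1C_HI = 7.5, 1.2, 5.8, 11.5
CARB_SENS_INTERCEPT = 0.35       # mg/dL per g carb at GI 100
CARB_SENS_PER_HBA1C = 0.22
CARB_SENS_IDIO_SD = 0.05

MEAL_SLOTS = {"breakfast": 8.0, "lunch": 13.0, "dinner": 19.0, "snack": 16.5}


def truncated_normal_mean(mean: float, sd: float, lo: float, hi: float) -> float:
    """Mean of the truncated normal used for basal glucose (documented oracle)."""
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return float(stats.truncnorm.mean(a, b, loc=mean, scale=sd))


@dataclass(frozen=True)
class KernelShape:
    """Timing constants of the meal-response curve (minutes)."""

    rise_time_min: float = 45.0
    decay_tau_min: float = 35.0
    window_min: float = 120.0

    @property
    def support_min(self) -> float:
        # curve is exactly back to baseline at window end + decay constant
        return self.window_min + self.decay_tau_min


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation configuration; the seed fully determines output."""

    n_patients: int = 60
    days: int = 30
    cgm_interval: int = 5           # minutes
    meals_per_day: int = 3
    seed: int = 0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    noise_sd: float = 12.0          # mg/dL sensor noise
    enrollment_span_days: int = 60  # staggered enrollment window
    start_date: str = "2024-01-01"
    kernel: KernelShape = field(default_factory=KernelShape)

    def validate(self) -> "SimConfig":
        if self.n_patients < 1:
            raise InvalidConfigError("n_patients must be >= 1")
        if self.cgm_interval <= 0:
            raise InvalidConfigError("cgm_interval must be positive")
        if not (0 <= self.missing_rate < 1) or not (0 <= self.outlier_rate < 1):
            raise InvalidConfigError("missing/outlier rates must be in [0, 1)")
        if self.noise_sd < 0:
            raise InvalidConfigError("noise_sd must be >= 0")
        if self.days < 1 or self.meals_per_day < 1:
            raise InvalidConfigError("days and meals_per_day must be >= 1")
        return self


@dataclass
class GroundTruthPatient:
    """Hidden mechanism parameters plus the observable profile."""

    patient_id: str
    basal_glucose: float            # mg/dL, before medication depression
    circadian_amplitude: float      # mg/dL
    circadian_phase_hour: float     # hour of circadian maximum
    carb_sensitivity: float         # mg/dL per g carb at GI 100
    fiber_damping: float            # mg/dL per g fiber
    protein_fat_damping: float      # mg/dL per g protein+fat
    activity_damping: float         # fraction of carb term per 1000 steps/h
    sleep_penalty: float            # mg/dL per hour of sleep deficit (<7 h)
    med_effect: float               # mg/dL baseline depression, all agents
    noise_sd: float                 # mg/dL sensor noise
    # observable profile
    age: int = 50
    sex: str = "F"
    bmi: float = 28.0
    hba1c: float = 7.5
    homa: float = 3.5
    waist_cm: float = 95.0
    medications: list = field(default_factory=list)

    def validate(self) -> "GroundTruthPatient":
        if not (60.0 <= self.basal_glucose <= 250.0):
            raise InvalidConfigError("basal_glucose outside [60, 250]")
        nonneg = (self.carb_sensitivity, self.fiber_damping,
                  self.protein_fat_damping, self.activity_damping,
                  self.sleep_penalty, self.noise_sd, self.med_effect)
        if any(v < 0 for v in nonneg):
            raise InvalidConfigError("sensitivities/damping/noise must be >= 0")
        return self

    @property
    def effective_basal(self) -> float:
        return self.basal_glucose - self.med_effect


@dataclass
class MealContext:
    """Temporal context consumed by the response kernel."""

    steps_prev_1h: float = 0.0
    sleep_hours_prev_night: float = 7.0


@dataclass
class SyntheticDataset:
    """All simulated streams on one shared clock, plus the ground truth."""

    cgm: pd.DataFrame        # patient_id, timestamp, glucose_mgdl [, is_injected_outlier]
    meals: pd.DataFrame
    activity: pd.DataFrame
    sleep: pd.DataFrame
    profiles: pd.DataFrame
    truth_ppgr: pd.DataFrame
    config: SimConfig | None = None

    def copy(self) -> "SyntheticDataset":
        return SyntheticDataset(self.cgm.copy(), self.meals.copy(),
                                self.activity.copy(), self.sleep.copy(),
                                self.profiles.copy(), self.truth_ppgr.copy(),
                                self.config)

    def save(self, outdir: str | Path) -> None:
        """Write the standard CSV/JSON dialects (UTC ISO-8601, mg/dL)."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        cgm = self.cgm.drop(columns=["is_injected_outlier"], errors="ignore")
        cgm.to_csv(out / "cgm.csv", index=False)
        self.meals.to_csv(out / "meals.csv", index=False)
        self.activity.to_csv(out / "activity.csv", index=False)
        self.sleep.to_csv(out / "sleep.csv", index=False)
        self.truth_ppgr.to_csv(out / "truth_ppgr.csv", index=False)
        profiles = self.profiles.to_dict(orient="records")
        with open(out / "profiles.json", "w") as fh:
            json.dump(profiles, fh, indent=1, default=str)


def generate_cohort(config: SimConfig) -> list[GroundTruthPatient]:
    """Draw a cohort from the documented parameter distributions.

    Deterministic for a fixed seed: a single generator with a fixed drawing
    order produces byte-identical parameter tables across calls.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a, b = (BASAL_LO - BASAL_MEAN) / BASAL_SD, (BASAL_HI - BASAL_MEAN) / BASAL_SD
    patients = []
    med_classes = list(DEFAULT_MED_PENALTIES)
    for i in range(config.n_patients):
        basal = float(stats.truncnorm.rvs(a, b, loc=BASAL_MEAN, scale=BASAL_SD,
                                          random_state=rng))
        hba1c = float(np.clip(rng.normal(HBA1C_MEAN, HBA1C_SD),
                              HBA1C_LO, HBA1C_HI))
        homa = float(np.clip(rng.lognormal(np.log(3.5), 0.4), 1.0, 12.0))
        bmi = float(np.clip(rng.normal(28.5, 4.0), 19.0, 42.0))
        n_meds = int(rng.choice([0, 1, 2, 3], p=[0.15, 0.35, 0.35, 0.15]))
        classes = list(rng.choice(med_classes, size=n_meds, replace=False))
        meds = [{"name": c, "dose_mg": {"metformin": 1000, "sulfonylurea": 4,
                                        "sglt2_inhibitor": 10,
                                        "glp1_agonist": 1}[c],
                 "schedule": "daily"} for c in classes]
        cs = float(np.clip(CARB_SENS_INTERCEPT + CARB_SENS_PER_HBA1C * hba1c
                           + rng.normal(0.0, CARB_SENS_IDIO_SD), 0.3, 4.0))
        p = GroundTruthPatient(
            patient_id=f"P{i + 1:03d}",
            basal_glucose=basal,
            circadian_amplitude=float(rng.uniform(4.0, 12.0)),
            circadian_phase_hour=float(rng.uniform(5.0, 9.0)),
            carb_sensitivity=cs,
            fiber_damping=float(rng.uniform(0.8, 1.2)),
            protein_fat_damping=float(rng.uniform(0.25, 0.35)),
            activity_damping=float(rng.uniform(0.02, 0.05)),
            sleep_penalty=float(rng.uniform(2.0, 5.0)),
            med_effect=sum(DEFAULT_MED_PENALTIES[c] for c in classes),
            noise_sd=config.noise_sd,
            age=int(rng.integers(25, 70)),
            sex="M" if rng.random() < 0.5 else "F",
            bmi=bmi,
            hba1c=hba1c,
            homa=homa,
            waist_cm=float(70.0 + 1.8 * (bmi - 20.0) + rng.normal(0.0, 5.0)),
            medications=meds,
        )
        patients.append(p.validate())
    return patients


def closed_form_rise(patient: GroundTruthPatient, meal: MealRecord,
                     context: MealContext | None = None) -> float:
    """The generator's noiseless peak rise above baseline, in mg/dL."""
    context = context or MealContext()
    if min(meal.carbs_g, meal.protein_g, meal.fat_g, meal.fiber_g) < 0:
        raise InvalidMealError("meal macronutrients must be >= 0")
    carb_term = (patient.carb_sensitivity * meal.carbs_g
                 * meal.glycemic_index / 100.0)
    activity_frac = min(patient.activity_damping
                        * context.steps_prev_1h / 1000.0, 0.9)
    sleep_deficit_h = max(0.0, 7.0 - context.sleep_hours_prev_night)
    rise = (carb_term * (1.0 - activity_frac)
            - patient.fiber_damping * meal.fiber_g
            - patient.protein_fat_damping * (meal.protein_g + meal.fat_g)
            + patient.sleep_penalty * sleep_deficit_h)
    return max(rise, 0.0)


def kernel_curve(rise: float, offsets_min: np.ndarray,
                 kernel: KernelShape) -> np.ndarray:
    """Evaluate the rise/decay kernel at post-meal offsets (minutes)."""
    t = np.asarray(offsets_min, dtype=float)
    out = np.zeros_like(t)
    up = (t >= 0) & (t <= kernel.rise_time_min)
    out[up] = rise * t[up] / kernel.rise_time_min
    down = (t > kernel.rise_time_min) & (t < kernel.support_min)
    out[down] = rise * np.exp(-(t[down] - kernel.rise_time_min)
                              / kernel.decay_tau_min)
    return out


def simulate_meal_response(patient: GroundTruthPatient, meal: MealRecord,
                           context: MealContext | None = None,
                           noise_sd_override: float | None = None,
                           kernel: KernelShape | None = None,
                           cgm_interval: int = 5,
                           rng: np.random.Generator | None = None
                           ) -> tuple[np.ndarray, np.ndarray]:
    """Glucose curve segment for one meal: (offsets min, glucose mg/dL).

    The noiseless curve is the patient's effective basal plus the kernel;
    the peak rise equals :func:`closed_form_rise` exactly and occurs at
    ``rise_time_min`` (inside the post-meal window), and the curve is back
    at baseline by window end + decay constant.
    """
    kernel = kernel or patient_kernel_default()
    noise_sd = patient.noise_sd if noise_sd_override is None else noise_sd_override
    rise = closed_form_rise(patient, meal, context)
    offsets = np.arange(0.0, kernel.support_min + cgm_interval, cgm_interval)
    curve = patient.effective_basal + kernel_curve(rise, offsets, kernel)
    if noise_sd > 0:
        rng = rng or np.random.default_rng(0)
        curve = curve + rng.normal(0.0, noise_sd, size=curve.shape)
    return offsets, curve


def patient_kernel_default() -> KernelShape:
    return KernelShape()


def _sample_meal(rng: np.random.Generator, foods: pd.DataFrame,
                 pid: str, stamp: pd.Timestamp, meal_type: str) -> MealRecord:
    """Compose a meal from 2-3 bundled foods with portion multipliers."""
    k = int(rng.choice([2, 3]))
    idx = rng.choice(len(foods), size=k, replace=False)
    mult = rng.uniform(0.7, 1.6, size=k)
    sel = foods.iloc[idx]
    carbs = float(np.dot(sel["carbs_g"], mult))
    totals = {c: float(np.dot(sel[c], mult))
              for c in ("calories_kcal", "protein_g", "fat_g", "fiber_g")}
    # carb-weighted meal glycemic index
    w = sel["carbs_g"].to_numpy() * mult
    gi = float(np.dot(sel["glycemic_index"], w) / w.sum()) if w.sum() > 0 else 0.0
    return MealRecord(
        patient_id=pid, timestamp=stamp, meal_type=meal_type,
        items=[(fid, float(m)) for fid, m in zip(sel["food_id"], mult)],
        calories_kcal=totals["calories_kcal"], carbs_g=carbs,
        protein_g=totals["protein_g"], fat_g=totals["fat_g"],
        fiber_g=totals["fiber_g"], glycemic_index=gi,
        glycemic_load=gi / 100.0 * carbs)


def _meal_slots(meals_per_day: int) -> list[tuple[str, float]]:
    base = [("breakfast", 8.0), ("lunch", 13.0), ("dinner", 19.0)]
    if meals_per_day <= 3:
        return base[:meals_per_day]
    return base + [("snack", 16.5)] * (meals_per_day - 3)


def load_food_table() -> pd.DataFrame:
    from importlib import resources
    with resources.files("glycotwin.data").joinpath("foods.csv").open() as fh:
        return pd.read_csv(fh)


def simulate_study(cohort: list[GroundTruthPatient],
                   config: SimConfig) -> SyntheticDataset:
    """Simulate CGM/meal/activity/sleep streams for a whole cohort.

    Patients enroll staggered (evenly spaced over ``enrollment_span_days``)
    and each wears the sensor for ``days`` days at ``cgm_interval`` minutes.
    Every meal's ground-truth peak (noiseless window maximum), closed-form
    rise and noiseless pre-meal baseline are recorded in ``truth_ppgr``.
    """
    config.validate()
    if not cohort:
        raise InvalidConfigError("cohort must be nonempty")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    foods = load_food_table()
    kernel = config.kernel
    # timestamps are tz-naive UTC by convention
    start = pd.Timestamp(config.start_date)
    step = config.cgm_interval
    n_samples = config.days * 24 * 60 // step

    cgm_parts, meal_rows, act_parts, sleep_rows, prof_rows, truth_rows = \
        [], [], [], [], [], []

    for i, patient in enumerate(cohort):
        if len(cohort) > 1:
            offset_days = round(i * config.enrollment_span_days
                                / (len(cohort) - 1))
        else:
            offset_days = 0
        t0 = start + pd.Timedelta(days=offset_days)
        times = t0 + pd.to_timedelta(np.arange(n_samples) * step, unit="m")
        hours = ((times - t0).total_seconds() / 3600.0
                 + t0.hour) % 24.0
        hours = np.asarray(hours)

        noiseless = (patient.effective_basal
                     + patient.circadian_amplitude
                     * np.cos(2 * np.pi * (hours - patient.circadian_phase_hour)
                              / 24.0))

        # hourly activity stream over the wear period
        n_hours = config.days * 24
        hour_times = t0 + pd.to_timedelta(np.arange(n_hours), unit="h")
        hod = np.asarray([(t0.hour + h) % 24 for h in range(n_hours)])
        awake = (hod >= 7) & (hod < 22)
        steps = np.where(awake, rng.gamma(1.5, 350.0, size=n_hours), 0.0)
        steps = np.round(steps)
        active_min = np.clip(steps / 100.0, 0.0, 60.0)
        sed_min = np.where(awake, 60.0 - active_min, 0.0)

        # nightly sleep, one record per study morning
        n_nights = config.days + 1
        night_dates = (t0.normalize()
                       + pd.to_timedelta(np.arange(n_nights), unit="D"))
        s_min = np.clip(rng.normal(420.0, 45.0, size=n_nights), 300.0, 540.0)
        s_eff = rng.uniform(0.75, 0.97, size=n_nights)
        cum_steps = np.concatenate([[0.0], np.cumsum(steps)])

        for d in range(config.days):
            for meal_type, slot in _meal_slots(config.meals_per_day):
                jitter = rng.integers(-45 // step, 45 // step + 1) * step
                minute_of_day = int(slot * 60) + int(jitter)
                minute_of_day = (minute_of_day // step) * step
                stamp = t0 + pd.Timedelta(days=d, minutes=minute_of_day)
                meal = _sample_meal(rng, foods, patient.patient_id, stamp,
                                    meal_type)
                # context: trailing-hour steps and previous night's sleep
                h_idx = int((stamp - t0).total_seconds() // 3600)
                steps_1h = float(cum_steps[min(h_idx + 1, n_hours)]
                                 - cum_steps[max(h_idx, 0)])
                sleep_h = float(s_min[d] / 60.0)
                ctx = MealContext(steps_prev_1h=steps_1h,
                                  sleep_hours_prev_night=sleep_h)
                rise = closed_form_rise(patient, meal, ctx)
                k0 = int((stamp - t0).total_seconds() // 60) // step
                n_k = int(kernel.support_min // step) + 1
                k1 = min(k0 + n_k, n_samples)
                offs = (np.arange(k0, k1) - k0) * float(step)
                noiseless[k0:k1] += kernel_curve(rise, offs, kernel)
                meal_rows.append({
                    "patient_id": patient.patient_id, "timestamp": stamp,
                    "meal_type": meal_type,
                    "items": ";".join(f"{fid}x{m:.2f}" for fid, m in meal.items),
                    "calories_kcal": meal.calories_kcal,
                    "carbs_g": meal.carbs_g, "protein_g": meal.protein_g,
                    "fat_g": meal.fat_g, "fiber_g": meal.fiber_g,
                    "glycemic_index": meal.glycemic_index,
                    "glycemic_load": meal.glycemic_load,
                })
                truth_rows.append({
                    "patient_id": patient.patient_id, "meal_timestamp": stamp,
                    "truth_rise_mgdl": rise, "_k0": k0, "_i": i,
                })

        noise = (rng.normal(0.0, patient.noise_sd, size=n_samples)
                 if patient.noise_sd > 0 else np.zeros(n_samples))
        glucose = np.clip(noiseless + noise, 39.0, 500.0)

        # ground-truth peak = max of the noiseless trace in the meal window
        w = int(kernel.window_min // step)
        pre = int(30 // step)
        for row in truth_rows:
            if row.get("_i") != i:
                continue
            k0 = row.pop("_k0")
            seg = noiseless[k0 + 1:min(k0 + w + 1, n_samples)]
            j = int(np.argmax(seg))
            row["truth_peak_mgdl"] = float(seg[j])
            row["minutes_to_peak"] = float((j + 1) * step)
            base_seg = noiseless[max(k0 - pre, 0):k0 + 1]
            row["truth_baseline_mgdl"] = float(np.median(base_seg))
            row.pop("_i")

        cgm_parts.append(pd.DataFrame({
            "patient_id": patient.patient_id, "timestamp": times,
            "glucose_mgdl": glucose}))
        act_parts.append(pd.DataFrame({
            "patient_id": patient.patient_id, "timestamp": hour_times,
            "steps": steps, "active_minutes": active_min,
            "sedentary_minutes": sed_min}))
        for d in range(n_nights):
            sleep_rows.append({"patient_id": patient.patient_id,
                               "date": night_dates[d],
                               "sleep_minutes": float(s_min[d]),
                               "sleep_efficiency": float(s_eff[d])})
        prof_rows.append({
            "patient_id": patient.patient_id, "age": patient.age,
            "sex": patient.sex, "bmi": patient.bmi, "hba1c": patient.hba1c,
            "homa": patient.homa, "waist_cm": patient.waist_cm,
            "medications": patient.medications})

    truth = pd.DataFrame(truth_rows)[
        ["patient_id", "meal_timestamp", "truth_peak_mgdl", "truth_rise_mgdl",
         "truth_baseline_mgdl", "minutes_to_peak"]]
    return SyntheticDataset(
        cgm=pd.concat(cgm_parts, ignore_index=True),
        meals=pd.DataFrame(meal_rows),
        activity=pd.concat(act_parts, ignore_index=True),
        sleep=pd.DataFrame(sleep_rows),
        profiles=pd.DataFrame(prof_rows),
        truth_ppgr=truth,
        config=config,
    )


def corrupt_dataset(dataset: SyntheticDataset,
                    config: SimConfig) -> SyntheticDataset:
    """Inject missingness and sensor outliers into the CGM stream.

    CGM samples are removed completely at random at ``missing_rate``;
    surviving samples become large spike outliers at ``outlier_rate``
    (magnitude 80-250 mg/dL, random sign). Injected outliers are flagged in
    the hidden ``is_injected_outlier`` column so cleaning can be scored; the
    column is dropped when the dataset is written to disk.
    """
    config.validate()
    if config.missing_rate == 0 and config.outlier_rate == 0:
        return dataset.copy()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    out = dataset.copy()
    cgm = out.cgm
    keep = rng.random(len(cgm)) >= config.missing_rate
    cgm = cgm[keep].reset_index(drop=True)
    spike = rng.random(len(cgm)) < config.outlier_rate
    mag = rng.uniform(80.0, 250.0, size=len(cgm))
    sign = np.where(rng.random(len(cgm)) < 0.7, 1.0, -1.0)
    glucose = cgm["glucose_mgdl"].to_numpy(float).copy()
    glucose[spike] = np.clip(glucose[spike] + (sign * mag)[spike], 25.0, 590.0)
    cgm["glucose_mgdl"] = glucose
    cgm["is_injected_outlier"] = spike
    out.cgm = cgm
    return out
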