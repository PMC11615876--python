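"""Feature engineering: baselines, glucoseMax, impacts, assembly."""

import numpy as np
import pandas as pd
import pytest

from glycotwin.errors import (InsufficientDataError, InvalidInputError,
                              SchemaError)
from glycotwin.features import (MealRecord, TemporalContext,
                                assemble_features, baseline_glucose,
                                build_feature_table, glucose_max,
                                meal_features, normalized_impact,
                                temporal_context)
from glycotwin.registry import FeatureRegistry


def make_trace(values, start="2024-01-01 07:00", interval=5):
    ts = pd.date_range(start, periods=len(values), freq=f"{interval}min")
    return pd.DataFrame({"patient_id": "P001", "timestamp": ts,
                         "glucose_mgdl": [float(v) for v in values]})


def make_meal(**kw):
    defaults = dict(patient_id="P001",
                    timestamp=pd.Timestamp("2024-01-01 08:00"),
                    meal_type="breakfast", items=[], calories_kcal=400.0,
                    carbs_g=60.0, protein_g=20.0, fat_g=10.0, fiber_g=5.0,
                    glycemic_index=50.0, glycemic_load=30.0)
    defaults.update(kw)
    return MealRecord(**defaults)


MEAL_T = pd.Timestamp("2024-01-01 08:00")


class TestBaselineGlucose:
    def test_constant_premeal_no_meds(self):
        trace = make_trace([90] * 13)
        assert baseline_glucose(trace, MEAL_T, []) == 90.0

    def test_medication_penalty_added(self):
        trace = make_trace([90] * 13)
        out = baseline_glucose(trace, MEAL_T, ["metformin"],
                               penalty_table={"metformin": 8.0})
        assert out == 98.0

    def test_penalty_additive_and_order_independent(self):
        trace = make_trace([90] * 13)
        table = {"metformin": 6.0, "glp1_agonist": 9.0}
        a = baseline_glucose(trace, MEAL_T, ["metformin", "glp1_agonist"], table)
        b = baseline_glucose(trace, MEAL_T, ["glp1_agonist", "metformin"], table)
        assert a == b == 90.0 + 15.0

    def test_empty_window_rejected(self):
        trace = make_trace([90] * 5, start="2024-01-01 12:00")
        with pytest.raises(InsufficientDataError):
            baseline_glucose(trace, MEAL_T, [])


class TestGlucoseMax:
    def test_constant_window(self):
        trace = make_trace([100] * 30)
        peak, offset = glucose_max(trace, MEAL_T, 120)
        assert peak == 100.0
        assert offset == 5.0  # first sample strictly after the meal

    def test_forced_peak_at_45_minutes(self):
        values = [100] * 30
        values[12 + 9] = 180  # 60 min pre-meal, peak at +45
        trace = make_trace(values)
        peak, offset = glucose_max(trace, MEAL_T, 120)
        assert (peak, offset) == (180.0, 45.0)

    def test_tie_broken_by_earliest(self):
        values = [100] * 30
        values[12 + 6] = 150   # +30 min
        values[12 + 12] = 150  # +60 min
        peak, offset = glucose_max(make_trace(values), MEAL_T, 120)
        assert (peak, offset) == (150.0, 30.0)

    def test_empty_window_rejected(self):
        trace = make_trace([100] * 5)  # ends 07:20, before the meal
        with pytest.raises(InsufficientDataError):
            glucose_max(trace, MEAL_T, 120)


class TestNormalizedImpact:
    @pytest.mark.parametrize("peak,base,delta,rel", [
        (160.0, 100.0, 60.0, 0.60),
        (100.0, 100.0, 0.0, 0.0),
        (90.0, 100.0, -10.0, -0.10),
    ])
    def test_delta_and_relative(self, peak, base, delta, rel):
        d, r = normalized_impact(peak, base)
        assert d == pytest.approx(delta)
        assert r == pytest.approx(rel)

    def test_nonpositive_baseline_rejected(self):
        with pytest.raises(InvalidInputError):
            normalized_impact(160.0, 0.0)


class TestMealFeatures:
    def test_carb_to_protein_ratio(self):
        out = meal_features(make_meal(carbs_g=60.0, protein_g=20.0), [])
        assert out["carb_to_protein_ratio"] == pytest.approx(3.0)

    def test_first_meal_capped_and_flagged(self):
        out = meal_features(make_meal(), [])
        assert out["time_since_last_meal_min"] == 960.0
        assert out["first_meal_on_record"]

    def test_glycemic_load_recomputed(self):
        # GL = GI/100 x carbs, the standard definition as reconciliation oracle
        out = meal_features(make_meal(carbs_g=40.0, glycemic_index=50.0,
                                      glycemic_load=20.0), [])
        assert out["glycemic_load"] == pytest.approx(20.0)
        assert not out["glycemic_load_reconciled"]

    def test_meal_spacing_from_history(self):
        prev = [MEAL_T - pd.Timedelta(hours=5)]
        out = meal_features(make_meal(), prev)
        assert out["time_since_last_meal_min"] == pytest.approx(300.0)


class TestTemporalContext:
    def _streams(self):
        activity = pd.DataFrame({
            "patient_id": "P001",
            "timestamp": pd.date_range("2024-01-01", periods=9, freq="h"),
            "steps": [0, 0, 0, 0, 0, 0, 500, 800, 0],
            "active_minutes": [0] * 6 + [5, 8, 0],
            "sedentary_minutes": [0] * 6 + [55, 52, 0]})
        sleep = pd.DataFrame({"patient_id": "P001",
                              "date": [pd.Timestamp("2024-01-01")],
                              "sleep_minutes": [400.0],
                              "sleep_efficiency": [0.9]})
        return activity, sleep

    def test_exact_line_slope(self):
        trace = make_trace([100, 110, 120], start="2024-01-01 07:50")
        activity, sleep = self._streams()
        ctx = temporal_context(trace, activity, sleep, MEAL_T)
        assert ctx.premeal_slope_mgdl_min == pytest.approx(2.0)
        assert ctx.sleep_minutes_prev_night == 400.0
        # the 07:00 hourly bucket is the trailing hour before an 08:00 meal
        assert ctx.steps_prev_1h == pytest.approx(800.0)
        assert ctx.steps_prev_24h == pytest.approx(1300.0)

    def test_constant_trailing_glucose(self):
        trace = make_trace([100] * 13)
        activity, sleep = self._streams()
        ctx = temporal_context(trace, activity, sleep, MEAL_T)
        assert ctx.premeal_slope_mgdl_min == pytest.approx(0.0, abs=1e-9)
        assert ctx.trail1h_sd_mgdl == 0.0

    def test_single_sample_rejected(self):
        trace = make_trace([100], start="2024-01-01 07:55")
        activity, sleep = self._streams()
        with pytest.raises(InsufficientDataError):
            temporal_context(trace, activity, sleep, MEAL_T)


class TestAssembleFeatures:
    PROFILE = {"age": 55, "sex": "M", "bmi": 29.0, "hba1c": 7.2,
               "homa": 3.1, "waist_cm": 98.0,
               "medications": [{"name": "metformin", "dose_mg": 1000}]}

    def _context(self):
        return TemporalContext(2.0, 105, 4, 110, 8, 112, 10, 500, 6000,
                               60, 840, 400, 0.9)

    def test_vector_matches_registry_length_and_order(self, registry):
        vec = assemble_features(self.PROFILE, make_meal(), self._context(),
                                96.0, registry)
        assert vec.shape == (37,)
        assert vec[list(registry.names).index("hba1c_pct")] == 7.2

    def test_pure_function(self, registry):
        args = (self.PROFILE, make_meal(), self._context(), 96.0, registry)
        assert np.array_equal(assemble_features(*args),
                              assemble_features(*args))

    def test_unknown_registry_rejected(self):
        alien = FeatureRegistry(version=9, features=(
            {"name": "age_years"}, {"name": "not_a_real_feature"}))
        with pytest.raises(SchemaError, match="not_a_real_feature"):
            assemble_features(self.PROFILE, make_meal(), self._context(),
                              96.0, alien)


class TestBuildFeatureTable:
    def test_row_count_and_no_missing(self, small_features, registry):
        assert len(small_features) > 0
        assert not small_features[list(registry.names)].isna().any().any()

    def test_meal_in_cgm_gap_excluded_with_reason(self, small_dataset,
                                                  registry):
        ds = small_dataset.copy()
        meal0 = ds.meals.iloc[0]
        lo = meal0["timestamp"] - pd.Timedelta(minutes=40)
        mask = ~((ds.cgm["patient_id"] == meal0["patient_id"])
                 & (ds.cgm["timestamp"] >= lo)
                 & (ds.cgm["timestamp"] <= meal0["timestamp"]))
        ds.cgm = ds.cgm[mask].reset_index(drop=True)
        _, excl = build_feature_table(ds, registry)
        hit = excl[(excl["patient_id"] == meal0["patient_id"])
                   & (excl["meal_timestamp"] == meal0["timestamp"])]
        assert len(hit) == 1
        assert "no baseline" in hit.iloc[0]["reason"]

    def test_bulk_rows_match_op_by_op_assembly(self, small_dataset, registry,
                                               small_features):
        """Fast path agrees with the per-operation functions."""
        row = small_features.iloc[10]
        pid, stamp = row["patient_id"], row["meal_timestamp"]
        trace = small_dataset.cgm[small_dataset.cgm["patient_id"] == pid]
        profile = small_dataset.profiles.set_index("patient_id").loc[pid].to_dict()
        base = baseline_glucose(trace, stamp, profile["medications"] or [])
        peak, _ = glucose_max(trace, stamp, 120)
        assert base == pytest.approx(row["adjusted_baseline_mgdl"])
        assert peak == pytest.approx(row["observed_peak_mgdl"])
        activity = small_dataset.activity[
            small_dataset.activity["patient_id"] == pid]
        sleep = small_dataset.sleep[small_dataset.sleep["patient_id"] == pid]
        ctx = temporal_context(trace, activity, sleep, stamp)
        assert ctx.premeal_slope_mgdl_min == pytest.approx(
            row["premeal_slope_mgdl_min"])
        assert ctx.trail6h_mean_mgdl == pytest.approx(row["trail6h_mean_mgdl"])
        assert ctx.steps_prev_1h == pytest.approx(row["steps_prev_1h"])
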