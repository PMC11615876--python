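"""Multi-objective food scoring, argmin ranking, GFY/OFY/RFY rules."""

import logging

import numpy as np
import pandas as pd
import pytest

from glycotwin.errors import (EmptyCandidatesError, InvalidConfigError,
                              InvalidNRTError, UndefinedProportionsError)
from glycotwin.recommend import (FoodItem, NRTPolicy, NutritionRulesTable,
                                 PreferenceProfile, RecommendationConfig,
                                 VARIABILITY_SCALE_MGDL, adjust_nrt,
                                 classify_foods, initial_nrt,
                                 nutrient_variability, objective_score,
                                 predict_food_impacts, preference_penalty,
                                 recommend)
from glycotwin.synthetic import MealContext, closed_form_rise, load_food_table


def food(food_id="F1", carbs=12.5, protein=5.0, fat=10.0 / 3, fiber=1.0,
         gi=50.0, tags=()):
    kcal = carbs * 4 + protein * 4 + fat * 9
    return FoodItem(food_id=food_id, name=food_id, calories_kcal=kcal,
                    carbs_g=carbs, protein_g=protein, fat_g=fat,
                    fiber_g=fiber, glycemic_index=gi, tags=tuple(tags))


class TestNutrientVariability:
    def test_zero_when_proportions_match(self):
        # calorie shares: 50/20/30
        f = food(carbs=12.5, protein=5.0, fat=30.0 / 9)
        assert nutrient_variability(f, (0.5, 0.2, 0.3)) == pytest.approx(0.0)

    def test_hand_euclidean_example(self):
        # candidate shares (0.5, 0.2, 0.3) vs targets (0.5, 0.3, 0.2)
        f = food(carbs=12.5, protein=5.0, fat=30.0 / 9)
        d = nutrient_variability(f, (0.5, 0.3, 0.2))
        assert d == pytest.approx(np.sqrt(0.02), rel=1e-6)

    def test_zero_calorie_rejected(self):
        f = FoodItem("F0", "water", 0.0, 0.0, 0.0, 0.0, 0.0, 0.0)
        with pytest.raises(UndefinedProportionsError):
            nutrient_variability(f)


class TestPreferencePenalty:
    def test_allergen_hard_excluded(self):
        f = food(tags=("contains_nut",))
        prof = PreferenceProfile(hard_exclusions=("contains_nut",))
        assert preference_penalty(f, prof) is None

    def test_no_restrictions_zero(self):
        assert preference_penalty(food(), PreferenceProfile()) == 0.0

    def test_dislike_weight_added(self):
        prof = PreferenceProfile(soft_dislikes={"F1": 3.0})
        assert preference_penalty(food("F1"), prof) == 3.0


class TestObjectiveScore:
    def test_zero_lambdas_reduce_to_ppgr(self):
        cfg = RecommendationConfig(lambda1=0.0, lambda2=0.0)
        assert objective_score(food(), 42.0, cfg, PreferenceProfile()) == 42.0

    def test_variability_term_scales_linearly(self):
        prof = PreferenceProfile(macro_targets=(0.5, 0.3, 0.2))
        f = food(carbs=12.5, protein=5.0, fat=30.0 / 9)
        s0 = objective_score(f, 30.0, RecommendationConfig(lambda1=0.0,
                                                           lambda2=0.0), prof)
        s2 = objective_score(f, 30.0, RecommendationConfig(lambda1=2.0,
                                                           lambda2=0.0), prof)
        expected = 2.0 * np.sqrt(0.02) * VARIABILITY_SCALE_MGDL
        assert s2 - s0 == pytest.approx(expected)

    def test_negative_lambda_rejected(self):
        with pytest.raises(InvalidConfigError):
            RecommendationConfig(lambda1=-1.0).validate()


class TestRecommend:
    FOODS = [food("A"), food("B"), food("C")]
    IMPACTS = {"A": 30.0, "B": 20.0, "C": 40.0}

    def _cfg(self):
        return RecommendationConfig(lambda1=0.0, lambda2=0.0, top_k=3)

    def test_argmin_first(self):
        out = recommend(self.FOODS, self.IMPACTS, self._cfg())
        assert out.iloc[0]["food_id"] == "B"

    def test_hard_exclusion_changes_winner(self):
        prof = PreferenceProfile(hard_exclusions=("B",))
        out = recommend(self.FOODS, self.IMPACTS, self._cfg(), prof)
        assert out.iloc[0]["food_id"] == "A"

    def test_all_excluded_rejected(self):
        prof = PreferenceProfile(hard_exclusions=("A", "B", "C"))
        with pytest.raises(EmptyCandidatesError):
            recommend(self.FOODS, self.IMPACTS, self._cfg(), prof)

    def test_zero_lambdas_rank_by_predicted_ppgr(self):
        rng = np.random.default_rng(3)
        foods = [food(f"F{i}", carbs=rng.uniform(5, 60),
                      protein=rng.uniform(1, 30), fat=rng.uniform(1, 20))
                 for i in range(30)]
        impacts = {f.food_id: float(rng.uniform(5, 90)) for f in foods}
        out = recommend(foods, impacts,
                        RecommendationConfig(lambda1=0, lambda2=0, top_k=30))
        assert list(out["predicted_ppgr_mgdl"]) == sorted(impacts.values())

    def test_matches_brute_force_enumeration(self):
        """Ranking equals exhaustive scoring of every surviving candidate."""
        rng = np.random.default_rng(4)
        foods = [food(f"F{i:03d}", carbs=rng.uniform(5, 60),
                      protein=rng.uniform(1, 30), fat=rng.uniform(1, 25),
                      tags=("dislike",) if rng.random() < 0.3 else ())
                 for i in range(50)]
        impacts = {f.food_id: float(rng.uniform(0, 100)) for f in foods}
        cfg = RecommendationConfig(lambda1=float(rng.uniform(0, 2)),
                                   lambda2=float(rng.uniform(0, 2)),
                                   top_k=50)
        prof = PreferenceProfile(soft_dislikes={"dislike": 2.0})
        out = recommend(foods, impacts, cfg, prof)
        # independent oracle: score every candidate, sort by the tie-break keys
        scored = [(objective_score(f, impacts[f.food_id], cfg, prof),
                   impacts[f.food_id], f.food_id) for f in foods]
        oracle = [fid for _, _, fid in sorted(scored)]
        assert list(out["food_id"]) == oracle


class TestClassifyFoods:
    NRT = NutritionRulesTable(30.0, 60.0)

    def test_boundary_labels(self):
        labels = classify_foods({"a": 10.0, "b": 40.0, "c": 90.0}, self.NRT)
        assert labels == ["GFY", "OFY", "RFY"]

    def test_equal_impacts_same_label(self):
        labels = classify_foods({"a": 35.0, "b": 35.0, "c": 35.0}, self.NRT)
        assert set(labels) == {"OFY"}

    def test_partition_every_food_exactly_one_label(self):
        rng = np.random.default_rng(5)
        impacts = {f"f{i}": float(rng.uniform(-10, 120)) for i in range(200)}
        labels = classify_foods(impacts, self.NRT)
        assert len(labels) == 200
        assert set(labels) <= {"GFY", "OFY", "RFY"}

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(InvalidNRTError):
            classify_foods({"a": 1.0}, NutritionRulesTable(60.0, 30.0))


class TestAdjustNRT:
    def test_hand_tertiles(self):
        nrt = adjust_nrt(NutritionRulesTable(30.0, 60.0),
                         [10, 20, 30, 40, 50, 60],
                         NRTPolicy(min_observations=6))
        assert nrt.t_green == pytest.approx(26.6667, rel=1e-4)
        assert nrt.t_orange == pytest.approx(43.3333, rel=1e-4)
        assert nrt.version == 2
        assert nrt.provenance == "feedback-adjusted"

    def test_small_impacts_shrink_thresholds(self):
        nrt0 = NutritionRulesTable(30.0, 60.0)
        nrt = adjust_nrt(nrt0, np.linspace(2, 12, 30))
        assert nrt.t_green < nrt0.t_green
        assert nrt.t_orange < nrt0.t_orange
        # the adapted table still separates tiny impacts into green
        assert classify_foods({"tiny": 4.0}, nrt) == ["GFY"]

    def test_too_few_observations_noop_with_warning(self, caplog):
        nrt0 = NutritionRulesTable(30.0, 60.0)
        with caplog.at_level(logging.WARNING):
            nrt = adjust_nrt(nrt0, [5.0] * 4)
        assert nrt == nrt0
        assert any("skipped" in r.message for r in caplog.records)


class TestEndToEndDiet:
    def test_gfy_only_diet_lowers_mean_peak(self, small_model, small_features,
                                            small_cohort):
        """Eating only GFY-labelled foods beats eating uniformly at random."""
        foods_df = load_food_table()
        rng = np.random.default_rng(99)
        gfy_means, rnd_means = [], []
        for patient in small_cohort[:5]:
            rows = small_features[
                small_features["patient_id"] == patient.patient_id]
            context = rows.sort_values("meal_timestamp").iloc[-1]
            impacts = predict_food_impacts(small_model, context, foods_df)
            nrt = initial_nrt(impacts)
            gfy_ids = [fid for fid, imp in impacts.items()
                       if imp <= nrt.t_green]
            assert gfy_ids

            def truth_peak(fid):
                f = foods_df.set_index("food_id").loc[fid]
                from glycotwin.features import MealRecord
                meal = MealRecord(
                    patient_id=patient.patient_id,
                    timestamp=pd.Timestamp("2024-06-01 08:00"),
                    meal_type="lunch", items=[(fid, 1.0)],
                    calories_kcal=float(f["calories_kcal"]),
                    carbs_g=float(f["carbs_g"]),
                    protein_g=float(f["protein_g"]),
                    fat_g=float(f["fat_g"]), fiber_g=float(f["fiber_g"]),
                    glycemic_index=float(f["glycemic_index"]),
                    glycemic_load=float(f["glycemic_index"]) / 100
                    * float(f["carbs_g"]))
                rise = closed_form_rise(patient, meal, MealContext())
                return patient.effective_basal + rise

            all_ids = list(foods_df["food_id"])
            gfy_choice = rng.choice(gfy_ids, size=90)      # 30 days x 3 meals
            rnd_choice = rng.choice(all_ids, size=90)
            gfy_means.append(np.mean([truth_peak(f) for f in gfy_choice]))
            rnd_means.append(np.mean([truth_peak(f) for f in rnd_choice]))
        assert np.mean(gfy_means) < np.mean(rnd_means)
        assert all(g < r for g, r in zip(gfy_means, rnd_means))
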