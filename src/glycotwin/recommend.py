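"""Dietary recommendation engine.

Candidate foods are scored by a multi-objective function

    score = predicted PPGR + lambda1 * nutrient variability
                           + lambda2 * preference penalty

and the recommendation is the argmin over candidates (top-k returned in
ascending score). Nutrient variability is the Euclidean distance between
the candidate's calorie-share macronutrient proportions and the patient's
target proportions, scaled to mg/dL-comparable magnitude; hard dietary
restrictions remove foods before scoring, soft dislikes add their weight.
Each food is classified Green/Orange/Red "For You" by the patient's
Nutrition Rules Table thresholds on predicted impact, which adapt to the
patient's trailing response distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (EmptyCandidatesError, InvalidConfigError,
                     InvalidInputError, InvalidNRTError,
                     UndefinedProportionsError)

log = logging.getLogger(__name__)

# Atwater calorie factors (kcal per g) for calorie-share macro proportions.
KCAL_PER_G = {"carbs": 4.0, "protein": 4.0, "fat": 9.0}

# Distance-to-score scaling: one unit of macro-proportion distance (the
# maximum possible is sqrt(2)) is treated as comparable to this many mg/dL
# of predicted response, so that lambda1 ~ 1 is a meaningful default.
VARIABILITY_SCALE_MGDL = 50.0
PREFERENCE_SCALE_MGDL = 10.0


@dataclass
class FoodItem:
    food_id: str
    name: str
    calories_kcal: float
    carbs_g: float
    protein_g: float
    fat_g: float
    fiber_g: float
    glycemic_index: float
    tags: tuple = ()

    def validate(self) -> "FoodItem":
        if min(self.calories_kcal, self.carbs_g, self.protein_g,
               self.fat_g, self.fiber_g) < 0:
            raise InvalidInputError(f"{self.food_id}: negative nutrients")
        return self

    @classmethod
    def from_row(cls, row) -> "FoodItem":
        tags = row.get("tags", "")
        tags = tuple(t for t in str(tags).split(";")
                     if t and t != "none" and t != "nan")
        return cls(food_id=row["food_id"], name=row["name"],
                   calories_kcal=float(row["calories_kcal"]),
                   carbs_g=float(row["carbs_g"]),
                   protein_g=float(row["protein_g"]),
                   fat_g=float(row["fat_g"]), fiber_g=float(row["fiber_g"]),
                   glycemic_index=float(row["glycemic_index"]),
                   tags=tags).validate()


@dataclass
class PreferenceProfile:
    """Hard exclusions are absolute; soft dislikes are weighted penalties."""

    hard_exclusions: tuple = ()      # tags or food_ids; removed before scoring
    soft_dislikes: dict = field(default_factory=dict)  # tag/food_id -> weight
    macro_targets: tuple = (0.5, 0.25, 0.25)  # calorie shares carbs/protein/fat

    def __post_init__(self):
        if any(w < 0 for w in self.soft_dislikes.values()):
            raise InvalidConfigError("soft dislike weights must be >= 0")


@dataclass(frozen=True)
class RecommendationConfig:
    lambda1: float = 1.0
    lambda2: float = 1.0
    top_k: int = 10

    def validate(self) -> "RecommendationConfig":
        if self.lambda1 < 0 or self.lambda2 < 0:
            raise InvalidConfigError("lambda weights must be >= 0")
        if self.top_k < 1:
            raise InvalidConfigError("top_k must be >= 1")
        return self


@dataclass
class NutritionRulesTable:
    """Per-patient impact thresholds mapping predicted impact to GFY/OFY/RFY."""

    t_green: float
    t_orange: float
    version: int = 1
    provenance: str = "initial"

    def validate(self) -> "NutritionRulesTable":
        if not (self.t_green < self.t_orange):
            raise InvalidNRTError(
                f"NRT thresholds must satisfy t_green < t_orange "
                f"(got {self.t_green} >= {self.t_orange})")
        return self


def nutrient_variability(food: FoodItem,
                         targets: tuple = (0.5, 0.25, 0.25)) -> float:
    """Euclidean distance between calorie-share macros and target shares.

    Zero iff the candidate's carb/protein/fat calorie proportions equal the
    targets; undefined for zero-calorie candidates.
    """
    kcal = (food.carbs_g * KCAL_PER_G["carbs"]
            + food.protein_g * KCAL_PER_G["protein"]
            + food.fat_g * KCAL_PER_G["fat"])
    if kcal <= 0:
        raise UndefinedProportionsError(
            f"{food.food_id}: macro proportions undefined at zero calories")
    shares = np.array([food.carbs_g * 4.0, food.protein_g * 4.0,
                       food.fat_g * 9.0]) / kcal
    return float(np.linalg.norm(shares - np.asarray(targets, dtype=float)))


def preference_penalty(food: FoodItem, profile: PreferenceProfile) -> float | None:
    """Soft-dislike penalty, or None when the food is hard-excluded."""
    keys = set(food.tags) | {food.food_id}
    if any(h in keys for h in profile.hard_exclusions):
        return None
    return float(sum(w for k, w in profile.soft_dislikes.items() if k in keys))


def objective_score(food: FoodItem, predicted_ppgr: float,
                    config: RecommendationConfig,
                    profile: PreferenceProfile) -> float:
    """predicted PPGR + lambda1*variability + lambda2*preference, in mg/dL."""
    config.validate()
    penalty = preference_penalty(food, profile)
    if penalty is None:
        raise InvalidInputError(
            f"{food.food_id} is hard-excluded; filter before scoring")
    var = nutrient_variability(food, profile.macro_targets)
    return (predicted_ppgr
            + config.lambda1 * var * VARIABILITY_SCALE_MGDL
            + config.lambda2 * penalty * PREFERENCE_SCALE_MGDL)


def recommend(candidates: list[FoodItem], predicted_impacts: dict,
              config: RecommendationConfig | None = None,
              profile: PreferenceProfile | None = None,
              nrt: NutritionRulesTable | None = None) -> pd.DataFrame:
    """Rank candidate foods by the multi-objective score (argmin first).

    ``predicted_impacts`` maps food_id to the model's predicted PPGR (mg/dL
    delta). Hard-excluded foods are removed before scoring; ties break by
    lower predicted PPGR, then lexical food_id. The ranking provably equals
    exhaustive enumeration of the objective (the test suite checks this
    against a brute-force oracle).
    """
    config = (config or RecommendationConfig()).validate()
    profile = profile or PreferenceProfile()
    rows = []
    for food in candidates:
        penalty = preference_penalty(food, profile)
        if penalty is None:
            continue
        ppgr = float(predicted_impacts[food.food_id])
        score = objective_score(food, ppgr, config, profile)
        rows.append({"food_id": food.food_id, "name": food.name,
                     "predicted_ppgr_mgdl": ppgr, "score": score})
    if not rows:
        raise EmptyCandidatesError("no candidates survive hard exclusions")
    out = pd.DataFrame(rows).sort_values(
        ["score", "predicted_ppgr_mgdl", "food_id"]).reset_index(drop=True)
    if nrt is not None:
        out["label"] = classify_foods(
            dict(zip(out["food_id"], out["predicted_ppgr_mgdl"])), nrt)
    return out.head(config.top_k)


def classify_foods(predicted_impacts: dict,
                   nrt: NutritionRulesTable) -> list[str]:
    """GFY/OFY/RFY labels: impact <= t_green -> GFY, <= t_orange -> OFY, else RFY.

    Every food gets exactly one label and labels are monotone in impact.
    """
    nrt.validate()
    labels = []
    for impact in predicted_impacts.values():
        if impact <= nrt.t_green:
            labels.append("GFY")
        elif impact <= nrt.t_orange:
            labels.append("OFY")
        else:
            labels.append("RFY")
    return labels


MEAL_NUTRIENT_COLUMNS = ("calories_kcal", "carbs_g", "protein_g", "fat_g",
                         "fiber_g", "glycemic_index")


def predict_food_impacts(model, context_row: pd.Series,
                         foods: pd.DataFrame) -> dict:
    """Predicted PPGR (mg/dL delta) per candidate food for one patient.

    ``context_row`` is a feature-table row for the patient (their current
    temporal context, profile and baseline); each candidate food's nutrients
    are substituted for the meal columns and the model predicts the impact
    of eating one portion of that food now.
    """
    rows = []
    for _, f in foods.iterrows():
        r = context_row.copy()
        for c in MEAL_NUTRIENT_COLUMNS:
            r[c] = float(f[c])
        r["glycemic_load"] = float(f["glycemic_index"]) / 100.0 * float(f["carbs_g"])
        r["carb_to_protein_ratio"] = float(f["carbs_g"]) / max(float(f["protein_g"]), 1.0)
        rows.append(r)
    frame = pd.DataFrame(rows).reset_index(drop=True)
    preds = np.asarray(model.predict_frame(frame), dtype=float)
    if model.target == "peak":
        preds = preds - frame["premeal_baseline_mgdl"].to_numpy(float)
    return dict(zip(foods["food_id"], preds))


@dataclass(frozen=True)
class NRTPolicy:
    """Empirical-tertile adaptation of the NRT to trailing responses."""

    min_observations: int = 10
    quantiles: tuple = (1 / 3, 2 / 3)


def initial_nrt(predicted_impacts: dict) -> NutritionRulesTable:
    """Population-tertile initial thresholds over a food table's impacts."""
    vals = np.asarray(list(predicted_impacts.values()), dtype=float)
    lo, hi = np.quantile(vals, [1 / 3, 2 / 3])
    if not lo < hi:
        hi = lo + 1e-6
    return NutritionRulesTable(float(lo), float(hi), version=1,
                               provenance="initial")


def adjust_nrt(nrt: NutritionRulesTable, observed_impacts,
               policy: NRTPolicy | None = None) -> NutritionRulesTable:
    """Re-estimate thresholds from the patient's trailing impact distribution.

    Thresholds become the empirical tertiles (linear-interpolation quantile
    convention) of the observed impacts; with fewer than the policy minimum
    of observations the table is returned unchanged with a logged warning.
    """
    policy = policy or NRTPolicy()
    nrt.validate()
    vals = np.asarray(list(observed_impacts), dtype=float)
    if len(vals) < policy.min_observations:
        log.warning("NRT adjustment skipped: %d observations < minimum %d",
                    len(vals), policy.min_observations)
        return nrt
    lo, hi = np.quantile(vals, policy.quantiles, method="linear")
    if not lo < hi:
        hi = lo + 1e-6
    return NutritionRulesTable(float(lo), float(hi), version=nrt.version + 1,
                               provenance="feedback-adjusted")
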