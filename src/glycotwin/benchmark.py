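"""The desk benchmark: a fully synthetic, fully specified evaluation run.

One benchmark seed = simulate a 60-patient, 30-day, 3-meals/day cohort at
the generator defaults (sensor noise 12 mg/dL; a 7 mg/dL low-noise variant
exists for the squared-error check), build the 37-feature table, train the
Glucose Impact predictor with temporal-gap 5-fold nested CV at the capped
grid, and score the pooled outer-fold predictions. Repeated over five seeds,
a metric is summarized by the value attained in at least four of the five
(the second-worst seed).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .evaluate import (SpikeDefinition, regression_metrics, spike_auc,
                       within_tolerance)
from .features import build_feature_table
from .model import ModelConfig, make_folds, train
from .synthetic import SimConfig, generate_cohort, simulate_study

DESK_SEEDS = (1, 2, 3, 4, 5)


def desk_config(seed: int, noise_sd: float = 12.0) -> SimConfig:
    return SimConfig(n_patients=60, days=30, meals_per_day=3, seed=seed,
                     noise_sd=noise_sd)


def run_benchmark_seed(seed: int, noise_sd: float = 12.0,
                       model_config: ModelConfig | None = None,
                       spike_def: SpikeDefinition | None = None) -> dict:
    """One full simulate->featurize->train->score pass; returns pooled metrics."""
    spike_def = spike_def or SpikeDefinition()
    sim = desk_config(seed, noise_sd)
    cohort = generate_cohort(sim)
    dataset = simulate_study(cohort, sim)
    features, _ = build_feature_table(dataset)
    folds = make_folds(features["meal_timestamp"], k=5, gap_days=14)
    cfg = model_config or ModelConfig(seed=seed)
    model = train(features, config=cfg, folds=folds)

    preds = model.outer_predictions
    y = preds["observed_peak_mgdl"].to_numpy(float)
    yhat = preds["predicted_peak_mgdl"].to_numpy(float)
    d = preds["observed_delta_mgdl"].to_numpy(float)
    dhat = preds["predicted_delta_mgdl"].to_numpy(float)
    m = regression_metrics(y, yhat)
    return {
        "seed": seed, "noise_sd": noise_sd, "n": int(len(y)),
        "rmse": m.rmse, "mae": m.mae, "mse": m.mse, "r2": m.r2,
        "auc": spike_auc(d, dhat, spike_def),
        "within40_pct": within_tolerance(y, yhat, 40.0) * 100.0,
    }


def run_desk_benchmark(seeds=DESK_SEEDS, noise_sd: float = 12.0,
                       model_config: ModelConfig | None = None) -> pd.DataFrame:
    rows = [run_benchmark_seed(s, noise_sd, model_config) for s in seeds]
    return pd.DataFrame(rows)


def majority_value(values, higher_is_better: bool) -> float:
    """The value attained in >= 4 of 5 seeds (the second-worst seed).

    For error metrics (lower is better) this is the second-largest value;
    for R²/AUC-style metrics the second-smallest.
    """
    v = np.sort(np.asarray(list(values), dtype=float))
    if len(v) == 1:
        return float(v[0])
    return float(v[1]) if higher_is_better else float(v[-2])
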