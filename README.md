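# glycotwin

A desk-scale, fully testable implementation of a digital-twin pipeline for
**postprandial glycemic response (PPGR) prediction and personalized diet
recommendation** in type 2 diabetes.

People with T2D show large individual differences in how much the same meal
raises their glucose. A digital-twin platform predicts each patient's
post-meal glucose peak ("glucoseMax") from continuous glucose monitoring
(CGM), meal logs, wearable activity/sleep data and clinical labs, then uses
those predictions to rank foods and steer the diet toward low-impact
choices. glycotwin rebuilds that loop end to end on synthetic cohorts with
known ground truth, so every stage — cleaning, imputation, feature
engineering, model training, evaluation, recommendation — is verifiable
against closed-form oracles.

## The model

For each logged meal the pipeline extracts

- **glucoseMax**: the maximum glucose in the post-meal window
  `(t_meal, t_meal + 120 min]`,
- an **adjusted baseline**: the median glucose over the 30 min before the
  meal plus a per-drug penalty that compensates for pharmacologically
  depressed baselines,
- the **impact** `Δ = glucoseMax − baseline` (and the relative form
  `Δ/baseline`).

A gradient-boosted tree ensemble (LightGBM; random forest available) maps a
37-variable feature registry — demographics, HbA1c/HOMA, meal nutrients
(carbs, protein, fat, fiber, glycemic index/load, carb-to-protein ratio,
meal spacing), trailing glucose trend/mean/SD, steps, sleep, medication
burden, time of day — to the impact. A random forest's combiner is the tree
average `ŷ = (1/T) Σ_t h_t(x)`; the hybrid static+temporal form
`PPGR(t) = f(Σ_i w_i·φ(h_t, x_i))` is realized by concatenating the
temporal-context features `h_t` with static features `x_i`.

Validation uses **temporal-gap 5-fold cross-validation**: contiguous
validation blocks in time, every training row ≥ 14 days from every
validation row, hyperparameters chosen by nested (inner chronological) CV,
early stopping on the last tenth of the training period. All reported
metrics (MSE, RMSE, MAE, R², spike AUC, fraction within 40 mg/dL) come from
pooled outer-fold predictions only.

Recommendations minimize the multi-objective score

    score(food) = PPGR_predicted + λ1·NutrientVariability + λ2·PreferencePenalty

over candidate foods (hard dietary exclusions are filtered before scoring),
and each food is labelled **GFY / OFY / RFY** (Green/Orange/Red "For You")
by per-patient Nutrition Rules Table thresholds that adapt to the patient's
trailing response distribution.

## Worked example

```bash
glycotwin demo --out run/ --seed 5 --n-patients 8 --days 21
```

simulates an 8-patient, 21-day cohort (staggered enrollment, 5-min CGM,
12 mg/dL sensor noise, 1% missingness, 0.2% sensor spikes), cleans it,
builds features, trains with temporal-gap CV and writes
`run/validation_report.json`:

```
{'mse': 409.96, 'rmse': 20.25, 'mae': 15.54, 'r2': 0.753,
 'within_tolerance_pct': 94.64, 'auc': 0.947}   # n = 504 outer-fold meals
```

i.e. held-out peak predictions are on average 15.5 mg/dL off, 94.6% land
within 40 mg/dL of the observed peak, and predicted impacts separate
spike meals (rise > 40 mg/dL) from non-spikes with AUC 0.95. At this tiny
cohort size R² is limited by the per-meal noise floor; the 60-patient
benchmark below reaches R² ≈ 0.94. `run/recommendations.json` holds the
ranked food list for one patient:

```
sprouts salad (1 bowl)      predicted PPGR 25.3 mg/dL  score 35.3  GFY
chickpea curry (1 cup)      predicted PPGR 27.8 mg/dL  score 37.5  GFY
dal lentils (1 cup cooked)  predicted PPGR 24.4 mg/dL  score 38.5  GFY
...
```

The same stages are available individually
(`glycotwin simulate | clean | featurize | train | evaluate | recommend`)
and as library functions.

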