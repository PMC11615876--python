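# Methods

This note documents the models, conventions and design choices behind
glycotwin, in the spirit of a package's statistical reference manual. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## 1. The synthetic cohort and its ground-truth mechanism

Real CGM/meal datasets of this kind are proprietary, so the package ships a
generator whose ground truth is available in closed form; every downstream
stage is validated against it.

**Patient parameters.** Each virtual patient draws:

| parameter | distribution | units / notes |
|---|---|---|
| basal glucose | Normal(110, 15) truncated to [80, 180] | mg/dL, pre-medication |
| HbA1c | Normal(7.5, 1.2) clipped to [5.8, 11.5] | % |
| HOMA | logNormal(ln 3.5, 0.4) clipped to [1, 12] | — |
| BMI | Normal(28.5, 4) clipped to [19, 42] | kg/m² |
| carb sensitivity `cs` | 0.35 + 0.22·HbA1c + Normal(0, 0.05), clipped to [0.3, 4] | mg/dL per g carb at GI 100 |
| fiber damping | Uniform(0.8, 1.2) | mg/dL per g fiber |
| protein/fat damping | Uniform(0.25, 0.35) | mg/dL per g |
| activity damping | Uniform(0.02, 0.05) | fraction of the carb term per 1000 steps/h |
| sleep penalty | Uniform(2, 5) | mg/dL per hour of sleep deficit below 7 h |
| circadian | amplitude Uniform(4, 12), phase Uniform(5, 9) | cosine, mg/dL / peak hour |
| medications | 0–3 agents (P = .15/.35/.35/.15) from {metformin, sulfonylurea, SGLT2, GLP-1} | each depresses basal by its penalty-table value |
| sensor noise | configured, default 12 | mg/dL, iid Gaussian per sample |

Carb sensitivity is deliberately a function of an observable lab (HbA1c)
plus a small idiosyncratic term: the premise of the digital-twin approach is
that individual responsiveness is predictable from observable features, and
the generator's explainable variance is what makes the benchmark's R²
target meaningful. Mean sensitivity is ≈ 2.0 mg/dL per gram of carbohydrate
at GI 100, a plausible magnitude for medicated T2D.

**Meal kernel.** A meal raises glucose by a piecewise-linear rise over 45
minutes followed by exponential decay (τ = 35 min), clamped to zero at
window end + τ (155 min), so that curves provably return to baseline and
the noiseless peak equals the closed-form rise exactly:

```
rise = cs·carbs·GI/100·(1 − activity_damping·ksteps_prev_hour)
       − fiber_damping·fiber − pf_damping·(protein+fat)
       + sleep_penalty·max(0, 7h − sleep),          floored at 0
```

The kernel is monotone in carbohydrates by construction. The sharp (single
grid sample) peak makes the observed window-maximum behave like truth +
one noise draw, which the test suite checks against the folded-normal mean
√(2/π)·σ. The rise/decay shape is a modelling convenience — it is *not* a
physiological insulin–glucose ODE (explicitly out of scope) — chosen so
every oracle is closed-form.

**Meals, activity, sleep.** Three meals/day (8:00, 13:00, 19:00 ± 45 min,
snapped to the CGM grid) composed of 2–3 items from a bundled 44-item food
table (macros + GI; carb-weighted meal GI), portion multipliers
Uniform(0.7, 1.6). Hourly steps are Gamma(1.5, 350) during waking hours;
nightly sleep Normal(420, 45) min clipped to [300, 540] with efficiency
Uniform(0.75, 0.97).

**Staggered enrollment.** Patients enroll evenly over a configurable span
(default 60 days) and each wears the sensor for the study duration. This is
how real cohorts accrue, and it is what makes 5-fold cross-validation with
a 14-day train/validation gap feasible on a 30-day wear: without staggering,
the middle folds of a 30-day study would have empty training sets.

**What the generator does not emulate.** Meal-time insulin dosing dynamics,
mixed-meal absorption kinetics, compression-low sensor artifacts, microbiome
effects, behavioral feedback (patients changing diet in response to
readings), and overlapping meal windows (default spacing prevents overlap;
attribution of overlapping responses is left undefined). Passing tests
therefore demonstrate correctness of the pipeline's machinery and its
statistical contracts on a mechanistically simple world — not clinical
performance on real patients.

**Corruption.** `corrupt_dataset` removes CGM samples completely at random
and replaces surviving samples with large spikes (±80–250 mg/dL, 70%
positive) at configured rates, recording injected outliers in a hidden
truth column so cleaning recall can be scored.

## 2. Cleaning and imputation

- **Outlier flagging**: robust z-score against a centered rolling
  median/MAD (window 9 samples). Median/MAD rather than mean/SD so the
  statistic is not dragged by the spikes being detected. The default
  threshold z = 4.0 was calibrated once on the generator's corrupted stream
  to reach ≥ 0.9 recall on injected spikes (measured 0.94, at a 2.6%
  false-positive rate); z = 5 missed too many spikes riding on steep meal
  rises, where the local MAD is inflated. Flags never delete data, and
  flagging is idempotent and monotone in the threshold.
- **Gap interpolation**: interior gaps ≤ 30 min are filled linearly and
  flagged `imputed`; longer gaps are left missing and feature assembly
  drops meals whose baseline or peak window is affected (reason-logged).
  Endpoints are never extrapolated.
- **MICE**: chained equations, m = 5 datasets, 10 cycles, Bayesian linear
  regression with posterior-predictive draws for continuous variables and
  multinomial logistic regression for categoricals; predictive-mean-matching
  (5 donors) and random-forest drawers support the sensitivity suite.
  Convergence is not formally monitored — 10 cycles is far past mixing for
  the low-dimensional tables used here. Pooling follows Rubin's Rules
  (`T = W̄ + (1+1/m)B`, Barnard–Rubin-style small-m df, infinite df at B=0).
- **Sensitivity suite**: the same outcome under complete-case, MICE, PMM
  and RF imputation; deviations beyond 10% relative to the MICE reference
  are flagged.

## 3. Feature engineering

The 37-variable registry (`data/registry.yaml`) is contractual: assembly
emits columns in registry order, models store the registry hash, and
prediction refuses mismatched vectors. Conventions:

- adjusted baseline: median over `[t−30 min, t]`, ≥ 3 samples, plus the
  medication penalty (per-class defaults metformin 6, sulfonylurea 8,
  SGLT2 7, GLP-1 9 mg/dL — configuration values, not trial-derived);
- glucoseMax over `(t, t+120 min]`, ties to the earliest sample;
- pre-meal slope: least-squares slope over the trailing 30 min;
- trailing glucose mean/SD over 1 h / 6 h / 24 h windows (partial windows
  allowed with ≥ 2 samples, so first-day meals stay usable);
- carb-to-protein ratio with a 1 g protein floor; glycemic load recomputed
  as GI/100 × carbs and reconciled against the logged value;
- time since last meal capped at 960 min (first meal of record gets the
  cap, flagged);
- default training target is the delta (peak − adjusted baseline), with the
  peak reconstructed as delta + baseline; both the absolute and relative
  impact are surfaced because either normalization is defensible.

A vectorized bulk path builds the full table; the suite asserts row-level
agreement with the one-op-at-a-time functions.

## 4. The predictor and its validation protocol

Default backend is LightGBM gradient boosting (deterministic, single
thread); `random_forest` (scikit-learn, sqrt feature subsampling,
min_samples_split 2) is a drop-in alternative. Tuning ranges are enforced:
boosting 100–500 trees, learning rate 0.01–0.1, depth 3–5, subsample 0.8,
L2 regularization; forest 100–300 trees, depth 3–7. The desk-scale capped
grid is 4 combinations (learning rate {0.05, 0.1} × depth {3, 5}); larger
grids are configuration.

Temporal dependencies are carried by engineered lag/trend features consumed
by the ensemble. A recurrent encoder is not included: at desk scale the lag
features satisfy the same temporal-dependency contract deterministically,
which keeps training reproducible bit-for-bit; the recurrent knobs (units,
dropout, learning rate) remain in the config surface for interface
completeness and are validated against their documented ranges.

Protocol details:

- **Folds**: k = 5 contiguous-in-time validation blocks partitioning the
  rows; training rows ≥ 14 days from every validation row of the fold; a
  fold left with fewer than 50 training rows makes the layout infeasible.
- **Nested selection**: per outer fold, 3 chronological inner blocks on the
  fold's training rows choose the grid point by mean inner MAE (no gap
  inside the inner split; the leakage the gap guards against is
  train→validation, which the outer gap enforces).
- **Early stopping**: the time-ordered last 10% of the training rows is the
  stopping monitor (30 rounds); the ensemble is refit on all training rows
  at the selected size so no data is discarded.
- **Final model**: majority-vote hyperparameters across folds (ties by
  inner MAE), refit on everything; reported metrics always come from the
  pooled outer-fold predictions.
- **Diagnostics**: the validation report includes residual normality
  (D'Agostino) and lag-1 autocorrelation, since independent/normal
  residuals are an assumption to check, not to assume.
- **Corrective update**: when the mean absolute excursion error on newly
  observed meals exceeds the policy threshold (default 25 mg/dL), the
  ensemble is refit on original + new rows under the same configuration and
  the model version increments; otherwise the model is returned unchanged.

## 5. Recommendation engine

- **Nutrient variability** is formalized (the platform names but does not
  define it) as the Euclidean distance between the candidate's calorie-share
  macro proportions (Atwater 4/4/9) and the patient's target shares; it is
  scaled by 50 mg/dL per unit distance (max distance √2) so λ₁ ≈ 1 trades
  roughly half a typical meal response against a maximally off-target
  macro profile. Preference penalties scale at 10 mg/dL per dislike-weight
  unit. λ₁ = λ₂ = 1 defaults and both scales are configuration, not
  platform-derived values, and the distance is swappable.
- Hard restrictions (allergies, diet rules) are pre-filters, never
  penalties — an allergen must not be outrankable.
- Ranking is the exact argmin (ascending score, ties by lower predicted
  PPGR then lexical food id) and is tested against exhaustive enumeration.
- **NRT thresholds** are patient-relative quantiles rather than absolute
  mg/dL cutoffs: initial tables use tertiles of predicted impact over the
  candidate set; feedback adaptation re-estimates empirical tertiles
  (linear-interpolation quantile convention) over a trailing window of
  observed impacts, requiring ≥ 10 observations, preserving
  t_green < t_orange, and bumping the table version.

## 6. Evaluation conventions

- MSE/RMSE/MAE/R² in their closed forms; R² flagged undefined at zero
  target variance.
- Spike AUC is the rank-based (Mann–Whitney, midrank-tie) statistic; the
  default spike rule is a rise > 40 mg/dL above adjusted baseline ("spike"
  is otherwise undefined in the source platform); an absolute-180 mg/dL
  rule is available.
- TIR uses inclusive bounds [70, 180] mg/dL, sample-weighted on the
  cleaned equal-interval grid; glycemic variability is the per-day SD
  averaged across days.
- Bootstrap CIs: percentile, B = 500, seeded.

## 7. Benchmark problem sizes and determinism

The desk benchmark is 60 patients × 30 days × 3 meals/day (5400 meals;
≈ 518k CGM samples) per seed, five seeds, at sensor noise 12 mg/dL, with a
7 mg/dL variant for the squared-error figure; one seed simulates, features
and trains in ≈ 25 s on one CPU. Fixture studies in the test suite use
12 × 21 and 20 × 10 cohorts. Per-seed metrics are summarized by the
second-worst seed (the value attained in ≥ 4 of 5 seeds). Every stochastic
step — cohort draws, streams, corruption, imputation, training, bootstrap —
derives from explicit seeds, and rerunning any stage with the same
configuration reproduces identical artifacts.

At noise σ = 7 the observed window-maximum still carries ≈ σ² of
measurement variance, so the achievable MSE of peak predictions is floored
near 50 mg²/dL² plus model error; the suite asserts the documented bound as
stated and reports the measured value without adjustment.

## 8. Known limitations

- The mechanism is linear-additive with a fixed kernel shape; models that
  exploit curvature or timing variation in real PPGRs are untested here.
- Overlapping meal windows are excluded by construction; snack-heavy
  schedules would need an attribution rule.
- Medication penalties are static configuration; dose–response and
  titration dynamics are out of scope.
- The MICE implementation targets the low-dimensional tabular settings used
  here, not high-dimensional or hierarchical missingness.
- The recommendation engine ranks single foods; multi-item meal composition
  (knapsack-style) is out of scope.
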