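# Feature registry for the Glucose Impact predictor.
#
# 37 predictor variables covering demographics, labs, meal nutrition,
# meal timing, recent-glucose trends, wearable activity/sleep context and
# medication burden. Order is contractual: assembled feature vectors and
# trained models both hash this registry and refuse to mix versions.
version: 1
features:
  - {name: age_years,                  type: numeric,  unit: years}
  - {name: sex_male,                   type: binary,   unit: ""}
  - {name: bmi_kg_m2,                  type: numeric,  unit: kg/m2}
  - {name: hba1c_pct,                  type: numeric,  unit: "%"}
  - {name: homa_index,                 type: numeric,  unit: ""}
  - {name: waist_cm,                   type: numeric,  unit: cm}
  - {name: calories_kcal,              type: numeric,  unit: kcal}
  - {name: carbs_g,                    type: numeric,  unit: g}
  - {name: protein_g,                  type: numeric,  unit: g}
  - {name: fat_g,                      type: numeric,  unit: g}
  - {name: fiber_g,                    type: numeric,  unit: g}
  - {name: glycemic_index,             type: numeric,  unit: ""}
  - {name: glycemic_load,              type: numeric,  unit: ""}
  - {name: carb_to_protein_ratio,      type: numeric,  unit: ""}
  - {name: time_since_last_meal_min,   type: numeric,  unit: min}
  - {name: meal_breakfast,             type: binary,   unit: ""}
  - {name: meal_lunch,                 type: binary,   unit: ""}
  - {name: meal_dinner,                type: binary,   unit: ""}
  - {name: meal_snack,                 type: binary,   unit: ""}
  - {name: hour_sin,                   type: numeric,  unit: ""}
  - {name: hour_cos,                   type: numeric,  unit: ""}
  - {name: premeal_baseline_mgdl,      type: numeric,  unit: mg/dL}
  - {name: premeal_slope_mgdl_min,     type: numeric,  unit: mg/dL/min}
  - {name: trail1h_mean_mgdl,          type: numeric,  unit: mg/dL}
  - {name: trail1h_sd_mgdl,            type: numeric,  unit: mg/dL}
  - {name: trail6h_mean_mgdl,          type: numeric,  unit: mg/dL}
  - {name: trail6h_sd_mgdl,            type: numeric,  unit: mg/dL}
  - {name: trail24h_mean_mgdl,         type: numeric,  unit: mg/dL}
  - {name: trail24h_sd_mgdl,           type: numeric,  unit: mg/dL}
  - {name: steps_prev_1h,              type: numeric,  unit: steps}
  - {name: steps_prev_24h,             type: numeric,  unit: steps}
  - {name: active_min_prev_24h,        type: numeric,  unit: min}
  - {name: sedentary_min_prev_24h,     type: numeric,  unit: min}
  - {name: sleep_minutes_prev_night,   type: numeric,  unit: min}
  - {name: sleep_efficiency_prev_night, type: numeric, unit: ""}
  - {name: n_glucose_lowering_meds,    type: numeric,  unit: count}
  - {name: med_penalty_total_mgdl,     type: numeric,  unit: mg/dL}
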