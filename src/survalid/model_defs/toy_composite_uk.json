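{
  "name": "toy-composite-uk",
  "outcome_label": "composite_cvd",
  "horizon": 10.0,
  "predictors": [
    {"name": "age", "covariate": "age", "transform": {"type": "identity"}, "coefficient": 0.07},
    {"name": "sbp", "covariate": "sbp", "transform": {"type": "identity"}, "coefficient": 0.013},
    {"name": "chol_ratio", "covariate": "chol_ratio", "transform": {"type": "identity"}, "coefficient": 0.15},
    {"name": "smoker", "covariate": "smoker", "transform": {"type": "indicator"}, "coefficient": 0.55},
    {"name": "diabetes", "covariate": "diabetes", "transform": {"type": "indicator"}, "coefficient": 0.6},
    {"name": "af", "covariate": "af", "transform": {"type": "indicator"}, "coefficient": 0.8},
    {"name": "age_x_smoker", "covariate": "age",
     "transform": {"type": "product", "with_covariate": "smoker",
                   "with_transform": {"type": "indicator"}},
     "coefficient": -0.004}
  ],
  "centring_means": {
    "age": 70.0,
    "sbp": 145.0,
    "chol_ratio": 4.5,
    "smoker": 0.15,
    "diabetes": 0.13,
    "af": 0.05,
    "age_x_smoker": 10.5
  },
  "baseline_survival": 0.75,
  "outcome_fraction": 0.366,
  "clinical_threshold": 0.10,
  "eligibility": [
    {"name": "prior stroke or TIA", "covariate": "prior_stroke", "op": "truthy"},
    {"name": "coronary heart disease", "covariate": "chd", "op": "truthy"},
    {"name": "statin use", "covariate": "statin", "op": "truthy"}
  ]
}
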