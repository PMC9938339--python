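{
  "name": "toy-composite-us",
  "outcome_label": "hard_cvd",
  "horizon": 10.0,
  "predictors": [
    {"name": "log_age", "covariate": "age", "transform": {"type": "log"}, "coefficient": 4.0},
    {"name": "sbp", "covariate": "sbp", "transform": {"type": "identity"}, "coefficient": 0.012},
    {"name": "chol_ratio", "covariate": "chol_ratio", "transform": {"type": "identity"}, "coefficient": 0.12},
    {"name": "smoker", "covariate": "smoker", "transform": {"type": "indicator"}, "coefficient": 0.5},
    {"name": "diabetes", "covariate": "diabetes", "transform": {"type": "indicator"}, "coefficient": 0.55}
  ],
  "centring_means": {
    "log_age": 4.248,
    "sbp": 145.0,
    "chol_ratio": 4.5,
    "smoker": 0.15,
    "diabetes": 0.13
  },
  "baseline_survival": 0.78,
  "outcome_fraction": 0.289,
  "clinical_threshold": 0.075,
  "eligibility": [
    {"name": "prior stroke or TIA", "covariate": "prior_stroke", "op": "truthy"},
    {"name": "coronary heart disease", "covariate": "chd", "op": "truthy"},
    {"name": "atrial fibrillation history", "covariate": "af_history", "op": "truthy"}
  ]
}
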