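{
  "name": "toy-stroke-uk",
  "outcome_label": "ischemic_stroke_tia",
  "horizon": 10.0,
  "predictors": [
    {"name": "age", "covariate": "age", "transform": {"type": "identity"}, "coefficient": 0.055},
    {"name": "sbp", "covariate": "sbp", "transform": {"type": "identity"}, "coefficient": 0.012},
    {"name": "chol_ratio", "covariate": "chol_ratio", "transform": {"type": "identity"}, "coefficient": 0.1},
    {"name": "log_bmi", "covariate": "bmi", "transform": {"type": "log"}, "coefficient": 0.4},
    {"name": "smoker", "covariate": "smoker", "transform": {"type": "indicator"}, "coefficient": 0.45},
    {"name": "diabetes", "covariate": "diabetes", "transform": {"type": "indicator"}, "coefficient": 0.5},
    {"name": "af", "covariate": "af", "transform": {"type": "indicator"}, "coefficient": 0.7}
  ],
  "centring_means": {
    "age": 70.0,
    "sbp": 145.0,
    "chol_ratio": 4.5,
    "log_bmi": 3.28,
    "smoker": 0.15,
    "diabetes": 0.13,
    "af": 0.05
  },
  "baseline_survival": 0.9,
  "outcome_fraction": 1.0,
  "eligibility": [
    {"name": "prior stroke or TIA", "covariate": "prior_stroke", "op": "truthy"},
    {"name": "anticoagulant use", "covariate": "anticoagulant", "op": "truthy"}
  ]
}
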