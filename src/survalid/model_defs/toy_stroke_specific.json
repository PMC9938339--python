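{
  "name": "toy-stroke-specific",
  "outcome_label": "stroke_tia",
  "horizon": 10.0,
  "predictors": [
    {"name": "age", "covariate": "age", "transform": {"type": "identity"}, "coefficient": 0.05},
    {"name": "sbp", "covariate": "sbp", "transform": {"type": "identity"}, "coefficient": 0.015},
    {"name": "smoker", "covariate": "smoker", "transform": {"type": "indicator"}, "coefficient": 0.5},
    {"name": "diabetes", "covariate": "diabetes", "transform": {"type": "indicator"}, "coefficient": 0.5},
    {"name": "af", "covariate": "af", "transform": {"type": "indicator"}, "coefficient": 0.6},
    {"name": "bp_treat", "covariate": "bp_treat", "transform": {"type": "indicator"}, "coefficient": 0.3}
  ],
  "centring_means": {
    "age": 70.0,
    "sbp": 145.0,
    "smoker": 0.15,
    "diabetes": 0.13,
    "af": 0.05,
    "bp_treat": 0.35
  },
  "baseline_survival": 0.89,
  "outcome_fraction": 1.0,
  "eligibility": [
    {"name": "prior stroke or TIA", "covariate": "prior_stroke", "op": "truthy"}
  ]
}
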