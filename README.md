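# survalid

External validation of proportional-hazards risk prediction models for
time-to-event outcomes, with first-class support for competing risks.

`survalid` is aimed at biostatisticians and epidemiologists who need to
answer the question: *how well does a published risk score — a stroke score
such as the Framingham Stroke Risk Profile or QStroke, or a composite
cardiovascular score such as QRISK3 or the Pooled Cohort Equations —
actually predict events in my cohort?* It is built around the situation
that makes this hard in older populations: follow-up is censored, and
competing deaths from other causes remove people from the risk set before
the outcome of interest can happen.

## What it computes

A risk model is supplied as a declarative JSON definition: predictors with
transforms and published coefficients, centring means, the 10-year baseline
survivor function `S0(10)`, an outcome fraction for composite tools, and
eligibility predicates. For a subject with covariates `x`:

```
PI  = Σ_j β_j t_j(x_j)              prognostic index (linear predictor)
CPI = PI − Σ_j β_j m_j              centred at the development means
P   = 1 − S0(10)^exp(CPI)           predicted 10-year probability
P*  = P × outcome_fraction          rescaled to the outcome of interest
```

(the outcome fraction converts a composite-CVD probability to its stroke
component, e.g. 0.366 for a QRISK3-style tool or 0.289 for a PCE-style
tool; it is 1 for stroke-specific tools).

The validation report then contains, for a main analysis and — whenever
competing deaths are present — a competing-risks sensitivity analysis:

* **Discrimination** — Harrell's C with a jackknife CI (competing-event
  subjects recoded as event-free for the competing-risks variant), plus
  Kaplan-Meier curves of four risk groups cut at the 16th/50th/84th PI
  centiles.
* **Calibration** — the calibration slope (Cox coefficient of the CPI,
  Breslow ties, Newton-Raphson), mean calibration (mean predicted risk /
  observed risk, where observed risk is the KM failure estimate or the
  Aalen-Johansen cause-specific cumulative incidence), and decile-based and
  age-band calibration tables.
* **Classification** — censoring-adjusted sensitivity, specificity, PPV and
  NPV at the cohort's own observed-risk cut-off and at clinical composite
  thresholds (10% / 7.5%) applied to unscaled probabilities.

All estimators (Kaplan-Meier, Aalen-Johansen, univariate Cox, Harrell's C)
are implemented in the package and exposed both as scikit-learn-style
estimator classes (`KaplanMeierEstimator`, `AalenJohansenEstimator`,
`UnivariateCoxPH`, `RiskScorer`, `ExternalValidator`) and as plain
functions.

Because cohort data of this kind are rarely public, the package ships a
synthetic-cohort generator (`survalid.simulate`) producing older-male
cohorts from configurable cause-specific stroke and competing-death
hazards, with the latent truth (true cumulative incidence, true 10-year
status) exported alongside so every estimate can be checked against ground
truth.

## Worked example

Generate a 4,000-man synthetic cohort (ages 60–80, ~10% ten-year
stroke/TIA risk, ~25% competing deaths rising steeply with age) and
validate the model that generated it:

```
$ survalid simulate --n 4000 --seed 7 --out demo
n=4000 events=421 competing=1020
wrote demo/cohort.csv

$ survalid validate --cohort demo/cohort.csv \
    --model demo/generating_model.json --out demo/val --age-bands 65,70,75
model: generating-model  n=4000 events=421
C-index 0.6382  slope 1.116  mean calibration 1.074
report: demo/val/report.json
```

The report (`demo/val/report.json`) shows the typical pattern for an older
cohort. In the main analysis the model discriminates modestly (C = 0.638
[0.612–0.665] — risk distributions are narrow when everyone is old), the
calibration slope 1.12 [0.92–1.31] is compatible with 1, mean calibration
is 1.07, and at the observed-risk cut-off (12.4%) sensitivity/specificity
are 64%/56%. In the competing-risks variant the cut-off drops to 10.7%
(the cumulative incidence is below the KM risk because competing deaths
preclude strokes), mean calibration rises to 1.25, and C falls to 0.622 —
accounting for competing mortality makes the same model look more
optimistic and less discriminating, exactly the distortion the toolkit is
designed to expose.

`survalid head2head` scores several models on one common eligible
sub-sample and emits per-model reports plus an agreement table over deciles
of the across-model mean prediction. Toy model definitions (synthetic
coefficients, not the published ones) live in `src/survalid/model_defs/`;
users validating a real tool supply their own JSON with the published
coefficients from the tool's development paper.

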