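# Methods

This note documents the statistical procedures implemented in `survalid`,
the choices made where conventions differ between software packages, and
what the synthetic-data generator does and does not emulate.

## Risk-model scoring

A model definition is purely declarative: ordered predictors, each a
(covariate, transform, coefficient) triple; centring means on the
*transformed* scale; the baseline survivor function at the horizon; an
outcome fraction; eligibility predicates. The transform vocabulary is
`identity`, natural `log`, `indicator` (binary or level-matching),
`one_hot`, and `product` (an interaction of two transformed covariates) —
enough to express the male equations of the common stroke and composite
CVD tools. Predicted risk is `1 − S0(h)^exp(CPI)`. Exponent overflow
(|CPI| > 700) saturates the probability toward 1 with a warning, since a
CPI of that size always indicates a scoring bug (wrong units, uncentred
covariates) rather than a real subject.

Missing covariates are handled by a hard complete-case rule: scoring a
subject with a missing predictor raises, and the cohort-level filter drops
such subjects, logs per-covariate missingness, and warns when more than
15% of the sample is lost (external validations of this kind typically
lose on the order of 5–12%). Nothing is ever imputed silently.

Eligibility predicates are simple exclusion rules over covariate flags
(`truthy` or a comparison against a constant). Real tools' exclusion sets
(prior stroke/TIA, CHD, statin or anticoagulant use, ...) are expressible,
but the shipped toy definitions only document plausible predicate
compositions; they make no fidelity claim for any published tool.

## Nonparametric estimators

* **Kaplan-Meier**: product-limit over distinct event times. All step
  functions are right-continuous, and censored subjects tied with an event
  time stay in the risk set for that time (censoring-after-event
  convention).
* **Aalen-Johansen**: `CIF_k(t) = Σ_{t_i ≤ t} S(t_i−) d_{k,i}/n_i` with
  `S` the all-cause KM. This construction telescopes, so
  `Σ_k CIF_k(t) + S(t) = 1` holds at every event time to float precision —
  a property the test suite asserts at 1e−12. For the outcome cause,
  `CIF_1(t) ≤ 1 − KM_1(t)` always, where `KM_1` censors competing events:
  the naive KM failure estimate overstates absolute risk whenever competing
  deaths exist, which is the central mechanism the competing-risks
  sensitivity analysis exposes.
* **Univariate Cox**: Breslow ties (matching the default computation path
  of the major survival packages), Newton-Raphson with step-halving
  whenever a step would decrease the partial likelihood, at most 50
  iterations. Convergence requires a vanishing score (tolerance 1e−8) *or*
  a vanishing Newton step: at n ≈ 10⁴ the score is a difference of sums of
  order 10⁴, so its achievable absolute floor is ~1e−5 while the step
  `score/information` still resolves to 1e−8 and is the equivalent
  criterion on the parameter scale. A converged estimate beyond |β| > 15
  is re-flagged as non-converged: a score that vanishes only at such values
  indicates a monotone partial likelihood (perfect separation), where no
  finite maximum exists. The slope CI is Wald (`β ± 1.96·SE` from the
  observed information); profile-likelihood intervals are out of scope.

## Discrimination

Harrell's C uses the standard pair rules: a pair is comparable iff the
shorter follow-up ended in an outcome event; at tied times an
event/censored pair counts the event as earlier and two tied events are
not comparable; tied predictions score 1/2. The implementation is a
chunked vectorized pair count; the test suite checks it to 1e−12 against
an explicit O(n²) loop and against scikit-survival. The standard error is
a grouped leave-one-subject-out jackknife computed from per-subject pair
tallies (each subject's removal subtracts its pairs from the totals), so
the SE costs no more than the point estimate.

Under competing risks, subjects whose follow-up ended with the competing
event are known to be outcome-free at every horizon; their comparison time
is pushed beyond all observed times before the pair rules are applied.
With zero competing events this reduces exactly to the main estimator. A
truncated-horizon variant of this recoding exists in the literature; the
plain event-free recoding was chosen and is what the brute-force oracle
mirrors.

Risk groups cut the PI at its 16th/50th/84th centiles (linear-interpolation
quantiles, pinned for reproducibility) into groups of roughly 16/34/34/16%;
assignment is by half-open interval with the top group closed. Heavy ties
may collapse a group, which is warned about rather than repaired.

## Calibration

* **Slope**: Cox coefficient of the CPI as the sole covariate; ideal 1,
  below 1 means predictions are too extreme. The test against slope = 1 is
  a two-sided Wald test. For the competing-risks variant the same
  event-free recoding as for the C-index is applied.
* **Mean calibration**: mean predicted (outcome-scale) risk divided by the
  observed risk at the horizon — KM failure estimate in the main analysis,
  cause-1 Aalen-Johansen CIF in the competing-risks analysis. Since
  CIF ≤ KM-risk, the competing-risks ratio is never below the main one.
* **Decile calibration**: subjects ranked by prediction (stable sort, so
  ties break by input order), split into near-equal bins (sizes differ by
  at most 1); observed risk per bin is the *within-bin* KM (or CIF) at the
  horizon, not the raw event fraction, so censored subjects contribute
  correctly. A bin with zero events records observed risk 0 and is
  flagged.
* **Age-band calibration** reports mean prediction, KM risk and CIF risk
  per band (defaults ≤65, 65–70, 70–75, >75). The per-band KM−CIF spread
  is the display of how competing mortality increasingly distorts naive
  observed risk with age. Scaled (outcome-level) probabilities are used
  here for all tools, composite ones included, since the comparison is
  against observed stroke-level risk.

## Censoring-adjusted classification

With censoring, 10-year sensitivity/specificity cannot come from a 2×2
table. The package uses the cumulative/dynamic estimator with KM within
marker strata: for threshold `c`, `q = P(pred > c)`, `F⁺`/`F⁻` the
KM-at-horizon risk above/below the threshold, `F` the overall risk, and

```
Sn = q·F⁺/F     Sp = (1−q)(1−F⁻)/(1−F)     PPV = F⁺     NPV = 1−F⁻.
```

Without censoring these reduce *exactly* to the empirical 2×2 values,
which the tests assert to 1e−12. Under competing risks every `F` is
replaced by the cause-1 CIF (full substitution, consistent with reporting
observed risk as CIF in that variant). KM-stratum estimators can stray
slightly outside [0,1] under heavy censoring; metrics are clipped and the
clipping logged. Two threshold sources are distinguished: the cohort's own
observed risk at the horizon (applied to outcome-scale predictions), and
clinical composite thresholds — 10% (QRISK3-style) and 7.5% (PCE-style) —
applied to *unscaled* composite probabilities while the outcome being
classified remains the stroke event. The threshold sweep reports the
monotone Sn/Sp trade-off over a user grid.

## Synthetic cohort generator

The generator draws men aged uniformly 60–80 with a reduced cardiovascular
covariate panel (systolic BP, cholesterol ratio, BMI, smoking, diabetes,
AF, BP treatment, plus pure eligibility flags), then draws latent event
times from two cause-specific proportional-hazards models — stroke/TIA and
competing non-stroke death — by inverse transform from
`Λ(t|x) = rate·t^shape·exp(lp(x))` (shape 1 = exponential, else Weibull).
The observed cause is the argmin of the latent times; censoring is the
minimum of the 10-year administrative horizon and an independent uniform
dropout time (default dropout fraction 4%, emulating near-complete
follow-up). Every cohort carries a separate truth table (true linear
predictors, latent times, true 10-year CIF, true 10-year status) written
to a separate file so a validation pipeline cannot consume it by accident.

The default scenario's hazards were calibrated analytically — not fitted to
any test outcome — to the event mix typical of a cohort of older British
men: stroke baseline 0.0105/yr and competing baseline 0.027/yr at the
covariate centre give a closed-form 10-year stroke incidence near 10% and
competing mortality near 24% (about 2.5 competing deaths per stroke), and
the competing-death age coefficient 0.085/yr produces a KM−CIF gap of
roughly 4 percentage points above age 75. The slope-recovery scenario is
deliberately different: a single standardized risk covariate (sd 1.2), a
0.05/yr exponential baseline and no competing cause give ~4,000 events per
10,000 subjects, putting the Wald SE of a fitted calibration slope near
0.015 so that recovery experiments have unambiguous resolution. That
single-cause scenario is also the one used for mean-calibration recovery
checks, because there the KM estimand coincides exactly with the model's
net-risk estimand; in the competing-risks scenario the KM reference
carries both extra sampling noise (≈3% relative at 10% risk) and a small
dependent-censoring bias from covariates shared between the two hazards,
which is a property of KM-referenced mean calibration itself, not of the
estimator.

Miscalibration knobs manufacture the classic external-validation failure
modes relative to the *unmodified* evaluated model: `slope_multiplier m`
divides the true log-hazard spread so the fitted slope comes out near
`1/m` (predictions too extreme — overfitting); `baseline_inflation b`
divides the true baseline hazard so the mean-calibration ratio comes out
near `b` (exactly `b` only in the small-risk limit, slightly less at ~10%
risks because risk is a concave function of cumulative hazard);
`top_tail_inflation τ < 1` deflates true risk above a percentile of the
linear predictor (default 70th), confining overestimation to the upper
deciles.

What the generator does **not** emulate: real covariate correlation
structures, informative censoring (a knob exists but defaults off, since
independent censoring is the standard working assumption), recruitment or
secular effects, measurement error, and the exact covariate distributions
of any real cohort. Passing tests therefore demonstrate the correctness of
the validation machinery under a controlled truth, not the distributional
fidelity of any specific study population.

## Pipeline

`ExternalValidator.fit` executes, in order: eligibility filter →
complete-case filter → horizon capping (times beyond the horizon censored
at it) → minimum-event check (default 100 outcome events; overridable,
blocking otherwise) → scoring → discrimination → calibration →
classification, with a competing-risks variant appended whenever code-2
events exist — appended, never substituted, so the main analysis is always
reported. Each stage failure raises with a stage label and no partial
outputs are written. Reports are JSON with sorted keys plus tidy CSV
sub-tables; percentages are on the 0–100 scale; the provenance block
records input SHA-256 hashes, the run configuration and the package
version (no timestamps), so identical inputs produce byte-identical
outputs. Head-to-head runs build a single common sub-sample (union of all
models' exclusions, complete cases across all predictors), score every
model on it, and emit an agreement table over deciles of the across-model
mean prediction plus per-subject prediction scatter data.

## Known limitations

* Single-covariate Cox only — the slope machinery is not a general Cox
  regression; no Fine-Gray subdistribution model.
* Point estimates only for KM/CIF (no Greenwood variance); Wald CIs
  throughout.
* Female equations and re-derivation of published coefficients are out of
  scope; shipped model files are synthetic toys.
* The problem sizes used by the test-suite recovery experiments (10⁴–10⁵
  subjects) were chosen so that Monte-Carlo noise is small against the
  asserted tolerances while runs stay fast on a laptop.
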