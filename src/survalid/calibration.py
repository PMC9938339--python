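"""Calibration of predicted against observed risk.

Three complementary views:

* **calibration slope** — the coefficient of the centred prognostic index
  (CPI) as the single covariate of a Cox model refitted on the validation
  data; 1 is ideal, < 1 means predictions are too extreme (overfitting).
* **mean calibration** (calibration-in-the-large) — the ratio of the global
  mean predicted risk to the observed risk at the horizon; > 1 is global
  overestimation. Observed risk is the Kaplan-Meier failure estimate, or
  the cause-specific cumulative incidence when competing deaths are
  accounted for (the CIF never exceeds the KM risk, so the competing-risk
  ratio is never below the main one).
* **moderate calibration** — mean predicted vs observed risk within deciles
  of predicted risk, and within age bands.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimators import AalenJohansenEstimator, UnivariateCoxPH, kaplan_meier

__all__ = [
    "CalibrationSlope",
    "calibration_slope",
    "mean_calibration",
    "observed_risk",
    "decile_calibration",
    "age_group_calibration",
]


@dataclass
class CalibrationSlope:
    slope: float
    se: float
    ci95: tuple[float, float]
    p_vs_1: float  # two-sided Wald test of slope = 1
    n_events: int
    converged: bool
    variant: str


def _recode(times, event_codes, variant: str):
    """Outcome-event 0/1 coding for the requested variant.

    ``main`` treats competing deaths as censored at their event time;
    ``competing_risk`` treats them as known event-free beyond all observed
    times (Wolbers-style recoding).
    """
    t = np.asarray(times, dtype=float).copy()
    codes = np.asarray(event_codes, dtype=int)
    events = (codes == 1).astype(int)
    if variant == "competing_risk":
        t[codes == 2] = t.max() + 1.0
    elif variant != "main":
        raise ValueError(f"unknown variant {variant!r}")
    return t, events


def calibration_slope(times, event_codes, cpi_values, variant: str = "main") -> CalibrationSlope:
    """Cox regression of the outcome on the CPI as sole covariate."""
    t, events = _recode(times, event_codes, variant)
    fit = UnivariateCoxPH().fit(t, events, np.asarray(cpi_values, dtype=float)).fit_
    z = (fit.beta - 1.0) / fit.standard_error
    p = float(2.0 * stats.norm.sf(abs(z)))
    return CalibrationSlope(
        slope=fit.beta,
        se=fit.standard_error,
        ci95=fit.ci95,
        p_vs_1=p,
        n_events=fit.n_events,
        converged=fit.converged,
        variant=variant,
    )


def observed_risk(times, event_codes, horizon: float, reference: str = "km") -> float:
    """Observed outcome risk at the horizon.

    ``km`` censors competing deaths (net risk); ``cif`` is the cause-1
    Aalen-Johansen cumulative incidence (crude risk under competing risks).
    """
    times = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes, dtype=int)
    if reference == "km":
        return kaplan_meier(times, (codes == 1).astype(int)).risk_at(horizon)
    if reference == "cif":
        return AalenJohansenEstimator().fit(times, codes).incidence_at(horizon, cause=1)
    raise ValueError(f"unknown reference {reference!r}")


def mean_calibration(predictions, times, event_codes, horizon: float = 10.0,
                     reference: str = "km") -> float:
    """Ratio of global mean predicted risk to observed risk at the horizon."""
    obs = observed_risk(times, event_codes, horizon, reference)
    if obs <= 0:
        raise ValueError("observed risk at the horizon is zero; calibration ratio undefined")
    return float(np.mean(np.asarray(predictions, dtype=float)) / obs)


def decile_calibration(predictions, times, event_codes, n_bins: int = 10,
                       horizon: float = 10.0, reference: str = "km") -> pd.DataFrame:
    """Observed vs mean predicted risk in near-equal bins of predicted risk.

    Subjects are ranked by prediction (ties broken by input order) and split
    into ``n_bins`` groups whose sizes differ by at most one. Observed risk
    per bin is the within-bin KM failure estimate (or cause-1 CIF).
    """
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes, dtype=int)
    n = len(p)
    if n < n_bins:
        raise ValueError(f"need at least {n_bins} subjects for {n_bins} bins")
    order = np.argsort(p, kind="stable")
    rows = []
    for b, idx in enumerate(np.array_split(order, n_bins), start=1):
        n_events = int((codes[idx] == 1).sum())
        if n_events == 0:
            warnings.warn(f"calibration bin {b} has zero outcome events", UserWarning)
            obs = 0.0
        else:
            obs = observed_risk(t[idx], codes[idx], horizon, reference)
        rows.append(
            {
                "bin": b,
                "n": len(idx),
                "events": n_events,
                "mean_predicted": float(p[idx].mean()),
                "observed": float(obs),
            }
        )
    return pd.DataFrame(rows)


def age_group_calibration(ages, predictions, times, event_codes,
                          bins: tuple[float, ...] = (65.0, 70.0, 75.0),
                          horizon: float = 10.0) -> pd.DataFrame:
    """Mean predicted vs KM and CIF observed risk across age bands.

    Default bands: <=65, >65-<=70, >70-<=75, >75 years. The spread between
    the per-band KM risk and cause-1 CIF displays how strongly competing
    mortality distorts naive observed risk as age increases.
    """
    ages = np.asarray(ages, dtype=float)
    p = np.asarray(predictions, dtype=float)
    t = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes, dtype=int)
    edges = list(bins)
    band = np.digitize(ages, edges, right=True)
    labels = (
        [f"<={edges[0]:g}"]
        + [f">{lo:g}-<={hi:g}" for lo, hi in zip(edges[:-1], edges[1:])]
        + [f">{edges[-1]:g}"]
    )
    rows = []
    for b, label in enumerate(labels):
        idx = np.flatnonzero(band == b)
        if len(idx) == 0:
            warnings.warn(f"age band {label} is empty; omitted", UserWarning)
            continue
        rows.append(
            {
                "age_band": label,
                "n": len(idx),
                "events": int((codes[idx] == 1).sum()),
                "mean_predicted": float(p[idx].mean()),
                "km_risk": observed_risk(t[idx], codes[idx], horizon, "km"),
                "cif_risk": observed_risk(t[idx], codes[idx], horizon, "cif"),
            }
        )
    return pd.DataFrame(rows)
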