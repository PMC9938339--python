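"""Censoring-adjusted classification at a probability threshold.

Sensitivity and specificity for event-by-horizon status cannot be read off
a 2x2 table when follow-up is censored: a cumulative/dynamic estimator is
used instead, with Kaplan-Meier (or cause-1 cumulative incidence, under
competing risks) estimating the event-by-horizon fraction within each side
of the threshold:

    q   = P(prediction > c)
    F+  = risk at horizon among prediction > c
    F-  = risk at horizon among prediction <= c
    F   = overall risk at horizon
    Sn  = q * F+ / F          Sp = (1 - q) * (1 - F-) / (1 - F)
    PPV = F+                  NPV = 1 - F-

Without censoring or competing events these reduce exactly to the
empirical 2x2-table quantities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .calibration import observed_risk

__all__ = [
    "ClassificationResult",
    "censoring_adjusted_sn_sp",
    "threshold_at_observed_risk",
    "clinical_threshold_classification",
    "threshold_sweep",
    "CLINICAL_THRESHOLDS",
]

logger = logging.getLogger(__name__)

# conventional composite-CVD intervention thresholds (probability scale)
CLINICAL_THRESHOLDS = {"qrisk3": 0.10, "pce": 0.075}


@dataclass
class ClassificationResult:
    threshold: float
    horizon: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    variant: str  # "main" | "competing_risk"
    threshold_source: str  # "observed_risk" | "clinical" | "user"
    n_above: int = 0
    degenerate: bool = False


def censoring_adjusted_sn_sp(times, event_codes, predictions, threshold: float,
                             horizon: float = 10.0, variant: str = "main",
                             threshold_source: str = "user") -> ClassificationResult:
    """Cumulative/dynamic Sn, Sp, PPV and NPV at a probability threshold."""
    t = np.asarray(times, dtype=float)
    codes = np.asarray(event_codes, dtype=int)
    p = np.asarray(predictions, dtype=float)
    if (codes == 1).sum() == 0:
        raise ValueError("no outcome events; classification metrics undefined")
    reference = "cif" if variant == "competing_risk" else "km"

    above = p > threshold
    q = float(above.mean())
    degenerate = False
    if above.all() or (~above).all():
        warnings.warn(
            f"threshold {threshold:g} leaves one side of the split empty; "
            "metrics are degenerate boundary values",
            UserWarning,
        )
        degenerate = True

    overall = observed_risk(t, codes, horizon, reference)
    if overall <= 0 or overall >= 1:
        raise ValueError(f"overall risk at horizon is {overall:g}; Sn/Sp undefined")
    f_plus = observed_risk(t[above], codes[above], horizon, reference) if above.any() else 0.0
    f_minus = observed_risk(t[~above], codes[~above], horizon, reference) if (~above).any() else 0.0

    sn = q * f_plus / overall
    sp = (1.0 - q) * (1.0 - f_minus) / (1.0 - overall)
    raw = {"sensitivity": sn, "specificity": sp, "ppv": f_plus, "npv": 1.0 - f_minus}
    clipped = {k: float(np.clip(v, 0.0, 1.0)) for k, v in raw.items()}
    for k in raw:
        if raw[k] != clipped[k]:
            logger.info("classification metric %s=%.4f clipped into [0,1]", k, raw[k])
    return ClassificationResult(
        threshold=float(threshold),
        horizon=float(horizon),
        variant=variant,
        threshold_source=threshold_source,
        n_above=int(above.sum()),
        degenerate=degenerate,
        **clipped,
    )


def threshold_at_observed_risk(times, event_codes, horizon: float = 10.0,
                               variant: str = "main") -> float:
    """The cohort's own risk at the horizon, used as the high-risk cut-off.

    KM failure estimate for the main validation; cause-1 cumulative
    incidence under competing risks (always at or below the KM value).
    """
    reference = "cif" if variant == "competing_risk" else "km"
    risk = observed_risk(np.asarray(times, float), np.asarray(event_codes, int), horizon, reference)
    if risk <= 0:
        raise ValueError("no observed risk at the horizon; cut-off undefined")
    return risk


def clinical_threshold_classification(unscaled_predictions, times, event_codes,
                                      tool: str, horizon: float = 10.0,
                                      variant: str = "main") -> ClassificationResult:
    """Classification at a conventional composite-CVD intervention threshold.

    The threshold (10% for QRISK3-style tools, 7.5% for PCE-style tools)
    applies to the UNSCALED composite probabilities, while the outcome being
    classified remains the stroke event.
    """
    try:
        threshold = CLINICAL_THRESHOLDS[tool.lower()]
    except KeyError:
        raise ValueError(f"unknown tool {tool!r}; expected one of {sorted(CLINICAL_THRESHOLDS)}")
    res = censoring_adjusted_sn_sp(times, event_codes, unscaled_predictions, threshold,
                                   horizon=horizon, variant=variant, threshold_source="clinical")
    return res


def threshold_sweep(predictions, times, event_codes, thresholds,
                    horizon: float = 10.0, variant: str = "main") -> pd.DataFrame:
    """One classification row per threshold (thresholds sorted ascending)."""
    thresholds = list(thresholds)
    if thresholds != sorted(thresholds):
        raise ValueError("thresholds must be sorted ascending")
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)  # boundary thresholds are expected here
        for c in thresholds:
            r = censoring_adjusted_sn_sp(times, event_codes, predictions, c,
                                         horizon=horizon, variant=variant)
            rows.append(
                {
                    "threshold": r.threshold,
                    "sensitivity": r.sensitivity,
                    "specificity": r.specificity,
                    "ppv": r.ppv,
                    "npv": r.npv,
                    "n_above": r.n_above,
                }
            )
    return pd.DataFrame(rows)
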