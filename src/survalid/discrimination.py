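"""Discrimination: Harrell's C-index and prognostic-index risk groups.

A pair of subjects is comparable when the one with the shorter follow-up
had the outcome event (an event/censored tie at the same time counts the
event as earlier; two events at the same time are not comparable). The pair
is concordant when the earlier-event subject carries the higher predicted
risk; prediction ties contribute 1/2. Under competing risks, subjects whose
follow-up ended with the competing event are known to be outcome-free at
every horizon, so their comparison time is pushed beyond all observed times
before the standard pair rule is applied.

The standard error is a grouped leave-one-subject-out jackknife over the
pair counts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .estimators import SurvivalCurve, kaplan_meier

__all__ = [
    "DiscriminationResult",
    "RiskGroups",
    "harrells_c",
    "harrells_c_competing",
    "risk_groups_by_pi",
    "km_by_group",
]

GROUP_LABELS = ("low", "intermediate", "high", "very_high")


@dataclass
class DiscriminationResult:
    c_index: float
    se: float
    ci95: tuple[float, float]
    n_pairs: int
    variant: str  # "main" | "competing_risk"


@dataclass
class RiskGroups:
    labels: np.ndarray  # per-subject label from GROUP_LABELS
    cut_points: tuple[float, float, float]  # PI at the 16th, 50th, 84th centiles

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)


def _pair_counts(times, events, predictions, chunk: int = 512):
    """Total and per-subject comparable/score counts over all ordered pairs."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    p = np.asarray(predictions, dtype=float)
    n = len(t)
    num_i = np.zeros(n)  # concordant + 0.5*tied contributions per subject
    den_i = np.zeros(n)  # comparable pairs per subject
    for start in range(0, n, chunk):
        sl = slice(start, min(start + chunk, n))
        ti, ei, pi_ = t[sl, None], e[sl, None], p[sl, None]
        # orientation: row subject is the (earlier) case
        case = (ti < t[None, :]) & ei
        case |= (ti == t[None, :]) & ei & ~e[None, :]
        conc = case & (pi_ > p[None, :])
        tied = case & (pi_ == p[None, :])
        score = conc + 0.5 * tied
        num_i[sl] += score.sum(axis=1)
        num_i += score.sum(axis=0)
        den_i[sl] += case.sum(axis=1)
        den_i += case.sum(axis=0)
    return num_i, den_i


def _c_from_counts(num_i, den_i, variant: str) -> DiscriminationResult:
    # every pair is counted once in each of its two members' tallies
    total_num = num_i.sum() / 2.0
    total_den = den_i.sum() / 2.0
    if total_den == 0:
        raise ValueError("no comparable pairs; C-index undefined")
    c = total_num / total_den
    n = len(num_i)
    # leave-one-out: remove all pairs involving subject i
    with np.errstate(invalid="ignore"):
        loo = (total_num - num_i) / (total_den - den_i)
    loo = np.where(den_i == total_den, c, loo)  # degenerate: subject in every pair
    se = float(np.sqrt((n - 1) / n * np.sum((loo - loo.mean()) ** 2)))
    lo, hi = c - 1.96 * se, c + 1.96 * se
    return DiscriminationResult(
        c_index=float(c),
        se=se,
        ci95=(max(0.0, float(lo)), min(1.0, float(hi))),
        n_pairs=int(round(total_den)),
        variant=variant,
    )


def harrells_c(times, events, predictions) -> DiscriminationResult:
    """Harrell's concordance index for right-censored data (events 0/1)."""
    events = np.asarray(events, dtype=int)
    if not np.isin(events, (0, 1)).all():
        raise ValueError("events must be coded 0/1; use harrells_c_competing for code 2")
    if events.sum() == 0:
        raise ValueError("no events; C-index undefined")
    num_i, den_i = _pair_counts(times, events, predictions)
    return _c_from_counts(num_i, den_i, "main")


def harrells_c_competing(times, event_codes, predictions) -> DiscriminationResult:
    """Competing-risks C-index: competing-event subjects recoded event-free.

    Their follow-up time is set beyond every observed time so they act as
    controls in all comparable pairs, then the standard pair rule applies.
    Identical to :func:`harrells_c` when no competing events exist.
    """
    t = np.asarray(times, dtype=float).copy()
    codes = np.asarray(event_codes, dtype=int)
    if not np.isin(codes, (0, 1, 2)).all():
        raise ValueError("event codes must be in {0,1,2}")
    competing = codes == 2
    t[competing] = t.max() + 1.0
    events = (codes == 1).astype(int)
    if events.sum() == 0:
        raise ValueError("no outcome events; C-index undefined")
    num_i, den_i = _pair_counts(t, events, predictions)
    return _c_from_counts(num_i, den_i, "competing_risk")


def risk_groups_by_pi(pi_values) -> RiskGroups:
    """Split subjects into 4 risk groups at the 16th/50th/84th PI centiles."""
    pi = np.asarray(pi_values, dtype=float)
    if len(pi) < 4:
        raise ValueError("need at least 4 subjects to form risk groups")
    cuts = np.percentile(pi, [16, 50, 84])  # linear-interpolation quantiles
    idx = np.digitize(pi, cuts)  # half-open [lo, hi); top group closed
    labels = np.array(GROUP_LABELS)[idx]
    counts = [(labels == g).sum() for g in GROUP_LABELS]
    if any(c == 0 for c in counts):
        warnings.warn(
            f"tied prognostic indices collapsed a risk group (sizes {counts}); "
            "groups are unbalanced",
            UserWarning,
        )
    return RiskGroups(labels=labels, cut_points=tuple(float(c) for c in cuts))


def km_by_group(times, events, groups: RiskGroups) -> dict[str, SurvivalCurve]:
    """One Kaplan-Meier curve per risk group (outcome events only)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    curves: dict[str, SurvivalCurve] = {}
    for g in GROUP_LABELS:
        idx = groups.indices(g)
        if len(idx) == 0:
            warnings.warn(f"risk group '{g}' is empty; omitted", UserWarning)
            continue
        curves[g] = kaplan_meier(times[idx], (events[idx] == 1).astype(int))
    return curves
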