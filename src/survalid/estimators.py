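"""Nonparametric survival estimators and a univariate Cox fitter.

These are the numeric core of the validation procedure: the Kaplan-Meier
product-limit estimator supplies observed risk at the horizon, the
Aalen-Johansen estimator supplies cause-specific cumulative incidence under
competing risks, and the single-covariate Cox partial-likelihood fitter is
the machinery behind the calibration slope.

All step functions are right-continuous; censored subjects at a tied time
are processed after the events at that time (they remain in the risk set
for the tie). Tied event times use the Breslow approximation in the Cox
partial likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "SurvivalCurve",
    "CIFCurve",
    "CoxFit",
    "KaplanMeierEstimator",
    "AalenJohansenEstimator",
    "UnivariateCoxPH",
    "kaplan_meier",
    "km_risk_at",
    "aalen_johansen",
    "fit_cox_single_covariate",
]


@dataclass
class SurvivalCurve:
    """Right-continuous product-limit survivor estimate.

    ``survival[i]`` is the step value S(t) for event_times[i] <= t <
    event_times[i+1]; S(t) = 1 before the first event time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray
    max_follow_up: float

    def survival_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("time must be >= 0")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def risk_at(self, t: float) -> float:
        """1 - S(t); beyond follow-up returns the last value with a warning."""
        if t > self.max_follow_up:
            warnings.warn(
                f"risk requested at t={t:g} beyond last follow-up {self.max_follow_up:g}; "
                "returning the final estimate",
                UserWarning,
            )
        return 1.0 - self.survival_at(min(t, self.max_follow_up))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times,
                "estimate": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
            }
        )


@dataclass
class CIFCurve:
    """Aalen-Johansen cumulative incidence for one cause, right-continuous."""

    cause: int
    event_times: np.ndarray
    incidence: np.ndarray
    max_follow_up: float

    def incidence_at(self, t: float) -> float:
        if t < 0:
            raise ValueError("time must be >= 0")
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.incidence[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.event_times, "estimate": self.incidence, "cause": self.cause})


@dataclass
class CoxFit:
    beta: float
    standard_error: float
    ci95: tuple[float, float]
    iterations: int
    converged: bool
    log_partial_likelihood: float
    n_events: int = 0


def _check_times(times) -> np.ndarray:
    times = np.asarray(times, dtype=float)
    if times.ndim != 1:
        raise ValueError("times must be 1-dimensional")
    if np.any(times <= 0):
        raise ValueError("all times must be > 0")
    return times


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit estimator of the survivor function.

    Fitted attributes
    -----------------
    curve_ : SurvivalCurve
        Step-function estimate over the distinct event times.
    """

    def fit(self, times, events):
        times = _check_times(times)
        events = np.asarray(events, dtype=int)
        if times.shape != events.shape:
            raise ValueError("times and events must have equal length")
        if not np.isin(events, (0, 1)).all():
            raise ValueError("events must be coded 0/1")
        if events.sum() == 0:
            warnings.warn("no events observed; survivor curve is flat at 1", UserWarning)

        t = np.sort(times, kind="stable")
        te = np.sort(times[events == 1], kind="stable")
        uniq = np.unique(te)
        n = len(t)
        # censored at u stay in the risk set for events at u
        at_risk = n - np.searchsorted(t, uniq, side="left")
        n_events = np.searchsorted(te, uniq, side="right") - np.searchsorted(te, uniq, side="left")
        surv = np.cumprod(1.0 - n_events / at_risk)
        self.curve_ = SurvivalCurve(uniq, surv, at_risk, n_events, float(times.max()) if n else 0.0)
        return self

    def survival_at(self, t: float) -> float:
        return self.curve_.survival_at(t)

    def risk_at(self, t: float) -> float:
        return self.curve_.risk_at(t)


class AalenJohansenEstimator(BaseEstimator):
    """Cause-specific cumulative incidence under competing risks.

    CIF_k(t) = sum_{t_i <= t} S(t_i-) d_{k,i} / n_i with S the all-cause
    Kaplan-Meier estimate, so that sum_k CIF_k(t) + S(t) = 1 at every event
    time by construction.

    Fitted attributes
    -----------------
    cif_ : dict[int, CIFCurve]
        One curve per observed cause code (outcome = 1, competing = 2).
    overall_survival_ : SurvivalCurve
        All-cause Kaplan-Meier survivor estimate.
    """

    def fit(self, times, event_codes):
        times = _check_times(times)
        codes = np.asarray(event_codes, dtype=int)
        if not np.isin(codes, (0, 1, 2)).all():
            raise ValueError("event codes must be in {0,1,2}")

        any_event = (codes > 0).astype(int)
        km = KaplanMeierEstimator().fit(times, any_event)
        self.overall_survival_ = km.curve_

        uniq = km.curve_.event_times
        # S(t-) at each distinct event time: 1 before the first
        s_minus = np.concatenate([[1.0], km.curve_.survival[:-1]])
        self.cif_ = {}
        for cause in (1, 2):
            tc = np.sort(times[codes == cause], kind="stable")
            d_k = np.searchsorted(tc, uniq, side="right") - np.searchsorted(tc, uniq, side="left")
            inc = np.cumsum(s_minus * d_k / km.curve_.at_risk)
            self.cif_[cause] = CIFCurve(cause, uniq, inc, km.curve_.max_follow_up)
        return self

    def incidence_at(self, t: float, cause: int = 1) -> float:
        return self.cif_[cause].incidence_at(t)


class UnivariateCoxPH(BaseEstimator):
    """Single-covariate Cox proportional-hazards fitter (Breslow ties).

    Newton-Raphson on the log partial likelihood with step-halving when a
    step would decrease the likelihood. Intended for the calibration slope,
    where the covariate is the centred prognostic index.

    Parameters
    ----------
    tol : float
        Convergence tolerance on the absolute score.
    max_iter : int
        Maximum Newton iterations; non-convergence is flagged, never silent.

    Fitted attributes
    -----------------
    fit_ : CoxFit
        beta, model-based SE from the observed information, Wald 95% CI.
    """

    def __init__(self, tol: float = 1e-8, max_iter: int = 50):
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, times, events, x):
        times = _check_times(times)
        events = np.asarray(events, dtype=int)
        x = np.asarray(x, dtype=float)
        if events.sum() < 2:
            raise ValueError("Cox fit requires at least 2 events")
        if np.ptp(x) == 0:
            raise ValueError("covariate is constant; Cox fit is degenerate")

        # sort descending by time so the risk set at each event time is a prefix
        order = np.argsort(-times, kind="stable")
        t, d, xv = times[order], events[order], x[order]
        event_mask = d == 1
        uniq = np.unique(t[event_mask])
        # per distinct event time: Breslow multiplicity, sum of x over the
        # tied events, and the prefix end of its risk set (all t >= u;
        # censored at u stay in the risk set)
        k_u = np.array([np.sum(event_mask & (t == u)) for u in uniq], dtype=float)
        sx_u = np.array([xv[event_mask & (t == u)].sum() for u in uniq])
        last_u = np.searchsorted(-t, -uniq, side="right") - 1
        sum_event_x = float(sx_u.sum())

        def loglik_parts(beta: float):
            w = np.exp(beta * xv)
            s0 = np.cumsum(w)[last_u]
            s1 = np.cumsum(w * xv)[last_u]
            s2 = np.cumsum(w * xv * xv)[last_u]
            xbar = s1 / s0
            ll = beta * sum_event_x - float(k_u @ np.log(s0))
            score = sum_event_x - float(k_u @ xbar)
            info = float(k_u @ (s2 / s0 - xbar * xbar))
            return ll, score, info

        beta = 0.0
        ll, score, info = loglik_parts(beta)
        converged = False
        it = 0
        for it in range(1, self.max_iter + 1):
            # converged when the score vanishes or the Newton step does
            # (the absolute score saturates at float precision for large n)
            if abs(score) < self.tol or abs(score / info) < self.tol:
                converged = True
                break
            step = score / info
            new_beta = beta + step
            new_ll, new_score, new_info = loglik_parts(new_beta)
            halvings = 0
            while new_ll < ll - 1e-12 * abs(ll) and halvings < 30:
                step /= 2.0
                new_beta = beta + step
                new_ll, new_score, new_info = loglik_parts(new_beta)
                halvings += 1
            beta, ll, score, info = new_beta, new_ll, new_score, new_info
        if abs(score) < self.tol or abs(score / info) < self.tol:
            converged = True
        if converged and abs(beta) > 15.0:
            # monotone partial likelihood (perfect separation): the score
            # vanishes only as beta drifts to the boundary
            warnings.warn(
                f"estimate drifted to |beta|={abs(beta):.1f}; the partial likelihood "
                "appears monotone (perfect separation) and no finite maximum exists",
                UserWarning,
            )
            converged = False
        if not converged:
            warnings.warn(
                f"Cox fit did not converge in {self.max_iter} iterations (|score|={abs(score):.2e})",
                UserWarning,
            )
        se = float(1.0 / np.sqrt(info))
        self.fit_ = CoxFit(
            beta=float(beta),
            standard_error=se,
            ci95=(float(beta - 1.96 * se), float(beta + 1.96 * se)),
            iterations=it,
            converged=converged,
            log_partial_likelihood=float(ll),
            n_events=int(events.sum()),
        )
        return self


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------

def kaplan_meier(times, events) -> SurvivalCurve:
    """Product-limit survivor estimate (events coded 0/1)."""
    return KaplanMeierEstimator().fit(times, events).curve_


def km_risk_at(curve: SurvivalCurve, t: float) -> float:
    """Observed risk 1 - S(t) by right-continuous lookup."""
    return curve.risk_at(t)


def aalen_johansen(times, event_codes) -> tuple[dict[int, CIFCurve], SurvivalCurve]:
    """Per-cause cumulative incidence plus all-cause survivor curve."""
    est = AalenJohansenEstimator().fit(times, event_codes)
    return est.cif_, est.overall_survival_


def fit_cox_single_covariate(times, events, x, tol: float = 1e-8, max_iter: int = 50) -> CoxFit:
    """Breslow-ties Newton-Raphson fit of a one-covariate Cox model."""
    return UnivariateCoxPH(tol=tol, max_iter=max_iter).fit(times, events, x).fit_
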