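"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (explicit pair loops, direct
log-likelihood evaluation, grid maximization) and shares no code with the
package implementation it checks.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def concordance_bruteforce(times, events, predictions):
    """All-pairs Harrell's C: (concordant + 0.5*tied) / comparable.

    A pair is comparable when the shorter follow-up ended in an event; at a
    tied time an event/censored pair counts the event as earlier and two
    events are not comparable.
    """
    t = list(map(float, times))
    e = list(map(int, events))
    p = list(map(float, predictions))
    n = len(t)
    num = 0.0
    den = 0
    for i in range(n):
        for j in range(i + 1, n):
            if t[i] == t[j]:
                if e[i] + e[j] != 1:
                    continue
                case, other = (i, j) if e[i] == 1 else (j, i)
            elif t[i] < t[j]:
                if e[i] != 1:
                    continue
                case, other = i, j
            else:
                if e[j] != 1:
                    continue
                case, other = j, i
            den += 1
            if p[case] > p[other]:
                num += 1.0
            elif p[case] == p[other]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den, den


def concordance_bruteforce_competing(times, event_codes, predictions):
    """Competing-event subjects recoded as event-free beyond all times."""
    t = [float(x) for x in times]
    codes = [int(c) for c in event_codes]
    far = max(t) + 1.0
    t2 = [far if c == 2 else ti for ti, c in zip(t, codes)]
    e2 = [1 if c == 1 else 0 for c in codes]
    return concordance_bruteforce(t2, e2, predictions)


def cox_log_partial_likelihood(beta, times, events, x):
    """Direct Breslow-ties log partial likelihood."""
    t = list(map(float, times))
    e = list(map(int, events))
    xs = list(map(float, x))
    ll = 0.0
    for u in sorted({ti for ti, ei in zip(t, e) if ei == 1}):
        risk = [math.exp(beta * xi) for ti, xi in zip(t, xs) if ti >= u]
        d = [xi for ti, ei, xi in zip(t, e, xs) if ti == u and ei == 1]
        ll += beta * sum(d) - len(d) * math.log(sum(risk))
    return ll


def cox_grid_oracle(times, events, x, lo=-8.0, hi=8.0):
    """1-d maximization of the partial likelihood: coarse grid then bounded
    scalar refinement. Returns the maximizing beta."""
    grid = np.linspace(lo, hi, 2001)
    vals = [cox_log_partial_likelihood(b, times, events, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda b: -cox_log_partial_likelihood(b, times, events, x),
        bounds=(max(lo, b0 - 0.05), min(hi, b0 + 0.05)),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)


def km_survival_bruteforce(times, events, t_query):
    """Product-limit by direct enumeration of distinct event times."""
    t = list(map(float, times))
    e = list(map(int, events))
    s = 1.0
    for u in sorted({ti for ti, ei in zip(t, e) if ei == 1}):
        if u > t_query:
            break
        at_risk = sum(1 for ti in t if ti >= u)
        d = sum(1 for ti, ei in zip(t, e) if ti == u and ei == 1)
        s *= 1 - d / at_risk
    return s


def random_competing_instance(rng, n, p_censor=0.3, p_competing=0.2, tie_prob=0.5):
    """A small survival instance with ties in times and predictions."""
    if rng.uniform() < tie_prob:
        times = rng.integers(1, max(3, n // 4), size=n).astype(float)
        preds = rng.integers(0, max(3, n // 5), size=n).astype(float)
    else:
        times = rng.uniform(0.1, 10.0, size=n)
        preds = rng.normal(size=n)
    u = rng.uniform(size=n)
    codes = np.where(u < p_censor, 0, np.where(u < p_censor + p_competing, 2, 1))
    if (codes == 1).sum() == 0:
        codes[int(rng.integers(0, n))] = 1
    return times, codes.astype(int), preds
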