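"""Independent oracles used by the test suite.

Deliberately naive implementations (enumeration, hand formulas, grid
search) kept separate from the package so tests compare two routes.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import optimize


def hypergeom_upper_tail(k: int, universe: int, set_size: int, selected: int) -> float:
    """P[X >= k] for X ~ Hypergeom by direct enumeration of the support."""
    total = math.comb(universe, selected)
    p = 0.0
    for j in range(k, min(set_size, selected) + 1):
        if selected - j > universe - set_size:
            continue
        p += math.comb(set_size, j) * math.comb(universe - set_size, selected - j) / total
    return p


def cox_log_partial_likelihood(beta: float, time, event, x) -> float:
    """Breslow log partial likelihood for a single covariate (== Efron
    without ties)."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(event == 1)[0]:
        risk = time >= time[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll


def cox_grid_mle(time, event, x, bounds=(-5.0, 5.0)) -> float:
    """Grid search + golden-section refinement of the partial likelihood."""
    grid = np.linspace(*bounds, 401)
    vals = [cox_log_partial_likelihood(b, time, event, x) for b in grid]
    b0 = grid[int(np.argmax(vals))]
    res = optimize.minimize_scalar(
        lambda b: -cox_log_partial_likelihood(b, time, event, x),
        bounds=(b0 - 0.1, b0 + 0.1),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def cox_score_test_stat(time, event, x) -> float:
    """Cox score test of beta = 0: U(0)^2 / V(0), closed form, no ties."""
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    x = np.asarray(x, float)
    u = v = 0.0
    for i in np.where(event == 1)[0]:
        risk = x[time >= time[i]]
        m = risk.mean()
        u += x[i] - m
        v += np.mean(risk**2) - m**2
    return u**2 / v


def logrank_two_group(t1, e1, t2, e2) -> float:
    """Two-group log-rank chi-square by the hand O-E formula."""
    t1, e1 = np.asarray(t1, float), np.asarray(e1, int)
    t2, e2 = np.asarray(t2, float), np.asarray(e2, int)
    times = np.unique(np.concatenate([t1[e1 == 1], t2[e2 == 1]]))
    o_minus_e = var = 0.0
    for t in times:
        n1 = (t1 >= t).sum()
        n2 = (t2 >= t).sum()
        d1 = ((t1 == t) & (e1 == 1)).sum()
        d2 = ((t2 == t) & (e2 == 1)).sum()
        n, d = n1 + n2, d1 + d2
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    return float(o_minus_e**2 / var)


def km_by_hand(times, events):
    """Product-limit estimate as explicit running products."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    out = {}
    s = 1.0
    for t in np.unique(times[events == 1]):
        at_risk = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1 - d / at_risk
        out[float(t)] = s
    return out


def chi_square_by_hand(table: np.ndarray) -> float:
    """Pearson chi-square via sum (O-E)^2 / E."""
    table = np.asarray(table, float)
    rows = table.sum(axis=1, keepdims=True)
    cols = table.sum(axis=0, keepdims=True)
    expected = rows * cols / table.sum()
    return float(((table - expected) ** 2 / expected).sum())
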