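"""Independent brute-force oracles used only by the tests.

Each oracle re-derives a statistic from its definition (pair enumeration,
product-limit recursion, grid search over a hand-coded partial likelihood) so
the implementation under test is checked against something that shares none of
its code path.
"""

from itertools import combinations

import numpy as np
from scipy import optimize


def brute_force_concordance(time, event, risk):
    """Harrell's C by enumerating every pair.

    A pair is comparable iff the strictly earlier time is an event; the
    higher-risk member failing first scores 1, a risk tie scores 0.5.
    Returns (concordant_weight, comparable_pairs).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    risk = np.asarray(risk, dtype=float)
    concordant = 0.0
    comparable = 0
    for i, j in combinations(range(len(time)), 2):
        if time[i] == time[j]:
            continue
        a, b = (i, j) if time[i] < time[j] else (j, i)
        if event[a] != 1:
            continue
        comparable += 1
        if risk[a] > risk[b]:
            concordant += 1.0
        elif risk[a] == risk[b]:
            concordant += 0.5
    return concordant, comparable


def product_limit_risk(time, event, t):
    """Kaplan-Meier event risk by time t via the product-limit recursion.

    The risk set at an event time u is {j : time_j >= u}, so censorings at u
    leave the risk set only after u and events at u are included in 1 - S(t).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    survival = 1.0
    for u in sorted(set(time[event == 1])):
        if u > t:
            break
        at_risk = int(np.sum(time >= u))
        deaths = int(np.sum((time == u) & (event == 1)))
        survival *= 1.0 - deaths / at_risk
    return 1.0 - survival


def breslow_partial_loglik(beta, time, event, x):
    """Hand-coded Cox partial log-likelihood for one covariate, Breslow ties:
    each event contributes beta*x_i - log(sum over the risk set of exp(beta*x))."""
    time = np.asarray(time, dtype=float)
    x = np.asarray(x, dtype=float)
    ll = 0.0
    for i in np.flatnonzero(np.asarray(event) == 1):
        risk_set = x[time >= time[i]]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk_set)))
    return ll


def grid_search_cox_beta(time, event, x, lo=-5.0, hi=5.0, n_grid=2001):
    """Maximiser of the hand-coded partial likelihood: dense grid then a
    bounded scalar refinement around the best grid point."""
    grid = np.linspace(lo, hi, n_grid)
    lls = np.array([breslow_partial_loglik(b, time, event, x) for b in grid])
    best = grid[int(np.argmax(lls))]
    step = grid[1] - grid[0]
    res = optimize.minimize_scalar(
        lambda b: -breslow_partial_loglik(b, time, event, x),
        bounds=(best - step, best + step),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)
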