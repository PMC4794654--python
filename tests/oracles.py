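"""Independent oracles used by the test suite.

Each oracle is a direct, from-first-principles computation (normal
equations, explicit Mantel-Cox sums, product-limit enumeration, 1-D
partial-likelihood optimisation) kept deliberately separate from the code
paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize, stats


def ols_oracle(y, x, covariates=None):
    """Normal-equations OLS: coefficient of x, its SE and t-based p-value."""
    y = np.asarray(y, dtype=float)
    columns = [np.ones_like(y), np.asarray(x, dtype=float)]
    if covariates is not None:
        for col in np.atleast_2d(np.asarray(covariates, dtype=float).T):
            columns.append(col)
    X = np.column_stack(columns)
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    residuals = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = residuals @ residuals / df
    se = np.sqrt(sigma2 * np.diag(XtX_inv))
    t = beta[1] / se[1]
    p = 2.0 * stats.t.sf(abs(t), df)
    return beta[1], se[1], p


def hwe_oracle(n0, n1, n2):
    """Expected-count chi-square for Hardy-Weinberg proportions."""
    n = n0 + n1 + n2
    p = (2 * n0 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or p == 1.0:
        return 0.0, 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return chi2, float(stats.chi2.sf(chi2, 1))


def mantel_cox_oracle(times, events, groups):
    """Two-group Mantel-Cox log-rank chi-square by explicit O-E/V sums."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    assert labels.size == 2
    o_minus_e = 0.0
    variance = 0.0
    for t in np.unique(times[events == 1]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == labels[0])).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == labels[0])).sum()
        expected = d * n1 / n
        o_minus_e += d1 - expected
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    chi2 = o_minus_e ** 2 / variance
    return chi2, o_minus_e, variance


def cox_partial_loglik(beta, times, events, x):
    """Breslow-free partial log-likelihood for untied event times."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    x = np.asarray(x, dtype=float)
    loglik = 0.0
    for t in times[events == 1]:
        at_risk = times >= t
        i = np.flatnonzero((times == t) & (events == 1))
        assert i.size == 1, "oracle assumes no ties"
        loglik += beta * x[i[0]] - np.log(np.exp(beta * x[at_risk]).sum())
    return loglik


def cox_oracle(times, events, x, bracket=(-10.0, 10.0)):
    """1-D maximiser of the partial likelihood (coarse grid + refinement)."""
    grid = np.linspace(*bracket, 2001)
    values = [cox_partial_loglik(b, times, events, x) for b in grid]
    best = grid[int(np.argmax(values))]
    result = optimize.minimize_scalar(
        lambda b: -cox_partial_loglik(b, times, events, x),
        bounds=(best - 0.5, best + 0.5), method="bounded",
        options={"xatol": 1e-10},
    )
    return float(result.x)


def km_oracle(times, events):
    """Product-limit survival estimate at each distinct event time."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    survival = {}
    s = 1.0
    for t in np.unique(times[events == 1]):
        n = (times >= t).sum()
        d = ((times == t) & (events == 1)).sum()
        s *= 1.0 - d / n
        survival[float(t)] = s
    return survival
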