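"""Independent brute-force oracles used only by the tests.

These implement the statistical definitions directly (pair enumeration,
Efron partial likelihood + generic numeric optimizer, hypergeometric
log-rank, step-up FDR, product-limit estimator) without touching the
package's code paths, so agreement is a genuine cross-check.
"""

from __future__ import annotations

import numpy as np
from scipy import optimize


def efron_loglik(beta, X, durations, events) -> float:
    """Efron-approximated Cox log partial likelihood, computed directly."""
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(durations):
        X = X.T
    eta = X @ beta
    theta = np.exp(eta)
    T = np.asarray(durations, dtype=float)
    E = np.asarray(events, dtype=bool)
    ll = 0.0
    for t in np.unique(T[E]):
        deaths = E & (T == t)
        at_risk = T >= t
        d = int(deaths.sum())
        sum_risk = theta[at_risk].sum()
        sum_dead = theta[deaths].sum()
        ll += eta[deaths].sum()
        for l in range(d):
            ll -= np.log(sum_risk - (l / d) * sum_dead)
    return float(ll)


def maximize_efron(X, durations, events, penalizer: float = 0.0) -> np.ndarray:
    """Numerically maximize the (optionally L2-penalized) Efron likelihood.

    The penalty matches the convention of total log-likelihood minus
    n * penalizer * ||beta||^2 / 2.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(durations):
        X = X.T
    n, p = X.shape

    def neg(beta):
        return -(efron_loglik(beta, X, durations, events)
                 - 0.5 * n * penalizer * np.sum(np.asarray(beta) ** 2))

    res = optimize.minimize(neg, np.zeros(p), method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    res = optimize.minimize(neg, res.x, method="Nelder-Mead",
                            options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 20000})
    return np.atleast_1d(res.x)


def harrell_c_pairs(scores, durations, events) -> float:
    """Harrell's c by exhaustive enumeration of comparable pairs.

    The patient with the shorter survival should have the lower score
    (negative-log-partial-hazard convention); tied scores score 0.5.
    """
    s = np.asarray(scores, dtype=float)
    T = np.asarray(durations, dtype=float)
    E = np.asarray(events, dtype=bool)
    num = den = 0.0
    n = len(s)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            # pair usable iff the earlier time is an event and times differ
            if not (E[i] and T[i] < T[j]):
                continue
            den += 1
            if s[i] < s[j]:
                num += 1
            elif s[i] == s[j]:
                num += 0.5
    if den == 0:
        raise ValueError("no comparable pairs")
    return num / den


def bh_stepup(p_values, q) -> np.ndarray:
    """Benjamini-Hochberg step-up by its closed-form definition."""
    p = np.asarray(p_values, dtype=float)
    m = len(p)
    if m == 0:
        return np.zeros(0, dtype=bool)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]
    thresholds = q * (np.arange(1, m + 1)) / m
    below = np.nonzero(sorted_p <= thresholds)[0]
    reject = np.zeros(m, dtype=bool)
    if len(below):
        k = below.max()
        reject[order[: k + 1]] = True
    return reject


def logrank_two_group(durations, events, groups) -> float:
    """Two-group log-rank chi-square from per-event-time 2x2 tables."""
    T = np.asarray(durations, dtype=float)
    E = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    assert len(labels) == 2
    is0 = g == labels[0]
    obs_minus_exp = 0.0
    var = 0.0
    for t in np.unique(T[E]):
        at_risk = T >= t
        n = at_risk.sum()
        n0 = (at_risk & is0).sum()
        d = (E & (T == t)).sum()
        d0 = (E & (T == t) & is0).sum()
        obs_minus_exp += d0 - d * n0 / n
        if n > 1:
            var += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return float(obs_minus_exp**2 / var)


def km_product_limit(durations, events):
    """Product-limit estimate: (times, survival) including t=0."""
    T = np.asarray(durations, dtype=float)
    E = np.asarray(events, dtype=bool)
    times = [0.0]
    surv = [1.0]
    s = 1.0
    for t in np.unique(T[E]):
        n = (T >= t).sum()
        d = (E & (T == t)).sum()
        s *= 1 - d / n
        times.append(float(t))
        surv.append(float(s))
    return np.array(times), np.array(surv)


def ellipse_axes_from_moments(mask) -> tuple[float, float]:
    """Major/minor axis lengths of the ellipse with equal second moments,
    computed directly from pixel central moments."""
    ys, xs = np.nonzero(mask)
    n = len(xs)
    x0, y0 = xs.mean(), ys.mean()
    # pixel-center convention with unit pixel inertia correction as in
    # image-moment ellipse fitting: mu'_ij over pixel coordinates
    mu20 = ((xs - x0) ** 2).sum() / n
    mu02 = ((ys - y0) ** 2).sum() / n
    mu11 = ((xs - x0) * (ys - y0)).sum() / n
    common = np.sqrt((mu20 - mu02) ** 2 + 4 * mu11**2)
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    return 4 * np.sqrt(lam1), 4 * np.sqrt(lam2)
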