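"""Survival-model evaluation: concordance, resampling inference, KM risk
groups, cross-modal concordance, and ordinal response association.

Risk scores throughout follow the negative-log-partial-hazard convention:
higher score = predicted longer survival, so an informative model has
Harrell's c > 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from scipy import stats

#: the percentile grid searched for KM risk-group thresholds
DEFAULT_THRESHOLD_GRID = tuple(np.round(np.arange(0.33, 0.661, 0.01), 2))


@dataclass
class EvaluationReport:
    """Concordance of one model on one patient set."""

    c_index: float
    ci_low: float
    ci_high: float
    permutation_p: float
    n_patients: int
    n_events: int

    def as_dict(self) -> dict:
        return {
            "c_index": float(self.c_index),
            "ci_low": float(self.ci_low),
            "ci_high": float(self.ci_high),
            "permutation_p": float(self.permutation_p),
            "n_patients": int(self.n_patients),
            "n_events": int(self.n_events),
        }


@dataclass
class RiskGroups:
    """A frozen risk-score threshold and the resulting group labels."""

    percentile: float
    score_cut: float
    groups: pd.Series  # id -> "high" | "low"
    logrank_p: float
    endpoint: str = "OS"

    def apply(self, scores: pd.Series) -> pd.Series:
        """Label new patients with the frozen score cut (no re-search)."""
        return pd.Series(
            np.where(scores.to_numpy() <= self.score_cut, "high", "low"),
            index=scores.index,
        )


@dataclass
class SurvivalCurve:
    """A Kaplan-Meier product-limit estimate as a step function."""

    times: np.ndarray  # increasing, starting at 0
    survival: np.ndarray  # S(t) at each time, S(0) = 1, non-increasing
    at_risk: np.ndarray


def _as_arrays(risks, durations, events):
    r = np.asarray(risks, dtype=float)
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if not (len(r) == len(d) == len(e)):
        raise ValueError("risks, durations and events must have equal length")
    return r, d, e


def harrell_c(risks, durations, events) -> float:
    """Harrell's concordance index.

    Over comparable pairs (usable under right censoring), a pair is
    concordant when the patient who failed earlier has the lower score;
    tied scores count 0.5.  Raises when no pair is comparable.
    """
    r, d, e = _as_arrays(risks, durations, events)
    if not e.any():
        raise ValueError("no events; no comparable pairs")
    try:
        return float(concordance_index(d, r, e))
    except ZeroDivisionError as err:
        raise ValueError("no comparable pairs") from err


def bootstrap_ci(
    risks,
    durations,
    events,
    n_reps: int = 100,
    seed: int = 0,
    method: str = "bootstrap",
) -> tuple[float, float]:
    """95% CI for the c-index by patient resampling.

    ``method="bootstrap"`` (default): ``n_reps`` resamples with replacement,
    percentile 2.5/97.5 interval.  ``method="jackknife"``: leave-one-out
    pseudo-value interval.  Resamples with no comparable pairs are redrawn.
    """
    r, d, e = _as_arrays(risks, durations, events)
    n = len(r)
    if method == "jackknife":
        cs = []
        for i in range(n):
            keep = np.arange(n) != i
            try:
                cs.append(harrell_c(r[keep], d[keep], e[keep]))
            except ValueError:
                continue
        lo, hi = np.percentile(cs, [2.5, 97.5])
        return float(lo), float(hi)
    if method != "bootstrap":
        raise ValueError("method must be 'bootstrap' or 'jackknife'")
    rng = np.random.default_rng(seed)
    cs = []
    attempts = 0
    while len(cs) < n_reps:
        idx = rng.integers(0, n, size=n)
        attempts += 1
        if attempts > 20 * n_reps:
            raise RuntimeError("could not draw resamples with comparable pairs")
        try:
            cs.append(harrell_c(r[idx], d[idx], e[idx]))
        except ValueError:
            continue  # redraw
    lo, hi = np.percentile(cs, [2.5, 97.5])
    return float(lo), float(hi)


def permutation_test(
    risks, durations, events, n_perm: int = 1000, seed: int = 0
) -> float:
    """One-sided permutation p for the observed c-index.

    Risk scores are permuted against fixed outcomes;
    p = (1 + #{c_perm >= c_obs}) / (n_perm + 1), so p is never 0 and the
    significance claim is conservative.
    """
    r, d, e = _as_arrays(risks, durations, events)
    c_obs = harrell_c(r, d, e)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if harrell_c(rng.permutation(r), d, e) >= c_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def evaluate(
    risks, durations, events, n_bootstrap: int = 100, n_perm: int = 1000, seed: int = 0
) -> EvaluationReport:
    """c-index with bootstrap 95% CI and permutation p, in one report."""
    r, d, e = _as_arrays(risks, durations, events)
    return EvaluationReport(
        c_index=harrell_c(r, d, e),
        ci_low=bootstrap_ci(r, d, e, n_reps=n_bootstrap, seed=seed)[0],
        ci_high=bootstrap_ci(r, d, e, n_reps=n_bootstrap, seed=seed)[1],
        permutation_p=permutation_test(r, d, e, n_perm=n_perm, seed=seed),
        n_patients=len(r),
        n_events=int(e.sum()),
    )


# -- Kaplan-Meier ----------------------------------------------------------

def km_curve(durations, events) -> SurvivalCurve:
    """Product-limit survival estimate."""
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(d) == 0:
        raise ValueError("need at least one record")
    kmf = KaplanMeierFitter().fit(d, e)
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy(dtype=float)
    # lifelines includes t=0 with S=1 as the first row
    at_risk = np.array([int((d >= t).sum()) for t in times])
    return SurvivalCurve(times=times, survival=surv, at_risk=at_risk)


def survival_at(curve: SurvivalCurve, t: float) -> float:
    """Fraction surviving at ``t``, linearly interpolated between KM steps."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return float(np.interp(t, curve.times, curve.survival))


def median_survival(curve: SurvivalCurve) -> float:
    """First time the interpolated survival reaches 0.5 (NaN if never)."""
    s = curve.survival
    if s[-1] > 0.5:
        return float("nan")
    idx = int(np.argmax(s <= 0.5))
    if idx == 0:
        return float(curve.times[0])
    t0, t1 = curve.times[idx - 1], curve.times[idx]
    s0, s1 = s[idx - 1], s[idx]
    if s0 == s1:
        return float(t1)
    return float(t0 + (s0 - 0.5) * (t1 - t0) / (s0 - s1))


def logrank(durations, events, groups) -> tuple[float, float]:
    """Multivariate log-rank test across ≥2 nonempty groups.

    Returns (chi-square statistic with k-1 df, p-value).  Raises when fewer
    than two groups are present or no events occur at all.
    """
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) < 2:
        raise ValueError("need at least two nonempty groups")
    if not e.any():
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(d, g, e)
    return float(res.test_statistic), float(res.p_value)


def threshold_search(
    risks: pd.Series,
    durations,
    events,
    grid: Sequence[float] = DEFAULT_THRESHOLD_GRID,
    endpoint: str = "OS",
) -> RiskGroups:
    """Search percentile thresholds for the most significant KM separation.

    For each percentile in ``grid`` the training scores are cut at that
    quantile (scores at or below the cut = high risk, since low score =
    high hazard), and the two-group log-rank p is computed; the percentile
    with minimal p wins.  Ties break to the threshold nearest 0.5, then the
    lower one.  Degenerate splits are skipped.  The winning cut is frozen
    as a raw score value to be applied unchanged to test data.
    """
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    r = risks.to_numpy(dtype=float)
    d = np.asarray(durations, dtype=float)
    e = np.asarray(events, dtype=bool)
    best = None
    for q in grid:
        cut = float(np.quantile(r, q))
        high = r <= cut
        if high.all() or not high.any():
            continue
        try:
            _, p = logrank(d, e, np.where(high, "high", "low"))
        except ValueError:
            continue
        key = (p, abs(q - 0.5), q)
        if best is None or key < best[0]:
            best = (key, q, cut, p)
    if best is None:
        raise ValueError("every threshold in the grid gave a degenerate split")
    _, q, cut, p = best
    groups = pd.Series(
        np.where(r <= cut, "high", "low"), index=risks.index, name="risk_group"
    )
    return RiskGroups(
        percentile=float(q), score_cut=cut, groups=groups, logrank_p=p, endpoint=endpoint
    )


# -- cross-modal and ordinal associations ---------------------------------

def kendall_cross_modal(
    score_table: pd.DataFrame, modality_pair: tuple[str, str]
) -> float:
    """Kendall tau-b between two modalities' risk quantiles.

    Each modality's scores are converted to quantiles within its own
    available set; tau-b is computed over patients with both scores.
    """
    a, b = modality_pair
    qa = score_table[a].rank(pct=True)
    qb = score_table[b].rank(pct=True)
    both = qa.notna() & qb.notna()
    if both.sum() < 2:
        raise ValueError("need at least 2 patients with both modality scores")
    tau, _ = stats.kendalltau(qa[both], qb[both])
    return float(tau)


def kendall_matrix(score_table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise tau-b matrix across all modality columns."""
    mods = list(score_table.columns)
    out = pd.DataFrame(np.eye(len(mods)), index=mods, columns=mods)
    for i, a in enumerate(mods):
        for j in range(i + 1, len(mods)):
            b = mods[j]
            try:
                tau = kendall_cross_modal(score_table, (a, b))
            except ValueError:
                tau = float("nan")
            out.loc[a, b] = out.loc[b, a] = tau
    return out


def crs_association(
    scores: pd.Series,
    crs: pd.Series,
    direction: str = "greater",
    high_level: int = 3,
) -> float:
    """One-sided Mann-Whitney U test of fused score vs CRS stratum.

    Strata are CRS ≥ ``high_level`` (good responders) vs below.  With
    ``direction="greater"`` the alternative is that good responders have
    greater scores (higher score = lower predicted hazard).  The exact null
    distribution is enumerated when the combined n ≤ 20 and there are no
    tied scores; otherwise the normal approximation with tie correction is
    used.
    """
    mask = crs.notna() & scores.notna()
    s = scores[mask]
    c = crs[mask]
    hi = s[c >= high_level].to_numpy(dtype=float)
    lo = s[c < high_level].to_numpy(dtype=float)
    if len(hi) == 0 or len(lo) == 0:
        raise ValueError("both CRS strata must be nonempty")
    n = len(hi) + len(lo)
    ties = len(np.unique(np.concatenate([hi, lo]))) < n
    method = "exact" if (n <= 20 and not ties) else "asymptotic"
    res = stats.mannwhitneyu(hi, lo, alternative=direction, method=method)
    return float(res.pvalue)
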