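"""Thin wrapper around lifelines' Cox proportional-hazards fitter.

All Cox fits in the package go through here so that tie handling (Efron),
the convergence fallback ladder, and warning suppression are uniform.
The L2 penalty follows lifelines' convention: the maximized objective is
the total Efron log partial likelihood minus ``n * penalizer * ||beta||^2 / 2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError


@dataclass
class CoxFit:
    """Result of one Cox fit: coefficient table plus convergence status."""

    params: pd.Series  # log hazard ratios per covariate
    p_values: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    status: str  # "ok" | "regularized" | "failed-defaulted"
    penalizer: float


def _fit_once(df: pd.DataFrame, penalizer: float) -> CoxPHFitter:
    cph = CoxPHFitter(penalizer=penalizer, l1_ratio=0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        # tight Newton tolerance: coefficients at the partial-likelihood
        # optimum to well below 1e-6 (the default stopping rule leaves
        # visible gaps along flat likelihood ridges)
        cph.fit(
            df,
            duration_col="duration",
            event_col="event",
            fit_options={"precision": 1e-13},
        )
    if not np.all(np.isfinite(cph.params_.to_numpy())):
        raise ConvergenceError("non-finite coefficients")
    return cph


def fit_cox_ladder(
    df: pd.DataFrame,
    fallback_l2: float = 0.2,
    penalizer: float = 0.0,
    allow_fallback: bool = True,
) -> CoxFit:
    """Fit a Cox model with the convergence fallback ladder.

    Fit with the requested ``penalizer`` (default unregularized); if the
    optimizer fails, refit with L2 strength ``fallback_l2``; if that also
    fails, return a defaulted result with log(HR) 0 and p-value 1 for every
    covariate.  With ``allow_fallback=False`` a first-stage failure defaults
    immediately (used where a regularized rescue would be misleading, e.g.
    collinear multivariable fits).  ``df`` must contain ``duration`` and
    ``event`` columns; all other columns are covariates.
    """
    covariates = [c for c in df.columns if c not in ("duration", "event")]
    if df["event"].sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    ladder = ((penalizer, "ok"), (fallback_l2, "regularized"))
    if not allow_fallback:
        ladder = ladder[:1]
    for pen, status in ladder:
        try:
            cph = _fit_once(df, pen)
        except Exception:
            continue
        summ = cph.summary
        return CoxFit(
            params=cph.params_.copy(),
            p_values=summ["p"].copy(),
            ci_low=summ["coef lower 95%"].copy(),
            ci_high=summ["coef upper 95%"].copy(),
            status=status,
            penalizer=pen,
        )
    zeros = pd.Series(0.0, index=covariates)
    ones = pd.Series(1.0, index=covariates)
    return CoxFit(
        params=zeros, p_values=ones, ci_low=zeros.copy(), ci_high=zeros.copy(),
        status="failed-defaulted", penalizer=fallback_l2,
    )


def fit_cox_strict(df: pd.DataFrame, penalizer: float) -> CoxPHFitter:
    """Fit a final (penalized) Cox model; nonconvergence raises.

    Used for the production submodels, which must never silently default.
    """
    if df["event"].sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    try:
        return _fit_once(df, penalizer)
    except Exception as err:  # re-raise with diagnostics
        raise ConvergenceError(
            f"Cox model failed to converge (penalizer={penalizer}, "
            f"n={len(df)}, events={int(df['event'].sum())}, "
            f"covariates={[c for c in df.columns if c not in ('duration', 'event')]}): {err}"
        ) from err


def make_survival_frame(
    X: pd.DataFrame | pd.Series | np.ndarray,
    durations: np.ndarray | pd.Series,
    events: np.ndarray | pd.Series,
    control: Optional[pd.Series] = None,
) -> pd.DataFrame:
    """Assemble the (covariates, duration, event) frame lifelines expects."""
    if isinstance(X, pd.Series):
        X = X.to_frame()
    elif isinstance(X, np.ndarray):
        X = pd.DataFrame(np.atleast_2d(X.T).T)
        X.columns = [f"x{i}" for i in range(X.shape[1])]
    df = X.reset_index(drop=True).copy()
    dur = np.asarray(durations, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if len(dur) != len(df) or len(ev) != len(df):
        raise ValueError("durations/events length does not match covariates")
    if control is not None:
        df[control.name or "control"] = np.asarray(control, dtype=float)
    df["duration"] = dur
    df["event"] = ev
    return df
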