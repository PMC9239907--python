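"""Per-modality prognostic feature selection.

The cascade, applied to the training split of one modality:

1. **Scaled-IQR filter** — each feature is min–max scaled to [0, 1] on the
   training values and features whose scaled interquartile range falls below
   a threshold (default 0.1) are removed as near-constant.
2. **Univariate Cox** — one proportional-hazards model per feature, fitted
   without regularization; on convergence failure the fit is re-attempted
   with L2 strength 0.2, and a model that still fails is assigned log(HR) 0
   and p-value 1.  For histopathology a specimen-size covariate may be
   included in every model to control for relative specimen size.
3. **Benjamini–Hochberg** — FDR step-up correction of the univariate
   p-values, applied only where configured (radiomics, the largest feature
   space).
4. **Greedy multivariable pruning** — candidates significant at level alpha,
   ordered by p-value, are added one at a time to a growing multivariable
   Cox model and kept only if the newly added covariate is significant,
   yielding a signature with low multicollinearity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .coxfit import fit_cox_ladder, make_survival_frame

MIN_EVENTS = 10  # modalities with fewer events refuse to fit


@dataclass
class SelectionConfig:
    """Knobs of the selection cascade for one modality."""

    iqr_threshold: float = 0.1
    alpha: float = 0.05
    fallback_l2: float = 0.2
    apply_bh: bool = False
    control_covariate: Optional[str] = None

    def __post_init__(self) -> None:
        if not 0 < self.iqr_threshold < 1:
            raise ValueError("iqr_threshold must lie in (0, 1)")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass(frozen=True)
class UnivariateResult:
    """One univariate (or size-controlled bivariate) Cox fit."""

    feature: str
    log_hr: float
    ci_low: float
    ci_high: float
    p: float
    status: str  # "ok" | "regularized" | "failed-defaulted"


@dataclass
class SelectedSignature:
    """Ordered surviving features with their multivariable statistics."""

    features: list[str]
    details: pd.DataFrame  # index feature; columns log_hr, p (at acceptance)
    audit: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.features)


# -- stage 1: scaled-IQR filter -------------------------------------------

def scaled_iqr(values: np.ndarray) -> float:
    """IQR of the min–max scaled values (0 for a constant feature)."""
    values = np.asarray(values, dtype=float)
    lo, hi = np.min(values), np.max(values)
    if hi == lo:
        return 0.0
    scaled = (values - lo) / (hi - lo)
    q1, q3 = np.percentile(scaled, [25, 75])  # linear-interpolation quantiles
    return float(q3 - q1)


def scaled_iqr_filter(
    matrix: pd.DataFrame, threshold: float = 0.1
) -> tuple[pd.DataFrame, dict[str, tuple[float, float]]]:
    """Drop near-constant features; return (filtered matrix, scaling params).

    The recorded per-feature (min, max) allows identical scaling of test
    data.  Constant features have scaled IQR defined as 0 and are dropped.
    """
    keep: list[str] = []
    scaling: dict[str, tuple[float, float]] = {}
    for name in matrix.columns:
        vals = matrix[name].to_numpy(dtype=float)
        if scaled_iqr(vals) >= threshold:
            keep.append(name)
            scaling[name] = (float(np.min(vals)), float(np.max(vals)))
    return matrix[keep], scaling


# -- stage 2: univariate Cox with fallback ladder -------------------------

def univariate_cox(
    values: pd.Series | np.ndarray,
    durations,
    events,
    control: Optional[pd.Series] = None,
    config: Optional[SelectionConfig] = None,
) -> UnivariateResult:
    """Univariate Cox fit of one feature, with the fallback ladder.

    When ``control`` is given the model is bivariate and the reported
    statistics are the feature's.  A zero-variance feature cannot inform the
    partial likelihood and is returned as failed-defaulted (log(HR) 0, p 1).
    """
    config = config or SelectionConfig()
    name = values.name if isinstance(values, pd.Series) else "feature"
    name = str(name)
    arr = np.asarray(values, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if len(arr) != len(np.asarray(durations)):
        raise ValueError("feature and durations lengths differ")
    if ev.sum() < 2:
        raise ValueError("need at least 2 events")
    if np.ptp(arr) == 0:
        return UnivariateResult(name, 0.0, 0.0, 0.0, 1.0, "failed-defaulted")
    df = make_survival_frame(pd.Series(arr, name=name), durations, ev, control=control)
    fit = fit_cox_ladder(df, fallback_l2=config.fallback_l2)
    if fit.status == "failed-defaulted":
        return UnivariateResult(name, 0.0, 0.0, 0.0, 1.0, "failed-defaulted")
    return UnivariateResult(
        name,
        float(fit.params[name]),
        float(fit.ci_low[name]),
        float(fit.ci_high[name]),
        float(fit.p_values[name]),
        fit.status,
    )


# -- stage 3: Benjamini-Hochberg ------------------------------------------

def benjamini_hochberg(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """FDR step-up rejection flags at level ``q`` (empty in → empty out)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


# -- stage 4: greedy multivariable pruning --------------------------------

def algorithm1_select(
    candidates: Sequence[str],
    matrix: pd.DataFrame,
    durations,
    events,
    alpha: float = 0.05,
    fallback_l2: float = 0.2,
    control: Optional[pd.Series] = None,
) -> SelectedSignature:
    """Greedy forward pruning of p-ordered candidates by multivariable Cox.

    Each candidate is tentatively appended to the kept set; the multivariable
    model is refitted without regularization and the candidate is kept only
    if its own coefficient is significant at ``alpha`` (the previously kept
    features stay).  A candidate whose unregularized fit fails to converge —
    notably one collinear with the kept set, which cannot improve the
    partial likelihood — is rejected and logged, never rescued by
    regularization.  The result is a signature whose features are mutually
    significant with low multicollinearity.
    """
    if len(set(candidates)) != len(candidates):
        raise ValueError("candidates must be unique")
    kept: list[str] = []
    rejected_failures: list[str] = []
    rows = []
    for cand in candidates:
        cols = kept + [cand]
        df = make_survival_frame(matrix[cols], durations, events, control=control)
        fit = fit_cox_ladder(df, fallback_l2=fallback_l2, allow_fallback=False)
        if fit.status == "failed-defaulted":
            rejected_failures.append(cand)
            continue
        if float(fit.p_values[cand]) < alpha:
            kept.append(cand)
            rows = [
                (f, float(fit.params[f]), float(fit.p_values[f])) for f in kept
            ]
    details = pd.DataFrame(rows, columns=["feature", "log_hr", "p"]).set_index("feature")
    return SelectedSignature(
        features=kept,
        details=details,
        audit={"n_candidates": len(candidates), "fit_failures": rejected_failures},
    )


# -- the full cascade ------------------------------------------------------

def select_modality(
    matrix: pd.DataFrame,
    durations,
    events,
    config: Optional[SelectionConfig] = None,
) -> SelectedSignature:
    """Run the whole cascade on one modality's training matrix.

    Order: scaled-IQR filter → univariate Cox (optionally controlled for a
    specimen-size covariate) → Benjamini–Hochberg where configured →
    candidates significant at 95% confidence ordered by p-value (ties broken
    lexicographically) → greedy multivariable pruning.  An empty signature is
    a valid outcome (the downstream submodel is then skipped).
    """
    config = config or SelectionConfig()
    ev = np.asarray(events, dtype=bool)
    if ev.sum() < MIN_EVENTS:
        raise ValueError(
            f"only {int(ev.sum())} events in training data; "
            f"at least {MIN_EVENTS} required for stable Cox selection"
        )
    control = None
    if config.control_covariate is not None:
        if config.control_covariate not in matrix.columns:
            raise KeyError(f"control covariate {config.control_covariate!r} not in matrix")
        control = matrix[config.control_covariate]
        matrix = matrix.drop(columns=[config.control_covariate])

    n_input = matrix.shape[1]
    filtered, scaling = scaled_iqr_filter(matrix, config.iqr_threshold)

    results = [
        univariate_cox(filtered[name], durations, ev, control=control, config=config)
        for name in filtered.columns
    ]
    p = np.array([r.p for r in results])
    if config.apply_bh:
        significant = benjamini_hochberg(p, q=config.alpha)
    else:
        significant = p < config.alpha
    cand = sorted(
        (r for r, s in zip(results, significant) if s),
        key=lambda r: (r.p, r.feature),
    )
    signature = algorithm1_select(
        [r.feature for r in cand],
        filtered,
        durations,
        ev,
        alpha=config.alpha,
        fallback_l2=config.fallback_l2,
        control=control,
    )
    signature.audit.update(
        {
            "n_input": int(n_input),
            "n_after_iqr": int(filtered.shape[1]),
            "n_candidates": len(cand),
            "n_selected": len(signature.features),
            "bh_applied": bool(config.apply_bh),
            "univariate": {
                r.feature: {"log_hr": r.log_hr, "p": r.p, "status": r.status}
                for r in results
            },
            "scaling": scaling,
        }
    )
    return signature
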