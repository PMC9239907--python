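"""Clinical encoding, final Cox submodels, and risk prediction.

Final per-modality models are linear Cox proportional-hazards fits with a
fixed L2 penalty (c = 0.5) on training-standardized features, using the
Efron approximation for tied event times.  Each submodel predicts a
per-patient risk score defined as the **negative** log partial hazard
(-x'beta), so that higher score = longer expected survival — the sign
convention under which an informative model yields a concordance index
above 0.5.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import RD_STATUSES, STAGES, TREATMENTS
from .coxfit import fit_cox_strict, make_survival_frame

FINAL_L2 = 0.5  # L2 strength of every final unimodal and multimodal model

CLINICAL_FEATURES = (
    ["rd", "parpi", "adnexal", "age_scaled"]
    + [f"stage_{s}" for s in STAGES]
    + [f"treatment_{t}" for t in TREATMENTS]
)


def encode_clinical(
    manifest: pd.DataFrame, age_range: Optional[tuple[float, float]] = None
) -> tuple[pd.DataFrame, tuple[float, float]]:
    """Encode clinical records as a fixed-length numeric matrix.

    Residual-disease status is binary (1 for ≤1 cm including complete gross
    resection, 0 otherwise); PARP-inhibitor receipt and adnexal-lesion
    presence are 0/1; age is scaled by the training-set range and clipped to
    [0, 1] at test time; stage and treatment are one-hot including their
    "unknown" categories, so every record encodes without error.

    Pass the training split first to learn ``age_range``, then reuse it for
    test data.  Returns (matrix, age_range).
    """
    man = manifest
    out = pd.DataFrame(index=man.index)
    rd = man["rd_status"].astype(str)
    if not rd.isin(RD_STATUSES).all():
        bad = sorted(set(rd) - set(RD_STATUSES))
        raise ValueError(f"unknown rd_status values: {bad}")
    out["rd"] = (rd == "le1cm").astype(float)
    out["parpi"] = man["parpi"].astype(bool).astype(float)
    out["adnexal"] = man["adnexal_present"].astype(bool).astype(float)
    age = man["age"].to_numpy(dtype=float)
    if age_range is None:
        age_range = (float(age.min()), float(age.max()))
    lo, hi = age_range
    span = hi - lo if hi > lo else 1.0
    out["age_scaled"] = np.clip((age - lo) / span, 0.0, 1.0)
    stage = man["stage"].astype(str).where(man["stage"].astype(str).isin(STAGES), "unknown")
    for s in STAGES:
        out[f"stage_{s}"] = (stage == s).astype(float)
    treat = man["treatment"].astype(str).where(
        man["treatment"].astype(str).isin(TREATMENTS), "unknown"
    )
    for t in TREATMENTS:
        out[f"treatment_{t}"] = (treat == t).astype(float)
    return out, age_range


@dataclass
class CoxSubmodel:
    """A fitted final Cox model for one modality.

    Coefficients are on the training-standardized feature scale; the stored
    means/stds are applied before prediction so raw feature matrices can be
    scored directly.
    """

    modality: str
    features: list[str]
    coefficients: np.ndarray
    feature_means: np.ndarray
    feature_stds: np.ndarray
    l2: float = FINAL_L2
    ties: str = "efron"
    n_train: int = 0
    p_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.features):
            raise ValueError("coefficient count must equal feature count")

    # -- serialization ----------------------------------------------------
    def to_json(self, path) -> None:
        payload = {
            "modality": self.modality,
            "features": self.features,
            "coefficients": [float(c) for c in self.coefficients],
            "feature_means": [float(m) for m in self.feature_means],
            "feature_stds": [float(s) for s in self.feature_stds],
            "l2": self.l2,
            "ties": self.ties,
            "n_train": self.n_train,
            "p_values": {k: float(v) for k, v in self.p_values.items()},
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CoxSubmodel":
        d = json.loads(Path(path).read_text())
        return cls(
            modality=d["modality"],
            features=list(d["features"]),
            coefficients=np.asarray(d["coefficients"], dtype=float),
            feature_means=np.asarray(d["feature_means"], dtype=float),
            feature_stds=np.asarray(d["feature_stds"], dtype=float),
            l2=d["l2"],
            ties=d["ties"],
            n_train=d["n_train"],
            p_values=d.get("p_values", {}),
        )


def fit_submodel(
    features: Sequence[str],
    matrix: pd.DataFrame,
    durations,
    events,
    modality: str = "model",
    l2: float = FINAL_L2,
) -> CoxSubmodel:
    """Fit the final L2-penalized Cox submodel on a nonempty signature.

    Features are z-scored on the training data so the fixed penalty weight
    is comparable across features; scaling is stored on the model and
    inverted at prediction time.  Nonconvergence raises — a final model must
    never silently default.
    """
    features = list(features)
    if not features:
        raise ValueError("signature is empty; no submodel to fit")
    X = matrix[features].to_numpy(dtype=float)
    means = X.mean(axis=0)
    # ddof=1 so the standardized columns have unit sample std: the L2
    # penalty then acts as n * l2 * ||beta||^2 / 2 exactly on this scale
    stds = X.std(axis=0, ddof=1) if len(X) > 1 else np.ones(X.shape[1])
    stds[stds == 0] = 1.0
    Z = pd.DataFrame((X - means) / stds, columns=features)
    df = make_survival_frame(Z, durations, events)
    cph = fit_cox_strict(df, penalizer=l2)
    return CoxSubmodel(
        modality=modality,
        features=features,
        coefficients=cph.params_.loc[features].to_numpy(dtype=float),
        feature_means=means,
        feature_stds=stds,
        l2=l2,
        n_train=len(df),
        p_values={f: float(cph.summary.loc[f, "p"]) for f in features},
    )


def predict_risk(model: CoxSubmodel, matrix: pd.DataFrame) -> pd.Series:
    """Negative log partial hazards (-x'beta) for every row of ``matrix``.

    Rows with any missing model feature get a missing (NaN) score.  Raises
    if a model feature is absent from the matrix columns.
    """
    missing_cols = [f for f in model.features if f not in matrix.columns]
    if missing_cols:
        raise KeyError(f"matrix lacks model features: {missing_cols}")
    X = matrix[model.features].to_numpy(dtype=float)
    Z = (X - model.feature_means) / model.feature_stds
    scores = -(Z @ model.coefficients)
    scores = np.where(np.isnan(X).any(axis=1), np.nan, scores)
    return pd.Series(scores, index=matrix.index, name=f"{model.modality}_score")
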