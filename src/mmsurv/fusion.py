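"""Late fusion of per-modality risk scores.

Each unimodal submodel is trained on *all* training patients with that
modality available, then a small second-stage Cox model integrates the
per-modality negative log partial hazards, fitted only on the intersection
set (patients with every included modality).  The second stage fits one
coefficient per modality — it benefits from having few parameters — and no
missing scores are imputed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import MultimodalCohort
from .coxfit import fit_cox_strict, make_survival_frame
from .hrd import genomic_risk
from .models import FINAL_L2, CoxSubmodel, predict_risk

MODALITY_TAGS = {"genomic": "G", "radiomic": "R", "histopathology": "H", "clinical": "C"}


@dataclass
class FusionModel:
    """Second-stage Cox model over modality score columns (one coef each)."""

    modalities: list[str]
    coefficients: np.ndarray
    n_intersection: int
    l2: float = FINAL_L2
    p_values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(self.modalities):
            raise ValueError("one coefficient per included modality required")

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "modalities": self.modalities,
                    "coefficients": [float(c) for c in self.coefficients],
                    "n_intersection": self.n_intersection,
                    "l2": self.l2,
                    "p_values": {k: float(v) for k, v in self.p_values.items()},
                },
                indent=2,
                sort_keys=True,
            )
        )


def assemble_submodel_scores(
    cohort: MultimodalCohort,
    submodels: dict[str, CoxSubmodel],
    clinical_matrix: Optional[pd.DataFrame] = None,
    include_genomic: bool = True,
) -> pd.DataFrame:
    """Per-patient score table (id × modality) with missingness preserved.

    Imaging/clinical columns hold each submodel's negative log partial
    hazard for patients with that modality; the genomic column is the
    rule-based risk (HRP → 1.0, HRD → 0.0, ambiguous → missing).  No model
    parameters are fitted for the genomic modality.
    """
    table = pd.DataFrame(index=cohort.patient_ids)
    for mod, model in submodels.items():
        if mod == "clinical":
            if clinical_matrix is None:
                raise ValueError("clinical submodel given but no clinical matrix")
            matrix = clinical_matrix
        else:
            matrix = cohort.features[mod]
        scores = predict_risk(model, matrix)
        table[mod] = scores.reindex(cohort.patient_ids)
    if include_genomic:
        table["genomic"] = [
            genomic_risk(call) for call in cohort.manifest["hrd_call"]
        ]
    return table


def fit_fusion(
    score_table: pd.DataFrame,
    durations: pd.Series,
    events: pd.Series,
    modalities: Sequence[str],
    l2: float = FINAL_L2,
) -> FusionModel:
    """Fit the second-stage Cox model on the intersection set.

    Only patients with every included modality's score contribute.  Score
    columns are used as-is (they are already on the log-hazard scale, so
    coefficients stay interpretable).  An empty or event-poor intersection
    raises, naming the modality that most restricts it.
    """
    modalities = list(modalities)
    missing = [m for m in modalities if m not in score_table.columns]
    if missing:
        raise KeyError(f"score table lacks modalities: {missing}")
    sub = score_table[modalities]
    complete = sub.notna().all(axis=1)
    if complete.sum() == 0 or events.loc[sub.index[complete]].sum() < 2:
        binding = sub.notna().sum().idxmin()
        raise ValueError(
            f"intersection set too small to fit fusion over {modalities} "
            f"(binding modality: {binding})"
        )
    ids = sub.index[complete]
    df = make_survival_frame(
        sub.loc[ids].reset_index(drop=True),
        durations.loc[ids].to_numpy(),
        events.loc[ids].to_numpy(),
    )
    cph = fit_cox_strict(df, penalizer=l2)
    return FusionModel(
        modalities=modalities,
        coefficients=cph.params_.loc[modalities].to_numpy(dtype=float),
        n_intersection=int(complete.sum()),
        l2=l2,
        p_values={m: float(cph.summary.loc[m, "p"]) for m in modalities},
    )


def predict_fused(model: FusionModel, score_table: pd.DataFrame) -> pd.Series:
    """Fused negative log partial hazard; missing when any modality is.

    The fused score is the fixed linear combination -sum_m beta_m s_m of the
    submodel scores; patients lacking any included modality get NaN.
    """
    sub = score_table[model.modalities]
    X = sub.to_numpy(dtype=float)
    fused = -(X @ model.coefficients)
    fused = np.where(np.isnan(X).any(axis=1), np.nan, fused)
    return pd.Series(fused, index=score_table.index, name="fused_score")
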