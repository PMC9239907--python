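"""Multimodal cohort container and plain-text (TSV) serialization.

A cohort bundles, per patient: right-censored OS/PFS outcomes, a clinical
record, an HRD subtype call, an optional chemotherapy response score (CRS),
and zero or more per-modality feature vectors.  Modality availability is
explicit — a patient missing a modality simply has no row in that modality's
feature matrix and a ``has_<modality>`` flag of 0 in the manifest.

All on-disk formats are delimited text so cohorts can be inspected, diffed
and versioned; floats round-trip exactly through ``repr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

ENDPOINTS = ("OS", "PFS")

#: manifest columns, in on-disk order (``has_<modality>`` flags follow these)
MANIFEST_COLUMNS = [
    "os_months",
    "os_event",
    "pfs_months",
    "pfs_event",
    "stage",
    "rd_status",
    "treatment",
    "parpi",
    "age",
    "adnexal_present",
    "hrd_call",
    "crs",
]

STAGES = ("I", "II", "III", "IV", "unknown")
TREATMENTS = ("NACT-IDS", "PDS", "unknown")
RD_STATUSES = ("le1cm", "gt1cm", "unknown")


@dataclass(frozen=True)
class SurvivalOutcome:
    """A right-censored survival record for one endpoint.

    ``duration`` is in months and must be finite and positive; ``event`` is
    True when the endpoint (death for OS, progression for PFS) was observed,
    False for censored records.
    """

    duration: float
    event: bool
    endpoint: str = "OS"

    def __post_init__(self) -> None:
        if self.endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        if not np.isfinite(self.duration) or self.duration <= 0:
            raise ValueError("duration must be finite and positive")


@dataclass
class MultimodalCohort:
    """Patients × (outcomes, clinical record, HRD call, modality features).

    Attributes
    ----------
    manifest
        DataFrame indexed by patient id with :data:`MANIFEST_COLUMNS` plus
        one ``has_<modality>`` flag per feature modality.
    features
        Mapping modality name → DataFrame (patients × named features);
        rows exist only for patients with that modality available.
    ground_truth
        Simulation-only: per-patient true linear predictor (log relative
        hazard). ``None`` for cohorts read from real data.
    variants, signatures
        Optional genomic evidence: long-form variant/CNA rows and per-patient
        SBS3/panel rows, as consumed by :mod:`mmsurv.hrd`.
    """

    manifest: pd.DataFrame
    features: dict[str, pd.DataFrame] = field(default_factory=dict)
    ground_truth: Optional[pd.Series] = None
    variants: Optional[pd.DataFrame] = None
    signatures: Optional[pd.DataFrame] = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors ---------------------------------------------------------
    @property
    def patient_ids(self) -> pd.Index:
        return self.manifest.index

    @property
    def modalities(self) -> list[str]:
        return sorted(self.features)

    def outcomes(self, endpoint: str = "OS") -> pd.DataFrame:
        """Return a (duration, event) frame for one endpoint, indexed by id."""
        if endpoint not in ENDPOINTS:
            raise ValueError(f"endpoint must be one of {ENDPOINTS}")
        col = endpoint.lower()
        out = self.manifest[[f"{col}_months", f"{col}_event"]].copy()
        out.columns = ["duration", "event"]
        out["event"] = out["event"].astype(bool)
        return out

    def available(self, modality: str) -> pd.Index:
        """Patient ids with the given modality present."""
        return self.features[modality].index

    def subset(self, ids) -> "MultimodalCohort":
        """Restrict the cohort to the given patient ids (order preserved)."""
        ids = pd.Index(ids)
        missing = ids.difference(self.manifest.index)
        if len(missing):
            raise KeyError(f"unknown patient ids: {list(missing)[:5]}")
        feats = {m: f.loc[f.index.intersection(ids)] for m, f in self.features.items()}
        gt = None if self.ground_truth is None else self.ground_truth.loc[ids]
        var = None
        if self.variants is not None:
            var = self.variants[self.variants["patient_id"].isin(ids)].reset_index(drop=True)
        sig = None
        if self.signatures is not None:
            sig = self.signatures[self.signatures["patient_id"].isin(ids)].reset_index(drop=True)
        return MultimodalCohort(
            manifest=self.manifest.loc[ids].copy(),
            features=feats,
            ground_truth=gt,
            variants=var,
            signatures=sig,
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        if self.manifest.index.has_duplicates:
            dup = self.manifest.index[self.manifest.index.duplicated()].unique()
            raise ValueError(f"duplicated patient ids: {list(dup)[:5]}")
        for col in ("os_months", "pfs_months"):
            d = self.manifest[col].to_numpy(dtype=float)
            if not np.all(np.isfinite(d)) or np.any(d <= 0):
                raise ValueError(f"{col} must be finite and positive")
        seen: dict[str, str] = {}
        for mod, mat in self.features.items():
            extra = mat.index.difference(self.manifest.index)
            if len(extra):
                raise ValueError(f"{mod} matrix has unknown patients: {list(extra)[:5]}")
            if mat.index.has_duplicates:
                raise ValueError(f"{mod} matrix has duplicated patient ids")
            for name in mat.columns:
                if name in seen:
                    raise ValueError(
                        f"feature {name!r} appears in both {seen[name]} and {mod}"
                    )
                seen[name] = mod
            flag = f"has_{mod}"
            if flag in self.manifest.columns:
                flagged = set(self.manifest.index[self.manifest[flag].astype(bool)])
                if flagged != set(mat.index):
                    raise ValueError(f"{flag} flags disagree with {mod} matrix rows")


# -- serialization ---------------------------------------------------------

def write_cohort(cohort: MultimodalCohort, directory) -> Path:
    """Write a cohort as TSV files; returns the manifest path.

    Layout: ``manifest.tsv``, ``features_<modality>.tsv`` (first column id),
    optional ``ground_truth.tsv``, ``variants.tsv``, ``signatures.tsv``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.tsv"
    man = cohort.manifest.copy()
    man.index.name = "id"
    man.to_csv(manifest_path, sep="\t")
    for mod, mat in cohort.features.items():
        m = mat.copy()
        m.index.name = "id"
        m.to_csv(directory / f"features_{mod}.tsv", sep="\t")
    if cohort.ground_truth is not None:
        gt = cohort.ground_truth.rename("true_eta").to_frame()
        gt.index.name = "id"
        gt.to_csv(directory / "ground_truth.tsv", sep="\t")
    if cohort.variants is not None:
        cohort.variants.to_csv(directory / "variants.tsv", sep="\t", index=False)
    if cohort.signatures is not None:
        cohort.signatures.to_csv(directory / "signatures.tsv", sep="\t", index=False)
    return manifest_path


def read_cohort(directory) -> MultimodalCohort:
    """Read a cohort written by :func:`write_cohort` (round-trip identity)."""
    directory = Path(directory)
    manifest_path = directory / "manifest.tsv"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.tsv in {directory}")
    man = pd.read_csv(manifest_path, sep="\t", dtype={"id": str})
    if man["id"].duplicated().any():
        raise ValueError("manifest contains duplicated patient ids")
    man = man.set_index("id")
    for col in ("os_event", "pfs_event", "parpi", "adnexal_present"):
        if col in man.columns:
            man[col] = man[col].astype(bool)
    features: dict[str, pd.DataFrame] = {}
    for path in sorted(directory.glob("features_*.tsv")):
        mod = path.stem[len("features_"):]
        with open(path) as fh:
            n_fields = len(fh.readline().rstrip("\n").split("\t"))
            for lineno, line in enumerate(fh, start=2):
                if line.strip() and len(line.rstrip("\n").split("\t")) != n_fields:
                    raise ValueError(
                        f"{path.name}:{lineno}: feature count disagrees with header"
                    )
        mat = pd.read_csv(path, sep="\t", dtype={"id": str}).set_index("id")
        features[mod] = mat
    gt = None
    gt_path = directory / "ground_truth.tsv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path, sep="\t", dtype={"id": str}).set_index("id")["true_eta"]
    var = None
    var_path = directory / "variants.tsv"
    if var_path.exists():
        var = pd.read_csv(var_path, sep="\t", dtype={"patient_id": str})
    sig = None
    sig_path = directory / "signatures.tsv"
    if sig_path.exists():
        sig = pd.read_csv(sig_path, sep="\t", dtype={"patient_id": str})
    return MultimodalCohort(
        manifest=man, features=features, ground_truth=gt, variants=var, signatures=sig
    )
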