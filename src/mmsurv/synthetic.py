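"""Synthetic multimodal cohorts with known ground truth.

The generator emulates the statistical structure of a multimodal ovarian
cancer study so every downstream stage (selection, submodels, fusion,
evaluation) is testable without protected data:

* high-dimensional radiomic-like (600) and histopathology-like (216)
  feature blocks with a few planted prognostic features, block-equicorrelated
  Gaussian decoys, and a fraction of near-constant (zero-inflated) features
  that fail the scaled-IQR filter by construction;
* modality missingness at configurable availability rates (defaults match a
  404-patient training cohort with 243 H&E, 251 omental-CT and 337
  sequenced cases);
* a binary HRD ground-truth label with a prognostic effect, surfaced as
  genomic evidence rows so the rule engine produces the observed call;
* right-censored OS and PFS under a Weibull proportional-hazards model with
  independent exponential censoring calibrated by bisection to a target
  censored fraction;
* an ordinal 3-level chemotherapy response score whose distribution shifts
  with true risk.

A fixed seed yields a byte-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import MultimodalCohort
from .hrd import calls_from_tables
from .histo import TissueMap, default_palette

TRAIN_N = 404  # reference training-cohort size the default rates derive from
DEFAULT_AVAILABILITY = {
    "radiomic": 251 / TRAIN_N,
    "histopathology": 243 / TRAIN_N,
    "genomic": 337 / TRAIN_N,
}


@dataclass(frozen=True)
class PlantedEffect:
    """One prognostic feature planted in a modality block."""

    modality: str
    index: int
    log_hr: float


@dataclass
class SimulationConfig:
    """All knobs of the cohort generator; a fixed seed is reproducible.

    ``availability`` maps each modality to the probability that a patient
    has it (drawn independently per patient).  ``censoring_rate_target`` is
    the desired overall censored fraction per endpoint; 0 disables the
    censoring process entirely.  The Weibull baseline defaults to shape 1
    (exponential) with a 65-month scale, i.e. a ~45-month baseline median.
    """

    n_patients: int = 444
    n_features: dict[str, int] = field(
        default_factory=lambda: {"radiomic": 600, "histopathology": 216}
    )
    planted: list[PlantedEffect] = field(
        default_factory=lambda: [
            PlantedEffect("radiomic", 0, 1.0),
            PlantedEffect("histopathology", 0, 0.5),
            PlantedEffect("histopathology", 1, 0.5),
        ]
    )
    decoy_block_size: int = 8
    decoy_block_correlation: float = 0.5
    cross_modal_correlation: float = 0.0
    near_constant_fraction: float = 0.26
    availability: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AVAILABILITY)
    )
    baseline_shape: float = 1.0
    baseline_scale: float = 65.0
    pfs_scale: float = 24.0
    censoring_rate_target: float = 0.4
    hrd_prevalence: float = 119 / 337
    hrd_log_hr: float = 0.4  # hazard of HRP relative to HRD tumors
    rd_log_hr: float = -0.3  # effect of ≤1 cm residual disease
    parpi_log_hr: float = -0.2
    crs_fraction: float = 46 / TRAIN_N
    conflict_rate: float = 0.015  # sequenced patients with conflicting evidence
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for name, val in [
            ("decoy_block_correlation", self.decoy_block_correlation),
            ("cross_modal_correlation", self.cross_modal_correlation),
        ]:
            if not 0 <= val < 1:
                raise ValueError(f"{name} must lie in [0, 1)")
        for name, val in [
            ("near_constant_fraction", self.near_constant_fraction),
            ("censoring_rate_target", self.censoring_rate_target),
            ("hrd_prevalence", self.hrd_prevalence),
            ("crs_fraction", self.crs_fraction),
        ] + [(f"availability[{m}]", p) for m, p in self.availability.items()]:
            if not 0 <= val <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for eff in self.planted:
            if eff.modality not in self.n_features:
                raise ValueError(f"planted effect references unknown modality {eff.modality!r}")
            if not 0 <= eff.index < self.n_features[eff.modality]:
                raise ValueError(
                    f"planted feature index {eff.index} out of range for {eff.modality}"
                )


def feature_name(modality: str, index: int) -> str:
    return f"{modality}_f{index:04d}"


def _simulate_features(
    config: SimulationConfig, rng: np.random.Generator
) -> tuple[dict[str, pd.DataFrame], dict[str, list[str]]]:
    """Draw per-modality matrices; returns (matrices, near-constant names)."""
    n = config.n_patients
    rho = config.decoy_block_correlation
    kappa = config.cross_modal_correlation
    shared_latent = rng.standard_normal(n)  # couples planted blocks if kappa > 0
    matrices: dict[str, pd.DataFrame] = {}
    near_constant: dict[str, list[str]] = {}
    planted_idx = {
        mod: {e.index for e in config.planted if e.modality == mod}
        for mod in config.n_features
    }
    for mod in sorted(config.n_features):
        m = config.n_features[mod]
        cols = np.empty((n, m))
        candidates = np.array(
            [j for j in range(m) if j not in planted_idx[mod]], dtype=int
        )
        n_nc = int(round(config.near_constant_fraction * m))
        nc_idx = set(
            rng.choice(candidates, size=min(n_nc, len(candidates)), replace=False).tolist()
        )
        near_constant[mod] = [feature_name(mod, j) for j in sorted(nc_idx)]
        live = [j for j in range(m) if j not in nc_idx]
        block = config.decoy_block_size
        for b0 in range(0, len(live), block):
            members = live[b0 : b0 + block]
            z = rng.standard_normal(n)
            if kappa > 0 and any(j in planted_idx[mod] for j in members):
                z = np.sqrt(kappa) * shared_latent + np.sqrt(1 - kappa) * z
            for j in members:
                eps = rng.standard_normal(n)
                cols[:, j] = np.sqrt(rho) * z + np.sqrt(1 - rho) * eps
        for j in sorted(nc_idx):
            nonzero = rng.random(n) < 0.03
            cols[:, j] = np.where(nonzero, rng.uniform(0.5, 1.5, size=n), 0.0)
        matrices[mod] = pd.DataFrame(
            cols, columns=[feature_name(mod, j) for j in range(m)]
        )
    return matrices, near_constant


def _weibull_ph_times(
    eta: np.ndarray, shape: float, scale: float, rng: np.random.Generator
) -> np.ndarray:
    """Event times with S(t | eta) = exp(-(t/scale)^shape * e^eta)."""
    u = rng.random(len(eta))
    return scale * (-np.log(u) / np.exp(eta)) ** (1.0 / shape)


def _calibrate_censoring(times: np.ndarray, target: float) -> float:
    """Exponential censoring rate hitting the target censored fraction.

    Solves mean_i P(C < t_i) = target for the rate by bisection; keeps
    censoring independent of risk as the Cox model assumes.
    """
    def frac(rate: float) -> float:
        return float(np.mean(1.0 - np.exp(-rate * times)))

    lo, hi = 1e-12, 1.0
    while frac(hi) < target:
        hi *= 2.0
        if hi > 1e9:
            break
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _censor(
    times: np.ndarray, target: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    if target <= 0:
        return times, np.ones(len(times), dtype=bool)
    rate = _calibrate_censoring(times, target)
    censor_times = rng.exponential(scale=1.0 / rate, size=len(times))
    observed = np.minimum(times, censor_times)
    event = times <= censor_times
    return observed, event


def _genomic_evidence(
    ids: Sequence[str],
    hrd_true: np.ndarray,
    sequenced: np.ndarray,
    conflict_rate: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Variant and signature rows consistent with the true HRD labels."""
    var_rows = []
    sig_rows = []
    genes = ("BRCA1", "BRCA2", "PALB2", "RAD51C")
    for i, pid in enumerate(ids):
        if not sequenced[i]:
            sig_rows.append((pid, "unknown", np.nan, "none"))
            continue
        conflict = rng.random() < conflict_rate
        if hrd_true[i]:
            if rng.random() < 0.75:
                gene = genes[rng.integers(len(genes))]
                vclass = "deep_deletion" if rng.random() < 0.3 else "snv"
                var_rows.append((pid, gene, vclass, "significant"))
                sig_rows.append((pid, "low" if rng.random() < 0.4 else "absent", np.nan, "full_panel"))
            else:
                sig_rows.append((pid, "high", np.nan, "full_panel"))
            if conflict:  # HRD evidence plus subgroup evidence -> ambiguous call
                var_rows.append((pid, "CCNE1", "amplification", "significant"))
        else:
            if conflict:
                gene = genes[rng.integers(len(genes))]
                var_rows.append((pid, gene, "snv", "significant"))
                var_rows.append((pid, "CDK12", "snv", "significant"))
            elif rng.random() < 0.05:
                var_rows.append((pid, genes[rng.integers(len(genes))], "snv", "vus"))
            sig_rows.append((pid, "absent", np.nan, "full_panel"))
    variants = pd.DataFrame(
        var_rows, columns=["patient_id", "gene", "variant_class", "oncogenic_flag"]
    )
    signatures = pd.DataFrame(
        sig_rows, columns=["patient_id", "sbs3_status", "sbs3_frequency", "panel"]
    )
    return variants, signatures


def simulate_cohort(config: Optional[SimulationConfig] = None) -> MultimodalCohort:
    """Generate a multimodal cohort under the configured conditions."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    ids = [f"p{i:05d}" for i in range(1, n + 1)]

    # clinical record
    age = np.clip(rng.normal(62, 10, size=n), 30, 92).round(1)
    stage = rng.choice(
        ["I", "II", "III", "IV", "unknown"], size=n, p=[0.05, 0.06, 0.55, 0.30, 0.04]
    )
    treatment = rng.choice(["NACT-IDS", "PDS", "unknown"], size=n, p=[0.50, 0.45, 0.05])
    rd_status = rng.choice(["le1cm", "gt1cm", "unknown"], size=n, p=[0.60, 0.35, 0.05])
    parpi = rng.random(n) < 0.25
    adnexal = rng.random(n) < 245 / TRAIN_N

    # modality features and availability
    matrices, _ = _simulate_features(config, rng)
    has = {
        mod: rng.random(n) < config.availability.get(mod, 1.0)
        for mod in sorted(set(list(config.n_features) + ["genomic"]))
    }

    # true linear predictor (log relative hazard)
    hrd_true = rng.random(n) < config.hrd_prevalence  # True = HRD tumor
    eta = np.zeros(n)
    for eff in config.planted:
        eta += eff.log_hr * matrices[eff.modality][feature_name(eff.modality, eff.index)].to_numpy()
    eta += config.hrd_log_hr * (~hrd_true)
    eta += config.rd_log_hr * (rd_status == "le1cm")
    eta += config.parpi_log_hr * parpi

    # outcomes under Weibull proportional hazards + independent censoring
    os_true = _weibull_ph_times(eta, config.baseline_shape, config.baseline_scale, rng)
    os_months, os_event = _censor(os_true, config.censoring_rate_target, rng)
    pfs_true = _weibull_ph_times(eta, config.baseline_shape, config.pfs_scale, rng)
    pfs_months, pfs_event = _censor(pfs_true, config.censoring_rate_target, rng)

    # genomic evidence -> observed HRD call through the rule engine
    variants, signatures = _genomic_evidence(
        ids, hrd_true, has["genomic"], config.conflict_rate, rng
    )
    hrd_call = calls_from_tables(variants, signatures, ids, ruleset="msk")

    # ordinal chemotherapy response score, shifted by true risk
    crs_known = rng.random(n) < config.crs_fraction
    latent = -eta + rng.normal(0, 1.0, size=n)
    z = (latent - latent.mean()) / (latent.std() or 1.0)
    crs = 1 + (z > -0.43).astype(int) + (z > 0.43).astype(int)
    crs_col = np.where(crs_known, crs.astype(float), np.nan)

    manifest = pd.DataFrame(
        {
            "os_months": np.maximum(os_months, 1e-3),
            "os_event": os_event,
            "pfs_months": np.maximum(pfs_months, 1e-3),
            "pfs_event": pfs_event,
            "stage": stage,
            "rd_status": rd_status,
            "treatment": treatment,
            "parpi": parpi,
            "age": age,
            "adnexal_present": adnexal,
            "hrd_call": hrd_call.to_numpy(),
            "crs": crs_col,
        },
        index=pd.Index(ids, name="id"),
    )
    features = {}
    for mod, mat in matrices.items():
        mat = mat.set_axis(manifest.index)
        features[mod] = mat.loc[has[mod]]
        manifest[f"has_{mod}"] = has[mod]
    manifest["has_genomic"] = has["genomic"]
    return MultimodalCohort(
        manifest=manifest,
        features=features,
        ground_truth=pd.Series(eta, index=manifest.index, name="true_eta"),
        variants=variants,
        signatures=signatures,
    )


# -- synthetic tissue specimens -------------------------------------------

def simulate_tissue_specimen(
    width: int,
    height: int,
    class_layout: Sequence[tuple[str, int, int, int, int]],
    nuclei_spec: dict[str, dict],
    seed: int = 0,
    microns_per_pixel: float = 1.0,
) -> tuple[TissueMap, pd.DataFrame]:
    """Paint rectangular class regions and scatter nuclei inside them.

    ``class_layout`` is a sequence of (class, x, y, w, h) rectangles painted
    onto a background canvas; overlapping rectangles of different classes
    are an error.  ``nuclei_spec`` maps class → {n, area_mean, area_sd,
    lymphocyte_fraction}; each nucleus centroid is drawn uniformly inside
    its class region, so it lies in the intended region by construction.
    """
    palette = default_palette()
    name_to_idx = {v: k for k, v in palette.items()}
    labels = np.zeros((height, width), dtype=np.uint8)
    for cls, x, y, w, h in class_layout:
        if cls not in name_to_idx:
            raise ValueError(f"unknown tissue class {cls!r}")
        region = labels[y : y + h, x : x + w]
        conflict = (region != 0) & (region != name_to_idx[cls])
        if conflict.any():
            raise ValueError(f"layout rectangle for {cls!r} overlaps another class")
        region[:] = name_to_idx[cls]
    tm = TissueMap(labels, palette, microns_per_pixel)

    rng = np.random.default_rng(seed)
    rows = []
    nid = 0
    for cls in sorted(nuclei_spec):
        spec = nuclei_spec[cls]
        n = int(spec.get("n", 0))
        if n == 0:
            continue
        mask = tm.mask(cls)
        ys, xs = np.nonzero(mask)
        if len(ys) == 0:
            raise ValueError(f"no pixels of class {cls!r} to place nuclei in")
        for _ in range(n):
            k = rng.integers(len(ys))
            x = xs[k] + rng.random() * 0.999
            y = ys[k] + rng.random() * 0.999
            area = max(float(rng.normal(spec.get("area_mean", 30.0), spec.get("area_sd", 0.0))), 1.0)
            lymph = rng.random() < spec.get("lymphocyte_fraction", 0.0)
            nid += 1
            rows.append(
                {
                    "id": f"n{nid:05d}",
                    "x": float(x),
                    "y": float(y),
                    "area": area,
                    "diameter": 2.0 * np.sqrt(area / np.pi),
                    "circularity": float(np.clip(rng.normal(0.85, 0.05), 0.2, 1.0)),
                    "eosin_mean": float(np.clip(rng.normal(0.5, 0.1), 0, 1)),
                    "hematoxylin_mean": float(np.clip(rng.normal(0.6, 0.1), 0, 1)),
                    "cell_type": "lymphocyte" if lymph else "other",
                }
            )
    nuclei = pd.DataFrame(
        rows,
        columns=[
            "id", "x", "y", "area", "diameter", "circularity",
            "eosin_mean", "hematoxylin_mean", "cell_type",
        ],
    )
    return tm, nuclei
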