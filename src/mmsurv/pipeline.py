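"""End-to-end pipeline: split, per-modality selection and fitting, late
fusion over modality combinations, and a consolidated evaluation report.

The driver enforces a strict train/test separation: the test split is drawn
once from the full-information patients, test outcomes are held in an
access-counting guard, and the guard is asserted untouched before the
evaluation phase begins.  All randomness derives from one global seed via
named per-stage substreams, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cohort import MultimodalCohort
from .evaluation import (
    DEFAULT_THRESHOLD_GRID,
    evaluate,
    kendall_matrix,
    km_curve,
    logrank,
    median_survival,
    threshold_search,
    crs_association,
)
from .fusion import MODALITY_TAGS, assemble_submodel_scores, fit_fusion, predict_fused
from .models import CoxSubmodel, encode_clinical, fit_submodel
from .selection import SelectionConfig, select_modality

DEFAULT_COMBINATIONS = (
    ("genomic",),
    ("radiomic",),
    ("histopathology",),
    ("clinical",),
    ("radiomic", "histopathology"),
    ("genomic", "radiomic", "histopathology"),
    ("genomic", "radiomic", "histopathology", "clinical"),
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage substream seed (< 2^31)."""
    return (int(seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31 - 1)


def combo_tag(combination: Sequence[str]) -> str:
    return "".join(MODALITY_TAGS.get(m, m[0].upper()) for m in combination)


@dataclass
class PipelineConfig:
    """Configuration of one end-to-end run."""

    endpoint: str = "OS"
    modalities: list[str] = field(
        default_factory=lambda: ["genomic", "radiomic", "histopathology", "clinical"]
    )
    selection: dict[str, SelectionConfig] = field(default_factory=dict)
    combinations: list[tuple[str, ...]] = field(
        default_factory=lambda: [tuple(c) for c in DEFAULT_COMBINATIONS]
    )
    clinical_mode: str = "cascade"  # "cascade" | "replication" (fixed RD + PARPi pair)
    n_test: int = 40
    n_bootstrap: int = 100
    n_permutations: int = 1000
    threshold_grid: tuple[float, ...] = DEFAULT_THRESHOLD_GRID
    seed: int = 0

    def __post_init__(self) -> None:
        for combo in self.combinations:
            if not set(combo) <= set(self.modalities):
                raise ValueError(
                    f"combination {combo} references modalities outside {self.modalities}"
                )
        if self.clinical_mode not in ("cascade", "replication"):
            raise ValueError("clinical_mode must be 'cascade' or 'replication'")

    def selection_for(self, modality: str) -> SelectionConfig:
        if modality in self.selection:
            return self.selection[modality]
        # radiomics is the largest feature space: BH correction by default
        return SelectionConfig(apply_bh=(modality == "radiomic"))


class _OutcomeGuard:
    """Counts accesses to the held-out outcomes (train/test leak guard)."""

    def __init__(self, frame: pd.DataFrame) -> None:
        self._frame = frame
        self.accesses = 0

    def get(self) -> pd.DataFrame:
        self.accesses += 1
        return self._frame


def make_test_split(cohort: MultimodalCohort, n_test: int, seed: int) -> pd.Series:
    """Sample the test set uniformly from the full-information patients.

    Eligible patients have every modality available, an unambiguous HRD
    call and a known stage.  Returns a Series id → "train"/"test".
    """
    man = cohort.manifest
    eligible = pd.Series(True, index=man.index)
    for mod in cohort.features:
        eligible &= man[f"has_{mod}"].astype(bool)
    if "has_genomic" in man.columns:
        eligible &= man["has_genomic"].astype(bool)
    eligible &= man["hrd_call"] != "ambiguous"
    eligible &= man["stage"] != "unknown"
    pool = man.index[eligible]
    if len(pool) < n_test:
        raise ValueError(
            f"only {len(pool)} full-information patients; cannot sample {n_test} test cases"
        )
    rng = np.random.default_rng(seed)
    test_ids = pd.Index(rng.choice(pool.to_numpy(), size=n_test, replace=False))
    split = pd.Series("train", index=man.index, name="split")
    split.loc[test_ids] = "test"
    return split


def train_submodels(
    cohort: MultimodalCohort,
    train_ids: pd.Index,
    config: PipelineConfig,
    endpoint: str,
) -> tuple[dict[str, CoxSubmodel], Optional[pd.DataFrame], dict]:
    """Select features and fit one submodel per non-genomic modality.

    Each submodel trains on all *available* training patients for its
    modality.  Returns (submodels, clinical matrix for all patients, log).
    """
    outcomes = cohort.outcomes(endpoint).loc[train_ids]
    submodels: dict[str, CoxSubmodel] = {}
    clinical_all: Optional[pd.DataFrame] = None
    log: dict = {}
    for mod in config.modalities:
        if mod == "genomic":
            continue  # rule-based risk; no parameters fitted
        if mod == "clinical":
            train_clin, age_range = encode_clinical(cohort.manifest.loc[train_ids])
            clinical_all, _ = encode_clinical(cohort.manifest, age_range=age_range)
            matrix, rows = clinical_all, train_ids
        else:
            rows = cohort.features[mod].index.intersection(train_ids)
            matrix = cohort.features[mod]
        tr = matrix.loc[rows]
        out = outcomes.loc[rows]
        if mod == "clinical" and config.clinical_mode == "replication":
            features = ["rd", "parpi"]
            log[mod] = {"mode": "replication", "n_selected": 2}
        else:
            sig = select_modality(
                tr, out["duration"], out["event"], config.selection_for(mod)
            )
            features = sig.features
            log[mod] = {
                k: sig.audit[k]
                for k in ("n_input", "n_after_iqr", "n_candidates", "n_selected")
            }
            log[mod]["features"] = features
        if not features:
            log[mod]["skipped"] = "empty signature"
            continue
        submodels[mod] = fit_submodel(
            features, tr, out["duration"], out["event"], modality=mod
        )
    return submodels, clinical_all, log


def run_pipeline(
    cohort: MultimodalCohort,
    config: Optional[PipelineConfig] = None,
    outdir: Optional[Path] = None,
) -> dict:
    """Execute selection → submodels → fusion → evaluation; return reports."""
    config = config or PipelineConfig()
    endpoint = config.endpoint
    split = make_test_split(cohort, config.n_test, stage_seed(config.seed, "split"))
    train_ids = split.index[split == "train"]
    test_ids = split.index[split == "test"]
    guard = _OutcomeGuard(cohort.outcomes(endpoint).loc[test_ids])

    submodels, clinical_all, selection_log = train_submodels(
        cohort, train_ids, config, endpoint
    )
    score_table = assemble_submodel_scores(
        cohort,
        submodels,
        clinical_matrix=clinical_all,
        include_genomic="genomic" in config.modalities,
    )
    train_out = cohort.outcomes(endpoint).loc[train_ids]

    # -- training phase done: held-out outcomes must be untouched ----------
    accesses_before_eval = guard.accesses
    assert accesses_before_eval == 0, "test outcomes were read during training"
    test_out = guard.get()

    reports: dict[str, dict] = {}
    fused_scores: dict[str, pd.Series] = {}
    for combo in config.combinations:
        tag = combo_tag(combo)
        entry: dict = {"combination": list(combo), "tag": tag}
        try:
            model = fit_fusion(
                score_table.loc[train_ids],
                train_out["duration"],
                train_out["event"],
                combo,
            )
        except (ValueError, KeyError) as err:
            entry["error"] = str(err)
            reports[tag] = entry
            continue
        entry["coefficients"] = {
            m: float(c) for m, c in zip(model.modalities, model.coefficients)
        }
        entry["n_intersection"] = model.n_intersection
        fused = predict_fused(model, score_table)
        fused_scores[tag] = fused
        for name, ids, out in (
            ("train", train_ids, train_out),
            ("test", test_ids, test_out),
        ):
            s = fused.loc[ids].dropna()
            o = out.loc[s.index]
            entry[name] = evaluate(
                s,
                o["duration"],
                o["event"],
                n_bootstrap=config.n_bootstrap,
                n_perm=config.n_permutations,
                seed=stage_seed(config.seed, f"eval_{tag}_{name}"),
            ).as_dict()
        # KM risk groups: threshold searched on training, frozen for test
        s_train = fused.loc[train_ids].dropna()
        o_train = train_out.loc[s_train.index]
        try:
            groups = threshold_search(
                s_train,
                o_train["duration"],
                o_train["event"],
                grid=config.threshold_grid,
                endpoint=endpoint,
            )
        except ValueError as err:
            entry["risk_groups"] = {"error": str(err)}
            reports[tag] = entry
            continue
        rg: dict = {
            "percentile": groups.percentile,
            "score_cut": groups.score_cut,
            "train_logrank_p": groups.logrank_p,
        }
        for name, scores_split, out in (
            ("train", s_train, o_train),
            ("test", fused.loc[test_ids].dropna(), None),
        ):
            out = o_train if name == "train" else test_out.loc[scores_split.index]
            labels = groups.groups if name == "train" else groups.apply(scores_split)
            medians = {}
            for lab in ("high", "low"):
                ids_g = labels.index[labels == lab]
                if len(ids_g) == 0:
                    medians[lab] = float("nan")
                    continue
                curve = km_curve(
                    out.loc[ids_g, "duration"], out.loc[ids_g, "event"]
                )
                medians[lab] = median_survival(curve)
            rg[f"{name}_median_survival_months"] = medians
            if name == "test" and labels.nunique() == 2:
                _, p = logrank(
                    out["duration"], out["event"], labels.to_numpy()
                )
                rg["test_logrank_p"] = float(p)
        entry["risk_groups"] = rg
        reports[tag] = entry

    result: dict = {
        "endpoint": endpoint,
        "n_train": int(len(train_ids)),
        "n_test": int(len(test_ids)),
        "selection": selection_log,
        "test_outcome_accesses_before_evaluation": accesses_before_eval,
        "combinations": reports,
    }
    # cross-modal ordering information on the training set
    mods_present = [c for c in score_table.columns]
    if len(mods_present) >= 2:
        km = kendall_matrix(score_table.loc[train_ids])
        result["kendall_tau"] = {
            a: {b: float(km.loc[a, b]) for b in km.columns} for a in km.index
        }
    # CRS association of the fused score (largest fitted combination)
    crs = cohort.manifest.loc[train_ids, "crs"]
    if crs.notna().sum() >= 4:
        for tag in ("GRH", *reversed(list(fused_scores))):
            if tag in fused_scores:
                try:
                    p = crs_association(fused_scores[tag].loc[train_ids], crs)
                    result["crs_association"] = {"combination": tag, "one_sided_p": float(p)}
                except ValueError:
                    pass
                break

    if outdir is not None:
        _write_bundle(outdir, result, fused_scores, split, submodels)
    return result


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def _write_bundle(outdir, result, fused_scores, split, submodels) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(
        json.dumps(result, indent=2, sort_keys=True, default=_json_default)
    )
    split.to_frame().to_csv(outdir / "split.tsv", sep="\t")
    if fused_scores:
        pd.DataFrame(fused_scores).to_csv(outdir / "fused_scores.tsv", sep="\t")
    for mod, model in submodels.items():
        model.to_json(outdir / f"submodel_{mod}.json")
    rows = []
    for tag, entry in result["combinations"].items():
        if "test" in entry:
            rows.append(
                {
                    "combination": tag,
                    "test_c": entry["test"]["c_index"],
                    "test_ci_low": entry["test"]["ci_low"],
                    "test_ci_high": entry["test"]["ci_high"],
                    "test_permutation_p": entry["test"]["permutation_p"],
                    "train_c": entry["train"]["c_index"],
                }
            )
    pd.DataFrame(rows).to_csv(outdir / "comparison.tsv", sep="\t", index=False)


def ablation_full_information(
    cohort: MultimodalCohort,
    config: Optional[PipelineConfig] = None,
    combination: Optional[Sequence[str]] = None,
) -> dict:
    """Compare learning from all available unimodal cases vs full-information
    cases only.

    Arm "all_available" trains each submodel on every training patient with
    that modality; arm "full_information" restricts the entire cascade to
    training patients having all modalities.  Both fused models are
    evaluated on the same held-out test set.  In the restricted arm the
    selection is run without multiple-testing correction (the training set
    is small); an arm in which no submodel survives reports chance
    concordance (0.5).
    """
    config = config or PipelineConfig()
    endpoint = config.endpoint
    combination = tuple(combination or [m for m in config.modalities])
    split = make_test_split(cohort, config.n_test, stage_seed(config.seed, "split"))
    train_ids = split.index[split == "train"]
    test_ids = split.index[split == "test"]
    test_out = cohort.outcomes(endpoint).loc[test_ids]
    train_out_all = cohort.outcomes(endpoint)

    man = cohort.manifest
    full_info = pd.Series(True, index=man.index)
    for mod in cohort.features:
        full_info &= man[f"has_{mod}"].astype(bool)
    if "has_genomic" in man.columns:
        full_info &= man["has_genomic"].astype(bool)
    full_train_ids = train_ids.intersection(man.index[full_info])

    relaxed = PipelineConfig(
        endpoint=endpoint,
        modalities=config.modalities,
        combinations=[tuple(combination)],
        selection={
            m: SelectionConfig(apply_bh=False) for m in config.modalities if m != "genomic"
        },
        clinical_mode=config.clinical_mode,
        n_test=config.n_test,
        seed=config.seed,
    )

    out: dict = {"combination": list(combination), "n_full_information_train": int(len(full_train_ids))}
    for arm, ids, cfg in (
        ("all_available", train_ids, config),
        ("full_information", full_train_ids, relaxed),
    ):
        submodels, clinical_all, log = train_submodels(cohort, ids, cfg, endpoint)
        table = assemble_submodel_scores(
            cohort, submodels, clinical_matrix=clinical_all,
            include_genomic="genomic" in combination,
        )
        combo = [m for m in combination if m == "genomic" or m in submodels]
        c = 0.5
        note = None
        if combo:
            try:
                model = fit_fusion(
                    table.loc[ids],
                    train_out_all.loc[ids, "duration"],
                    train_out_all.loc[ids, "event"],
                    combo,
                )
                fused = predict_fused(model, table).loc[test_ids].dropna()
                o = test_out.loc[fused.index]
                from .evaluation import harrell_c

                c = harrell_c(fused, o["duration"], o["event"])
            except ValueError as err:
                note = f"fusion failed: {err}"
        else:
            note = "no submodel survived selection"
        out[arm] = {
            "test_c": float(c),
            "modalities_used": combo,
            "n_train": int(len(ids)),
            "selection": log,
            **({"note": note} if note else {}),
        }
    return out
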