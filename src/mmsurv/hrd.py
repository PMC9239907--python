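"""Rule-based homologous-recombination-deficiency (HRD) subtyping.

Tumors are assigned one of three subtypes from targeted-sequencing evidence:

* ``HRD`` — homologous recombination deficient (better prognosis under
  platinum/PARP-inhibitor therapy),
* ``HRP`` — proficient,
* ``ambiguous`` — unsequenced or conflicting evidence; excluded from all
  downstream analyses involving HRD status.

Two rule sets are provided.  The institutional ("msk") rules call HRD on a
high-confidence dominant SBS3 mutational signature or at least one
significant variant / deep deletion in an HRD-DDR gene, unless there is
evidence of the foldback-inversion (CCNE1 amplification) or
tandem-duplicator (CDK12 SNV) subgroups, in which case conflicting evidence
yields ``ambiguous``.  The TCGA rules work from public SNV/CNA calls plus an
SBS3 frequency with a 15% cutoff (strict inequality).

Every call carries a machine-readable ``rationale`` — the ordered list of
rule clauses that fired — so assignments are auditable.

LST (large-scale state transition) thresholding is deliberately not part of
either rule set, and variant significance is taken from the input
annotation flag; no re-annotation is performed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
import pandas as pd

VARIANT_CLASSES = ("snv", "indel", "deep_deletion", "amplification")
SBS3_STATUSES = ("high", "low", "absent", "unknown")
PANELS = ("full_panel", "hrd_ddr_sendout", "none")
SUBTYPES = ("HRD", "HRP", "ambiguous")

#: Default homologous-recombination DNA-damage-response gene panel.
#: CDK12 and CCNE1 are intentionally excluded: they mark the
#: tandem-duplicator and foldback-inversion subgroups, i.e. evidence
#: *against* HRD, and are handled by the exception clauses below.
DEFAULT_HRD_DDR_GENES = frozenset(
    {
        "BRCA1",
        "BRCA2",
        "PALB2",
        "RAD51B",
        "RAD51C",
        "RAD51D",
        "BRIP1",
        "BARD1",
        "ATM",
        "CHEK2",
        "FANCA",
    }
)

SBS3_FREQUENCY_CUTOFF = 0.15  # TCGA rule: HRD requires frequency strictly above


@dataclass(frozen=True)
class Variant:
    """One variant or copy-number row for a patient."""

    gene: str
    variant_class: str  # one of VARIANT_CLASSES
    oncogenic: str = "significant"  # "significant" | "vus"

    def __post_init__(self) -> None:
        if not self.gene:
            raise ValueError("gene symbol must be nonempty")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"unknown variant class {self.variant_class!r}; expected one of {VARIANT_CLASSES}"
            )


@dataclass
class GenomicEvidence:
    """Genomic evidence for one patient, as consumed by the rule engines."""

    variants: list[Variant] = field(default_factory=list)
    sbs3_status: str = "unknown"  # high | low | absent | unknown
    sbs3_frequency: Optional[float] = None
    panel: str = "full_panel"  # full_panel | hrd_ddr_sendout | none
    hrd_ddr_genes: frozenset[str] = DEFAULT_HRD_DDR_GENES

    def __post_init__(self) -> None:
        if self.sbs3_status not in SBS3_STATUSES:
            raise ValueError(f"sbs3_status must be one of {SBS3_STATUSES}")
        if self.panel not in PANELS:
            raise ValueError(f"panel must be one of {PANELS}")
        if self.sbs3_frequency is not None and not 0 <= self.sbs3_frequency <= 1:
            raise ValueError("sbs3_frequency must lie in [0, 1]")

    # -- evidence predicates ------------------------------------------------
    def hrd_ddr_hit(self, significant_only: bool = True) -> bool:
        """Any (significant) SNV/indel/deep deletion in an HRD-DDR gene."""
        for v in self.variants:
            if v.gene in self.hrd_ddr_genes and v.variant_class in (
                "snv",
                "indel",
                "deep_deletion",
            ):
                if not significant_only or v.oncogenic == "significant":
                    return True
        return False

    def ccne1_amplification(self) -> bool:
        return any(
            v.gene == "CCNE1" and v.variant_class == "amplification" for v in self.variants
        )

    def cdk12_snv(self) -> bool:
        return any(v.gene == "CDK12" and v.variant_class == "snv" for v in self.variants)

    def subtype_exception(self) -> bool:
        """Evidence of foldback-inversion or tandem-duplicator subgroups."""
        return self.ccne1_amplification() or self.cdk12_snv()


@dataclass(frozen=True)
class HRDCall:
    """Subtype assignment with the ordered list of fired rule clauses."""

    subtype: str
    rationale: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(f"subtype must be one of {SUBTYPES}")
        if not self.rationale:
            raise ValueError("rationale must be nonempty")


def call_hrd_msk(evidence: GenomicEvidence) -> HRDCall:
    """Institutional rule set (clinical panel + SigMA SBS3 calls).

    HRD requires high-confidence dominant SBS3 or ≥1 significant variant /
    deep deletion in the HRD-DDR genes, with no CCNE1 amplification and no
    CDK12 SNV; HRD evidence co-occurring with such subgroup evidence is a
    conflict → ambiguous.  Unsequenced patients are ambiguous.  Sequenced
    patients with no HRD evidence — including low-confidence SBS3 only,
    which is never used — are HRP.  Send-out HRD-DDR panels yield HRP unless
    the provider flagged a significant variant.
    """
    trace: list[str] = []
    if evidence.panel == "none":
        return HRDCall("ambiguous", ("no sequencing available",))

    if evidence.panel == "hrd_ddr_sendout":
        hit = evidence.hrd_ddr_hit(significant_only=True)
        if hit:
            trace.append("send-out panel: provider-flagged significant HRD-DDR variant")
        else:
            trace.append("send-out panel: no variant of known significance")
    else:
        hit = evidence.hrd_ddr_hit(significant_only=True)
        if evidence.sbs3_status == "high":
            trace.append("high-confidence dominant SBS3")
        elif evidence.sbs3_status == "low":
            trace.append("low-confidence SBS3 not used")
        if hit:
            trace.append("significant variant or deep deletion in HRD-DDR gene")
        hit = hit or evidence.sbs3_status == "high"

    exception = False
    if evidence.ccne1_amplification():
        trace.append("CCNE1 amplification (foldback inversion-enriched subgroup)")
        exception = True
    if evidence.cdk12_snv():
        trace.append("CDK12 SNV (tandem duplicator-enriched subgroup)")
        exception = True

    if hit and exception:
        trace.append("conflicting evidence -> ambiguous")
        return HRDCall("ambiguous", tuple(trace))
    if hit:
        trace.append("-> HRD")
        return HRDCall("HRD", tuple(trace))
    trace.append("sequenced, no HRD evidence -> HRP")
    return HRDCall("HRP", tuple(trace))


def call_hrd_tcga(evidence: GenomicEvidence) -> HRDCall:
    """Public-cohort rule set (cBioPortal SNV/CNA + SBS3 frequency).

    ≥1 significant SNV/indel/deep deletion in HRD-DDR genes → HRD, unless a
    CDK12 SNV or CCNE1 amplification co-occurs → ambiguous.  Otherwise an
    SBS3 frequency strictly above 15% without such conflicting evidence →
    HRD.  Patients without any SNV/CNA data are ambiguous.
    """
    trace: list[str] = []
    has_data = evidence.panel != "none"
    hit = has_data and evidence.hrd_ddr_hit(significant_only=True)
    exception = evidence.subtype_exception() if has_data else False
    freq = evidence.sbs3_frequency

    if hit and exception:
        trace.append("HRD-DDR variant with CDK12 SNV or CCNE1 amplification -> ambiguous")
        return HRDCall("ambiguous", tuple(trace))
    if hit:
        trace.append("significant SNV or deep deletion in HRD-DDR gene -> HRD")
        return HRDCall("HRD", tuple(trace))
    if freq is not None and freq > SBS3_FREQUENCY_CUTOFF and not exception:
        trace.append(f"SBS3 frequency {freq:.3f} > {SBS3_FREQUENCY_CUTOFF:.2f} -> HRD")
        return HRDCall("HRD", tuple(trace))
    if not has_data:
        return HRDCall("ambiguous", ("no SNV/CNA data available",))
    if freq is not None:
        trace.append(f"SBS3 frequency {freq:.3f} <= {SBS3_FREQUENCY_CUTOFF:.2f}")
    trace.append("no HRD-defining aberration -> HRP")
    return HRDCall("HRP", tuple(trace))


def call_hrd(evidence: GenomicEvidence, ruleset: str = "msk") -> HRDCall:
    """Dispatch on an explicit ``ruleset`` ∈ {"msk", "tcga"} (never guessed)."""
    if ruleset == "msk":
        return call_hrd_msk(evidence)
    if ruleset == "tcga":
        return call_hrd_tcga(evidence)
    raise ValueError(f"unknown ruleset {ruleset!r}; expected 'msk' or 'tcga'")


def genomic_risk(call: HRDCall | str) -> float:
    """Map a subtype to the genomic risk score.

    HRP tumors (no benefit from platinum/PARPi) are high risk → 1.0;
    HRD tumors are low risk → 0.0; ambiguous → NaN (the patient is excluded
    from genomic-model analyses).  No model parameters are fitted.
    """
    subtype = call.subtype if isinstance(call, HRDCall) else call
    if subtype == "HRP":
        return 1.0
    if subtype == "HRD":
        return 0.0
    if subtype == "ambiguous":
        return float("nan")
    raise ValueError(f"unknown subtype {subtype!r}")


# -- tabular front end -----------------------------------------------------

def calls_from_tables(
    variants: Optional[pd.DataFrame],
    signatures: Optional[pd.DataFrame],
    patient_ids: Iterable[str],
    ruleset: str = "msk",
    hrd_ddr_genes: frozenset[str] = DEFAULT_HRD_DDR_GENES,
) -> pd.Series:
    """Vector HRD calls from MAF-like variant rows and a signature table.

    ``variants``: columns patient_id, gene, variant_class, oncogenic_flag.
    ``signatures``: columns patient_id, sbs3_status, sbs3_frequency, panel.
    Patients absent from ``signatures`` are treated as unsequenced.
    """
    var_by_pat: dict[str, list[Variant]] = {}
    if variants is not None:
        for row in variants.itertuples(index=False):
            var_by_pat.setdefault(str(row.patient_id), []).append(
                Variant(row.gene, row.variant_class, row.oncogenic_flag)
            )
    sig_by_pat: dict[str, tuple[str, Optional[float], str]] = {}
    if signatures is not None:
        for row in signatures.itertuples(index=False):
            freq = getattr(row, "sbs3_frequency", None)
            freq = None if freq is None or (isinstance(freq, float) and np.isnan(freq)) else float(freq)
            sig_by_pat[str(row.patient_id)] = (row.sbs3_status, freq, row.panel)
    out = {}
    for pid in patient_ids:
        status, freq, panel = sig_by_pat.get(str(pid), ("unknown", None, "none"))
        ev = GenomicEvidence(
            variants=var_by_pat.get(str(pid), []),
            sbs3_status=status,
            sbs3_frequency=freq,
            panel=panel,
            hrd_ddr_genes=hrd_ddr_genes,
        )
        out[pid] = call_hrd(ev, ruleset=ruleset).subtype
    return pd.Series(out, name="hrd_call")
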