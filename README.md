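# mmsurv — late-fusion multimodal survival stratification

`mmsurv` builds and evaluates prognostic models for right-censored survival
outcomes from four routine clinical data modalities — clinical variables,
rule-based genomic (HRD) status, radiomic feature tables, and interpretable
histopathology features — and integrates them by **late fusion**: each
modality trains its own Cox proportional-hazards submodel on *all* patients
with that modality available, and a small second-stage Cox model combines
the per-modality risk scores on the intersection set. The package is aimed
at biostatisticians and computational oncologists who want a tested,
reproducible implementation of this analysis pattern, exercisable end to
end on a synthetic multimodal cohort so that no protected patient data is
needed.

## The model

Each submodel is a linear Cox proportional-hazards model
*h(t | x) = h₀(t)·exp(βᵀx)* with L2 penalty (c = 0.5) on
training-standardized features, Efron tie handling. A patient's risk score
is the **negative log partial hazard** −βᵀx, so higher score = predicted
longer survival and an informative model has Harrell's c > 0.5.

Per-modality features are chosen by a selection cascade:

1. min–max scale each feature on the training split; drop features with
   scaled IQR < 0.1 (near-constant);
2. fit a univariate Cox model per feature without regularization; on
   convergence failure refit with L2 c = 0.2; if that fails assign
   log(HR) = 0, p = 1;
3. Benjamini–Hochberg FDR correction (radiomics, the largest feature
   space);
4. greedy multivariable pruning: walk candidates in increasing p-value
   order, keep a candidate only if it stays significant (p < α = 0.05) in
   the growing multivariable model — yielding a signature with low
   multicollinearity.

The genomic modality fits no parameters: homologous-recombination status is
called by an explicit rule engine (MSK-style and TCGA-style rule sets over
variant/copy-number/SBS3 evidence) and mapped HRP → risk 1.0, HRD → 0.0,
ambiguous → excluded.

The second-stage fusion model is a Cox fit over the per-modality scores of
the intersection set (one coefficient per modality). Evaluation uses
Harrell's c with 100-fold bootstrap CIs and 1000-fold permutation p-values,
Kaplan–Meier risk groups with a percentile-threshold search over
{0.33, …, 0.66} by training log-rank significance, Kendall τ-b cross-modal
concordance, and a one-sided Mann–Whitney U test against the ordinal
chemotherapy response score (CRS).

## Worked example

```python
from mmsurv import SimulationConfig, simulate_cohort
from mmsurv.pipeline import PipelineConfig, run_pipeline

cohort = simulate_cohort(SimulationConfig(seed=5))   # 444 patients
result = run_pipeline(cohort, PipelineConfig(seed=5, clinical_mode="replication"))
for tag, entry in result["combinations"].items():
    if "test" in entry:
        print(tag, round(entry["test"]["c_index"], 3))
```

prints (G = genomic, R = radiomic, H = histopathology, C = clinical):

```
G 0.586
R 0.654
H 0.644
C 0.532
RH 0.732
GRH 0.769
GRHC 0.771
```

Each number is the held-out-test Harrell c-index of that modality
combination. The single-modality models are modestly prognostic; fusing the
imaging modalities (RH) and adding genomics (GRH) improves test
concordance — the modalities carry complementary ordering information
(their pairwise Kendall τ on this cohort is near 0).

The same pipeline is scriptable from the shell:

```bash
mmsurv simulate --seed 5 --out cohort/
mmsurv run-all --cohort cohort/ --out reports/
mmsurv select --modality radiomic --cohort cohort/ --out signature.json
```

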