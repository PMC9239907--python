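# Methods

This note documents the statistical procedures implemented in `mmsurv`,
the design choices made where several reasonable definitions exist, and
what the synthetic study conditions do and do not establish.

## Survival model and risk convention

All fitted models are linear Cox proportional-hazards models with Efron
handling of tied event times (recorded in model metadata). Final unimodal
and fused models carry a fixed L2 penalty c = 0.5 and no L1 term. Because
an L2 penalty is scale-sensitive, `fit_submodel` standardizes features on
the training split (ddof-1 sample std, stored and inverted at prediction);
on that scale the maximized objective is exactly

    ll_Efron(β) − n · c · ‖β‖² / 2,

which is also the objective the test suite's brute-force optimizer checks
against. Risk scores are negative log partial hazards −βᵀx: higher score =
lower hazard, so concordance of an informative model exceeds 0.5 without
sign juggling. Second-stage fusion inputs are *not* re-standardized — they
are already on the log-hazard scale, which keeps the fusion coefficients
interpretable.

## Feature-selection cascade

Order of operations per modality, training split only: scaled-IQR filter →
univariate Cox → (radiomics only) Benjamini–Hochberg at q = α = 0.05 →
candidates significant at 95 % confidence, ordered by p → greedy
multivariable pruning.

* **Scaled IQR** is the interquartile range of the min–max-scaled feature
  (linear-interpolation quantiles). Min–max scaling was chosen over
  z-scoring or range division because it makes the 0.1 threshold unit-free
  and bounded; the choice is isolated in `selection.scaled_iqr`. Constant
  features have scaled IQR defined as 0 and are dropped. Scaling
  parameters are recorded for test-time reuse.
* **Univariate fits** are unregularized; a convergence failure triggers
  one refit at L2 c = 0.2; a second failure defaults the feature to
  log(HR) 0, p 1 (status `failed-defaulted`). A zero-variance feature
  cannot inform the partial likelihood and defaults immediately. For
  histopathology a specimen-size covariate can be added to every model
  (`control_covariate`); the reported statistics are always the feature's.
* **Greedy pruning** appends candidates in p order and keeps one only if
  its own coefficient is significant in the refitted multivariable model.
  These fits are unregularized *without* the fallback ladder: a
  regularized rescue would make an exactly collinear candidate look
  significant (verified numerically), whereas a collinear addition cannot
  improve the partial likelihood and must be rejected. Fit failures reject
  the candidate and are logged. Ties in candidate p-values break
  lexicographically for determinism.
* Modalities with fewer than 10 training events refuse to fit.

## HRD rule engine

Two rule sets, selected by an explicit `ruleset` parameter (never
auto-detected). MSK-style: HRD on high-confidence dominant SBS3 or ≥1
significant variant / deep deletion in the HRD-DDR gene set, unless CCNE1
amplification or a CDK12 SNV marks the foldback-inversion /
tandem-duplicator subgroups — HRD evidence plus subgroup evidence is a
conflict → ambiguous; unsequenced → ambiguous; otherwise HRP.
Low-confidence SBS3 is never used. Send-out HRD-DDR panels give HRP unless
the provider flagged a significant variant; significance always comes from
the input annotation (no re-annotation). TCGA-style: significant SNV/deep
deletion in HRD-DDR genes → HRD; co-occurring CDK12 SNV or CCNE1
amplification → ambiguous; else SBS3 frequency strictly above 15 % without
conflicting evidence → HRD; no SNV/CNA data → ambiguous. LST thresholding
is deliberately not part of either definition. The default HRD-DDR set is
a standard homologous-recombination panel (BRCA1/2, PALB2, RAD51B/C/D,
BRIP1, BARD1, ATM, CHEK2, FANCA) and is configurable; CDK12 and CCNE1 are
excluded from it because the rules use them as evidence *against* HRD.
Risk mapping: HRP → 1.0, HRD → 0.0, ambiguous → missing (excluded from all
genomic analyses). Every call records the ordered list of fired clauses.

## Histopathology features

Inputs are a per-pixel tissue-class map (tumor/stroma/necrosis/fat/
background) and a nucleus table with per-nucleus morphology and stain
statistics. Tissue-type features use `skimage` region properties
(moment-ellipse axes, eccentricity, solidity, perimeter) for both the
largest 8-connected component (connectivity configurable) and the union of
each class, plus all pairwise area ratios (missing, never infinite, when
the denominator class is absent). **Entropy of tumor/stroma** has no
single standard definition; here it is the mean Shannon entropy (bits) of
the tissue-class composition of fixed 64-px square patches restricted to
patches intersecting the class — 64 px matching the tile scale of typical
upstream tile classifiers. This is an interpretation and is flagged as
such. Nuclear aggregates are mean, population variance and deciles 10–90
(linear-interpolation quantiles) of area, diameter, circularity and stain
means, stratified by parent tissue {tumor, stroma, necrosis} × cell type
{all, lymphocyte, other}, plus per-parent lymphocyte fractions. A nucleus'
parent is the class of the pixel containing its centroid (floor; no
interpolation); background-parent nuclei are excluded. **Relative specimen
size** is implemented as the foreground (non-background) fraction of the
grid — whether a tile count or a physical area is meant elsewhere is not
derivable, so the bounded fraction was chosen. The full registry is the
cross-product above (versioned, deterministic order); the two classical
signature features — mean tumor nuclear area and stroma major axis
length — are guaranteed members.

## Evaluation

* Harrell's c over comparable pairs; tied scores count ½.
* 95 % CI by 100 patient-bootstrap resamples (percentile interval);
  resamples with no comparable pair are redrawn and logged. A
  leave-one-out jackknife mode is provided as an alternative, since
  "leave-one-out bootstrapping" admits both readings.
* Permutation p over 1000 risk-score permutations with the conservative
  (1 + k)/(n + 1) estimator, one-sided; p is never exactly 0.
* KM risk groups: percentile thresholds {0.33, 0.34, …, 0.66} are scored
  by training log-rank p; ties break to the threshold nearest 0.5, then
  the lower one; the winning cut is frozen as a raw score value and
  applied unchanged to test data. The search never touches test outcomes
  (asserted by an access-counting guard in the pipeline).
* Fraction surviving at t interpolates linearly between KM step corners.
* Cross-modal concordance: Kendall τ-b on per-modality risk quantiles,
  each computed within that modality's available set.
* CRS association: one-sided Mann–Whitney U, exact enumeration for
  combined n ≤ 20 without ties, normal approximation with tie correction
  otherwise.

## Synthetic study conditions

The generator's defaults emulate a 444-patient multimodal cohort:
600 radiomic-like and 216 histopathology-like features; availability 251/404
(radiomic), 243/404 (histopathology), 337/404 (sequenced) — so roughly a
third of patients carry full information; HRD prevalence 119/337 with a
log HR of 0.4 for HRP vs HRD tumors; OS from a Weibull
proportional-hazards baseline (shape 1 = exponential, scale 65 months,
i.e. ~45-month baseline median) and PFS from a 24-month scale;
independent exponential censoring with its rate solved by bisection to a
40 % censored fraction; clinical effects of residual disease (−0.3) and
PARP-inhibitor receipt (−0.2); a 3-level CRS observed in ~11 % of patients
whose distribution shifts with true risk. Planted prognostic features
default to one strong radiomic driver (log HR 1.0 per SD — a dominant
texture marker) and two moderate histopathology drivers (0.5 each),
mirroring a single-feature radiomic signature and a two-feature
histopathology signature. 26 % of features are near-constant
(zero-inflated) and fail the scaled-IQR filter by construction, so 444 of
600 radiomic features survive filtering. Remaining features are
block-equicorrelated Gaussians (blocks of 8, ρ = 0.5), which gives the
multivariable pruning real collinearity to remove; a `cross_modal_correlation`
knob can couple the planted blocks across modalities (default 0:
modalities carry independent signals, matching the low observed
cross-modal rank correlation).

Genomic evidence rows (variants, SBS3 status, panel) are generated
consistently with the true HRD label and passed through the rule engine,
so the observed call includes realistic ambiguity (unsequenced patients,
~1.5 % conflicting-evidence cases).

What the generator does **not** emulate: real radiomic/histologic feature
distributions (everything is Gaussian or zero-inflated), informative
censoring, non-proportional hazards, batch effects between scanners or
stains, and correlation between modality availability and outcome
(missingness is completely at random). Passing tests therefore establish
the correctness and internal consistency of the procedures under the
stated model, not clinical performance on real cohorts.

## Problem sizes used in the validation suite

The test battery uses scaled study sizes chosen to make each check
statistically decisive: exact-oracle checks on 20–1000 random small
instances; permutation-test calibration on 1000 null cohorts of n = 60
with 200 permutations; planted-effect recovery at n = 2000 over 10–20
seeds; the global-null false-selection rate on 250 cohorts of n = 140 with
20 features, asserted against the BH FDR guarantee plus a 99 % binomial
Monte-Carlo tolerance; fusion complementarity with planted log HR 0.4 per
modality (unimodal test c ≈ 0.60 by construction) on 1000 test patients ×
20 seeds; and the missing-data ablation at the default availability rates
on 504-patient cohorts with reduced feature blocks (40 + 30) × 20 seeds.
The ablation's restricted arm runs its selection without multiple-testing
correction (the full-information training set is small); an arm whose
selection retains nothing reports chance concordance 0.5.

## Known limitations

* The fallback ladder treats any optimizer exception as nonconvergence;
  it does not distinguish separation from ill-conditioning.
* The fusion stage requires a nonempty intersection set; no imputation of
  missing modality scores is attempted (by design — no robust
  cross-modality association exists to support it).
* Bootstrap CIs are percentile intervals; no BCa correction.
* The permutation test permutes risk scores against fixed outcomes and is
  one-sided; permuting outcome pairs instead would be equivalent in
  distribution but is not implemented.
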