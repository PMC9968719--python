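# Methods

This note documents the models and procedures implemented in `phosphostrat`,
the defaults chosen where the design was genuinely open, and what the
synthetic-data experiments do and do not demonstrate.

## Cohort model and synthetic data

The generator (`phosphostrat.simulate`) emulates a multi-centre AML cohort
with four groups: MLLGA and MLLGB (together the KMT2A-rearranged cases),
No-MLL (other poor-risk karyotypes) and Normal (healthy donors). Defaults are
8 / 4 / 20 / 4 — a 36-sample cohort whose geometry matches the study design
the pipeline targets (a training set of 36 gives the canonical 18-feature
signature; the 8-vs-4 split inside KMT2Ar mirrors the cluster-of-eight
subdivision the region step expects).

Phosphopeptide intensities are log2 values: per-feature baselines drawn from
Normal(22, 2) — a typical MS dynamic range; the baseline location is
irrelevant to every downstream statistic — plus independent Normal(0,
`noise_sd`) residuals, with `noise_sd = 0.5` log2 units by default. Exactly
`n_signature_features` (default 18) randomly chosen features are shifted by
`effect_size` (default 2.0 log2 units) in MLLGA samples only. Missingness is
completely at random at rate 0.1 by default; an intensity-dependent variant
(lower intensities more likely missing) is available but off, since no
missingness model is established for these data. Values without a stated
precedent (noise SD, missing rate, baseline spread) are single realistic
choices, exposed in `SimulationConfig`, and not tuned.

Kinase-substrate sets are sampled disjoint across kinases and never include
the planted signature features, so planted kinase-activity shifts (all
substrates of a chosen kinase shifted in a target group) are attributable.
Real substrate databases overlap heavily; disjointness is a deliberate
simplification that makes recovery experiments interpretable but optimistic.

The drug screen emulates a 384-well ex vivo viability assay: each drug ×
sample is measured at 5 concentrations in 10-fold dilutions from `conc_top`
(10 µM). Viability follows a log-logistic curve on a sample-specific IC50;
planted drugs are `potency_shift` (default 1.0) log10 units more potent in
MLLGA. Per sample the generator emits vehicle (DMSO) wells at day 0 and day
3, full-kill positive-control wells (signal 0 before noise), and treated
wells as `vehicle_day3 × viability/100`, all with multiplicative lognormal
noise (CV 0.1). MLLGA samples grow ~1.3× faster, so proliferation-based and
signature-based stratifications overlap but do not coincide — the structure
the stratification-comparison analysis requires.

All randomness derives from one seed through named `SeedSequence` child
streams; a cohort and its screen reproduce as a unit.

What passing tests on these data show: the statistics are implemented
correctly, calibrated under the null, and able to recover planted structure
at realistic effect sizes. What they do not show: robustness to batch
effects, intensity-dependent missingness, correlated features, overlapping
substrate sets or plate spatial artefacts, none of which the generator
produces.

## QC and normalization

QC consumes pre-computed boolean flags (mislabelled, high RBC, high T-cell,
low viability) and removes any flagged sample, reporting counts per reason; a
doubly-flagged sample is excluded once but counted under each reason. The
thresholds behind the flags are the caller's (a helper derives them from
numeric metadata columns) because no cytometry cut-offs are established
here. Normalization is per-sample median centering on observed values — a
transparent stand-in for upstream batch normalization, which this package
does not attempt; it preserves within-column differences exactly and never
imputes.

## Differential statistics

Two-group comparisons use the classic pooled-variance (Student) two-sided
t-test on observed values only (a Welch toggle exists). Features observed in
fewer than `min_obs = 3` samples per group are reported untested rather than
given a p-value; the threshold is exposed because no missingness rule is
canonical. Effect size is the difference of group means of log2 intensities.
Counting rules use strict inequalities (p < 0.05 and |log2 FC| > 0.8 or 0.7
depending on the analysis). FDR is Benjamini–Hochberg. Set enrichment is the
one-sided hypergeometric upper tail against a stated universe (all tested
features of the relevant layer), BH-adjusted across sets; the "modified"
EASE-style statistic of web enrichment tools is intentionally not
reproduced.

## Signature derivation and stratification

1. **Selection.** Training samples only; KMT2Ar vs all other karyotypes by
   t-test; features sorted by ascending p (ties: larger |log2 FC|, then
   feature id); top `k = ⌊n_train/2⌋` kept (override available). The
   half-the-training-set rule bounds model complexity by cohort size.
2. **PCA.** Fitted on training samples over the signature features. Missing
   cells are imputed with training-set feature means — a constant computed
   once from training data and reused for every projection, so new cohorts
   cannot shift the model.
3. **Region.** Ward hierarchical clustering (Euclidean) of the KMT2Ar
   training samples in (PC1, PC2), cut into two clusters. The clustering
   algorithm and the geometric notion of the MLLGA "area" are open design
   points; Ward/2-cut is the standard dendrogram subdivision, and the area is
   the convex hull of the larger cluster expanded outward by a margin
   (default 5% of the training PC1 range; square caps and mitred joins keep
   it a convex polygon, and degenerate hulls thicken into rectangles). The
   margin is the single transparent knob governing borderline samples.
4. **Classification.** Training samples are labelled by region membership;
   a random forest (1000 trees, fixed seed, bootstrap, out-of-bag accuracy
   reported) is trained on those labels over the signature features and
   reclassifies every sample. The forest's output is the authoritative final
   label (probability = fraction of trees voting MLLGA; ties at 0.5 go to
   MLLGA). Feature relevance is mean-decrease-in-impurity, normalized to sum
   to 1.

No-leakage is a hard invariant: selection, centering, imputation constants,
region and forest depend only on training samples, verified by perturbation
tests.

A note on null behaviour: when no signal exists, the derived labels are still
a deterministic function of the training data (clusters in the PCA of the
best-p features), so the forest's OOB accuracy on those labels stays well
above chance — that is circularity, not signal. The meaningful null check,
enforced in the tests, is that the derived split of KMT2Ar cases is
uncorrelated with any nominal subgroup labels (ARI ≈ 0).

## KSEA

For kinase K with m observed substrate scores S inside a score vector v:
`z(K) = (mean(S) − mean(v)) · √m / sd(v)` with sd the sample standard
deviation; two-sided normal p, BH across kinases; kinases with
m < `min_substrates` (default 3) are reported with null statistics. Per-sample
mode scores each sample's row-centered log2 intensities (its deviation from
the cohort mean profile); contrast mode scores a log2 fold-change vector.
The mean-enrichment z-score is the variant implemented; delta-count variants
are out of scope. Substrate sets are consumed at phosphopeptide-feature
granularity (GMT); mapping site-level databases onto quantified peptides is
the caller's responsibility.

## Dose-response and DSS

Inhibition is normalized per sample: `100·(vehicle − signal)/(vehicle −
positive)`, so vehicle wells sit at 0% and full-kill controls at 100%; a
plate whose vehicle mean does not exceed its positive-control mean is
rejected as dead. The curve model is a four-parameter log-logistic in log10
concentration with positive slope, fitted by bounded least squares (bottom ∈
[−10, 50], top ∈ [0, 120], slope ∈ [0.2, 10], IC50 within ±5 log units of the
window) from three fixed starts; `converged` is false when the optimizer
fails, the RMS residual exceeds 10 inhibition points, or the slope pins at a
bound, and any bound-pinned parameter is listed so poor fits are never
silent.

DSS integrates the fitted curve above an activity threshold t (default 10%)
over the tested window [x1, x2] (log10 of the lowest and highest dose),
in closed form:

    A    = ∫ over {x : y(x) ≥ t} (y(x) − t) dx
    DSS1 = 100·A / ((100 − t)·(x2 − x1))
    DSS2 = DSS1 · 100 / max(top, 1)        (default variant)

clipped to [0, 100]. The exact variant and threshold used by screening
facilities vary; both are parameters here, and the definitions above are this
package's fixed, fully-specified form of the normalized-area score.

Proliferation is reported exactly as the screen convention prints it,
`ratio = day0/day3 × 100` — note larger values mean slower growth — with
`growth_fold = day3/day0` provided alongside for interpretation.
Proliferation-based stratification thresholds at the arithmetic mean of a
reference group; samples at the mean go to "High pro" (documented tie rule).
Group comparisons of DSS use the same pooled t-test / BH machinery, with a
per-group `min_n = 5` filter (configurable) and an optional cohort-level
minimum-patients pre-filter.

## Correlation analyses

Spearman rho uses midranks. P-values switch by sample size: exact permutation
(full enumeration of n! orderings) for n ≤ 9, where the t-approximation is
poor and enumeration cheap; the t-approximation with n − 2 df otherwise.
Matrix correlations are pairwise-complete (missing pairs dropped per cell, n
reported); cells with fewer than `min_pairs = 5` pairs are untested, not
errors. No multiple-testing adjustment is applied inside correlation matrices
by default — matching per-test significance masks — with per-drug-row BH
available. Correlated-set extraction (features with p < α, split by sign)
feeds the enrichment machinery.

## Numerical choices and degenerate inputs

Ties in feature selection and importances break deterministically (feature
id); zero-variance t-tests return t = 0, p = 1 when means agree and p = 0
otherwise; KSEA on a zero-variance score vector and normalization of an
all-missing column raise degenerate-input errors naming the offender; BH
rejects p outside [0, 1]; region definition needs ≥ 3 points and a positive
margin when the hull is degenerate. Matrix TSV IO round-trips doubles exactly
(`%.17g` on write, correctly-rounded parsing on read) including the missing
mask.

## Problem sizes

Default experiments use 36-sample cohorts with 2000 phosphopeptides, 50
kinase sets of 10 substrates, and screens of tens of drugs at 5 doses —
sizes chosen to match the cohort geometry being emulated while keeping any
experiment reproducible on a laptop in seconds. Monte-Carlo checks use 100
replicates.

## Known limitations

Batch-effect estimation, peptide-to-protein rollup, survival analysis, plate
spatial corrections and drug-combination scoring are out of scope. The
enrichment test is a plain hypergeometric, not the modified EASE score of
DAVID-style tools. The generator's independence assumptions (features,
substrate sets, wells) make planted-recovery results upper bounds on
real-data performance.
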