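# Methods

`wlsig` re-implements, as a tested pipeline, a strategy for predicting
diet-induced weight-loss success from baseline adipose-tissue RNA-seq:
resampled differential expression feeds a GO enrichment map, whose
connected components yield small gene signatures that are evaluated as
linear-SVM classifiers against an empirical random-gene null. This note
records the model, the defaults, and the design decisions, in the order
the pipeline runs.

## Outcome definition

Overall weight loss is `WL% = 100 (w0 − w8)/w0` over an 8-month
intervention with weights measured at 0, 2 (end of the low-calorie
diet, LCD) and 8 months (end of maintenance). Within every sample
subset the binary outcome is the strict median split of WL%: high-WL
iff WL% > subset median. Labels are therefore subset-relative: training
and testing subsamples of a resampling run each use their own median.
Because the split is defined post-hoc, resampling cannot be stratified
by outcome.

## Resampling architecture

`make_resamples` draws `n_runs = 100` independent uniform 80/20
train/test splits (Monte-Carlo cross-validation). All models of a study
— signatures, combinations, clinical, hybrids, and the 100 random-gene
null sets — share one plan, so per-run AUC differences reflect features
only, not split noise. Within a run, *everything* that estimates
parameters (TMM factors, library sizes, batch adjustment, feature
standardization) is computed independently in the training and testing
subsamples; this unusual test-side normalization is deliberate and is
guarded by a poisoning test (altering test-subsample data must leave
every training-side artifact bit-identical).

## Normalization and batch adjustment

Genes with total count ≤ 5 across all samples are removed (strict
`> 5` filter). TMM factors follow the published trimmed-mean-of-M-values
recipe: reference = sample whose upper quartile of scaled counts is
closest to the mean upper quartile, 30% trim of log-ratios and 5% of
absolute intensities per tail, inverse-variance weights, factors
rescaled to geometric mean 1. The implementation was checked against
edgeR's `calcNormFactors` to 1e-6 during development and is tested
against a literal hand transcription of the recipe. Note that TMM is
only approximately invariant to rescaling one library: the
inverse-variance weights depend on absolute counts, so the test asserts
approximate (2e-2), not exact, invariance.

Expression features are `log2 CPM`: `log2((count + 0.5) /
(lib·TMM + 1) · 1e6)`, prior 0.5 so zeros stay finite.

Center (batch) effects are removed from the counts themselves by an NB
quantile-mapping scheme: per gene, an NB2 log-link regression with
center indicators plus sex and age covariates is fitted (method-of-
moments dispersion); each observation is mapped from its center-specific
fitted NB to the "center-free" NB obtained by replacing the center
indicators with their sample shares (CDF-matching, warm-started integer
walk). Sex and age terms are preserved, not removed. This is a
deliberately simplified scheme, not a port of ComBat-seq; its contract
is the recovery test (a planted ×2 center effect must flatten to within
10%) and idempotence. No library-size offset is used in this fit, so a
whole-batch depth shift is treated as a batch effect and removed.
Inside the per-run loop, library sizes and TMM factors are computed on
the *unadjusted* counts (the adjustment preserves totals to rounding),
and the quantile map is applied lazily to the genes a model actually
uses; this keeps the 100-run × 100-null-set loop to minutes without
changing any per-gene value.

## Differential expression

Per gene, an NB2 log-link GLM with class + sex + age (standardized) +
center indicators (reference = lexicographically first center) is
fitted by a vectorised IRLS with fixed per-gene dispersion, and the
class coefficient is tested with a two-sided Wald z. Dispersions are
method-of-moments estimates on size-factor-normalised counts, shrunk
25% toward a fitted `a0 + a1/mean` trend and floored at 1e-8. This
replaces DESeq2 (no lfc shrinkage, no outlier replacement, no
independent filtering) because the pipeline only consumes the DEG set
at nominal P < 0.01; the contract is calibration (type-I fraction at
0.01 within [0.005, 0.02] on null cohorts) and effect recovery, both
tested, plus coefficient agreement with `statsmodels` NB GLM to 1e-4
on toy genes. DE runs on raw counts with covariates in the model, not
on batch-adjusted counts.

## Enrichment map

Terms are flat gene sets (GMT); no GO DAG reasoning. The universe is
the filtered gene set of the training subsample. Over-representation
uses the upper-tail hypergeometric test (scipy, exact to rational
enumeration at N ≤ 30), BH correction, and a term is significant when
`P < 0.05 ∧ q < 0.2 ∧ q < 0.05` — the default `q < 0.2` and the
stricter `FDR < 0.05` are both applied, each independently
configurable. The map: pairs of significant terms with Jaccard ≥ 0.7
(on full annotated gene sets, not DEG-restricted overlaps) are
collapsed by iteratively dropping the larger-P term (ties by term id);
retained terms are joined by edges at Jaccard ≥ 0.2; connected
components (singletons included) are the candidate pathway classes.

## Signatures

Components are labelled by a keyword vote over term names
(case-insensitive substring; ties or zero matches → unlabeled). The
default keyword lists describe the lipid-metabolism, mitosis/meiosis
and response-to-virus classes; synthetic studies override them with
the planted module names. Within a run, the component's gene union is
standardized and decomposed by PCA; with d = the smallest number of
leading PCs whose cumulative explained variance reaches 0.70, each
gene's contribution is `Σ_{j≤d} λ_j ℓ²_{gj} / Σ_{j≤d} λ_j`
(eigenvalue-weighted squared loadings — the common "contrib"
convention; configurable to unweighted), and the top 10 genes are the
run's selection. Across runs, a gene's frequency is the percentage of
*all* runs featuring it (runs without the class count in the
denominator); the 10 most frequent genes form the class signature, ties
broken by mean within-run rank then gene id. Signatures combine by set
union (`A+B`) and difference (`A−B`); the evaluation phase forms these
combinations for the pair of discovered classes whose signatures share
the most genes (set-algebra models exist to probe inter-class gene
overlap), falling back to the two most-discovered classes when nothing
overlaps.

## Classification and inference

Features are the signature genes' adjusted log2-CPM values (clinical
factors append as extra columns), standardized with training
statistics; the classifier is a soft-margin linear SVM at cost 1
(libsvm via scikit-learn), scored by its continuous decision value.
AUC is computed by the rank-sum identity (ties count half); the DeLong
placement-value variance gives the 95% CI of the best run's AUC
(degenerate `[AUC, AUC]` under perfect separation, with a warning).
Runs whose test subset degenerates to one class are skipped and
counted, not imputed.

The null: 100 ten-gene sets drawn uniformly without replacement from
the filtered pool, evaluated on the same plan; the empirical P of a
model is the fraction of null sets with strictly higher median AUC —
no continuity correction, exactly as defined, so P = 0 is possible and
the granularity is 0.01.

## Clinical factors

Factors with |adjusted Fisher–Pearson skewness| > 1 are log_e-scaled
(shifted by `1 − min` first if non-positive; flags prevent
re-application). Sex/age adjustment is non-parametric in intent, not a
ComBat port: the linear age trend is residualised first (slope
estimated on sex-centred values so a sex offset cannot masquerade as an
age effect), then each sex stratum is aligned to the pooled median and
pooled within-stratum MAD. Ordering matters: aligning sex last makes
the stratum medians exactly equal; the reverse order lets the age
step re-introduce a sex difference (observed during development). The
baseline characteristics table uses unpaired two-sided t-tests
(log_e for skewed variables) and a chi-square without continuity
correction for sex. Hybrid models are compared to their expression-only
counterpart by a paired t-test on per-run AUCs plus the |ΔAUC| < 0.1
run classification (unchanged/improved/worsened).

## Trajectory diagnostics

Maintenance weight change is `100 (w2 − w8)/w0` — denominated in
baseline weight so the identity `overall = LCD + maintenance` is exact;
the regain threshold (> 4%) is applied on this scale (configurable to a
w2 denominator). Regainers are above-median overall losers with
maintenance below −4%. The Jonckheere–Terpstra test compares the
per-run regainer-in-training counts between runs with AUC ≤ 0.6 and
> 0.6 (alternative: decreasing burden in high-AUC runs). For pooled
n ≤ 12 the P is computed by full permutation enumeration; beyond that a
tie-corrected, continuity-corrected normal approximation is used. At
n = 12 the exact null is a coarse lattice (sd ≈ 6.6, CDF steps
0.03–0.06), so the normal approximation is only ±0.03-accurate there —
the reason the exact path exists and is the default at small n.

## Synthetic cohorts

The generator emulates the study's data structure, not adipose biology:

- **Counts**: NB2 with gene-wise dispersion `a0 + a1/mean`
  (default 0.05 + 2/mean, edgeR-style trend), gene baselines
  log2-normal (mean 5, sd 1.5 → median ≈ 32 counts), gene-specific
  center effects (log2 sd 0.1), small sex (sd 0.1) and age
  (sd 0.005/yr) effects, and per-sample depth noise (log2 sd 0.25).
  Planted modules shift module genes by their log2 effect in the
  high-WL class; the first two modules share a configurable fraction of
  the smaller module's genes (default 0.4, mirroring the lipid/virus
  gene sharing; at 0.5 with the default sizes the two module terms hit
  Jaccard 0.2 and merge into one map component, which is why 0.4 is the
  default).
- **Annotation**: one term per module plus two ≥ 0.7-Jaccard sibling
  terms each, padded with ≥ 50 random background terms (≥ 3 genes).
- **Weights**: baseline N(100, 15) kg truncated at 50; LCD and
  maintenance phase losses are class-conditional normals parameterised
  from the published group table (high: 12.3 ± 2.9 then +3.1 ± 2.5;
  low: 10.0 ± 1.9 then −4.2 ± 2.8, % of baseline), giving ≈ 15.4 vs
  5.8% overall and a ≈ 10% median split. A `regainer_fraction`
  (default 0.05) of high-WL samples instead gets a strong LCD
  (16.5 ± 1.5) followed by a > 4% rebound, so they stay above the
  overall median — the anomaly the diagnostics hunt for. With
  `regainer_fraction = 0` maintenance changes are clamped at ≥ +0.05%
  for everyone, making "no rebound at all" an exact guarantee rather
  than a distributional one.
- **Clinical**: 30 factors, 5 weakly informative (r = 0.25 with the
  class), 30% right-skewed (log-normal) to exercise the skewness rule.
- **Null cohorts**: identical expression machinery, but the label that
  drives the weights is an independent permutation, so every
  gene–outcome association is false by construction.

One seed fans out through `numpy.random.SeedSequence` children per
stage, so cohorts, plans and null draws are independently reproducible
and the whole study report is bit-stable.

What passing tests do *not* show about real data: the generator has no
GO topology beyond the planted overlap, no correlated gene networks
outside modules, no diet arms, no center-by-sex confounding, and
Gaussian weight phases rather than physiological dynamics. Recovery of
planted signatures here demonstrates the pipeline's correctness, not
the real-data effect size.

## Problem sizes

The synthetic study runs at n = 200 samples × 2,000 genes with 100
resampling runs and 100 null sets — large enough for stable AUC medians
and enrichment behaviour while keeping a full study under a few
minutes. Acceptance-style checks use the same scale; heavy
Monte-Carlo properties (DeLong coverage, type-I calibration) use
500/3,000 replicates respectively.

## Known limitations

- The NB Wald test is asymptotic; at very small n or extreme
  dispersions its calibration band is tested only at the study scale.
- The batch adjustment assumes the NB fit is adequate per gene; heavily
  zero-inflated genes would be mapped poorly (not generated here).
- Empirical P has granularity 1/100 and no continuity correction, so
  "P = 0" means "better than all 100 null sets", not zero probability.
- Real-data mode (TSV/MTX + GMT inputs) is supported but untested
  against the deposited cohort; no attempt is made to reproduce the
  published gene identities, which would require the real accession.
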