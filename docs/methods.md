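# Methods

## Overview

`egfr_msig` implements an expression-based classifier of EGFR mutation
status in lung adenocarcinoma (LUAD) — the *EGFR mutation signature*
(mSig) — together with the integrative analyses that give the signature its
meaning: cross-validated performance assessment, survival stratification at
a 36-month horizon, mutual-exclusivity testing of comutations, and a
rule-based subclassification of RAS-mutant tumors into EGFR-like (K-EGFR),
oxidative-stress-related (K-Ox), and TP53-associated (K-TP53) signaling
classes. Because the underlying clinical cohorts require controlled-access
downloads, a synthetic-cohort generator reproduces the statistical
structure the analysis assumes, at desk scale, so that every stage is
exercised end-to-end by code in this repository.

## The classifier

### Gene ranking

Genes are ranked by the SAM d-statistic against EGFR mutation status:

    d_g = (mean_mt,g − mean_wt,g) / (s_g + s0)

where `s_g = sqrt((1/n1 + 1/n2) · SS_within / (n1 + n2 − 2))` is the pooled
two-class scale and `s0 ≥ 0` is the exchangeability ("fudge") constant that
damps the otherwise explosive statistics of low-variance genes. Three `s0`
policies are provided: a fixed constant (default 0, since the pipeline uses
the ranks and not an FDR), the median of the per-gene scales, and a
percentile scan that evaluates `s0` candidates at the 0,5,…,100th
percentiles of `s_g` and keeps the candidate minimizing the coefficient of
variation of the median |d| across ten equal-count scale bins. A
pooled-variance two-sample t ranking (`ttest_rank`) is provided as the
feature-selection route used by generic machine-learning classifiers; ties
break deterministically by |t| and then gene id, so model files are
reproducible.

### Selection, centroids, and the mSig score

The signature takes the top `n_up` genes by descending d (overexpressed in
mutants) and the top `n_down` by ascending d (underexpressed), disjoint by
construction. Defaults are 690 up / 330 down = 1,020 genes, carried over
from the full-scale design; the desk-scale analyses use 101/49 = 150, the
same 690:330 proportion at the synthetic signature size. Class centroids
are unshrunken per-gene class means; the per-gene scale is the pooled
within-class SD computed with the total-n denominator
(`sqrt(SS_within / (n1 + n2))`), floored at 1e-6. Genes whose fitted
centroids contradict their requested direction are dropped with a warning,
and the model records the realized counts.

A sample x is scored by standardized squared distance to each centroid,
averaged over the genes available:

    dist_k(x) = (1/m) Σ_g ((x_g − c_k,g)/s_g)² − 2·ln(2·π_k)/m
    msig_score(x) = dist_wt(x) − dist_mt(x)

with m the number of model genes present and π_k the class priors (equal
by default, making the prior term vanish; the factor 2 inside the log is a
normalization so equal priors contribute exactly zero, and it cancels in
the score). Averaging over m keeps scores comparable when a validation
platform lacks part of the gene space. The call is mSig+ iff the score
strictly exceeds the threshold (default 0); ties therefore resolve to
mSig−, the conservative direction for a high-specificity positive call.
Classification is exactly invariant under gene-wise affine transforms
applied consistently to samples and model, which is what makes the
harmonization step safe.

### Cross-platform harmonization

`harmonize_gene_space` subsets a cohort to the model genes present
(requiring at least 50% coverage by default), re-applies the training
normalization recipe within the cohort, and reports the missing genes. The
default recipe — per-gene median centering followed by per-gene z-scoring —
is a within-cohort standardization, so a platform's gene-wise additive
offsets and positive scale distortions cancel exactly. Validation cohorts
are therefore standardized within-cohort rather than to training statistics;
this is the documented default and the alternative would only matter for
recipes that are not gene-wise.

## Normalization

Three steps compose into a declared recipe: median centering (per gene),
z-scoring (per gene, sample SD; constant genes are zeroed with a warning
rather than raising), and quantile normalization across samples using the
mean-of-order-statistics reference, with ties within a column receiving the
mean of the reference values their ranks span — the convention of the
standard Bioconductor implementation. Quantile normalization is idempotent
to 1e-12 and all steps preserve ranks within the unit they operate on.
Raw-array processing (Lowess, RMA) is out of scope; the recipe is recorded
in the model file for provenance.

## Evaluation conventions

Confusion counts follow the mutation-vs-signature convention: EGFR-mt/mSig+
is a true positive, WT/mSig− a true negative, WT/mSig+ a false positive,
and EGFR-mt/mSig− a false negative. Undefined ratios (zero denominators)
are reported as NaN with a warning, never as 0. AUROC is the Mann-Whitney
probability with ties counted one half. Cross-validation is stratified
(seeded scikit-learn folds) and repeats ranking, selection, and centroid
fitting inside every training fold; out-of-fold calls are pooled and scored
once. A regression test demonstrates that moving gene selection outside the
folds visibly inflates AUROC on label-permuted data while the guarded
pipeline stays near chance.

## RAS subclassification

For RAS-mutant samples (any canonical KRAS/NRAS/HRAS activating call;
a KRAS-only restriction is a caller-side filter on the annotation), rules
apply in precedence order:

1. mSig+ → K-EGFR;
2. mSig− and (STK11-mt or KEAP1-mt) → K-Ox;
3. mSig− and TP53-mt → K-TP53;
4. otherwise unclassified.

The signature is the primary axis, so K-EGFR wins all conflicts; the
metabolic clause precedes the TP53 clause because STK11/KEAP1 lesions tie a
tumor to the oxidative-stress program mechanistically, whereas TP53
comutation is frequent across contexts. No published precedence exists for
the mSig−/TP53+STK11 double-mutant case, so this ordering is a design
choice of this package, recorded per-sample in a `rule_fired` trace that
reconstructs each decision. DUSP4 expression is reported alongside the
classes where available but never enters the rule, since the signaling
claim it supports is a pattern, not a threshold.

## Survival

Overall survival runs from diagnosis to death from any cause;
administrative censoring truncates follow-up at 36 months (configurable).
KM curves, the k-group log-rank test, and the Cox proportional-hazards
model (categorical group covariate, Efron tie handling, likelihood-ratio
test against the null model, df = k−1) stand on lifelines. Time is in
months end-to-end. The package checks its survival stack against
hand-worked product-limit and observed-minus-expected oracles and verifies
Cox LRT type-I error calibration on 500 null simulations.

## Association statistics

Fisher's exact test (two-sided, summing hypergeometric probabilities no
greater than the observed table's) with the Haldane-Anscombe +0.5 odds-ratio
correction when a cell is zero (flagged); Pearson chi-square without
continuity correction; classical one-way ANOVA. All are scipy-backed, with
enumeration and direct-summation oracles in the tests.

## The synthetic-cohort generator

The generator emulates, at desk scale, the structure the analysis assumes:

- **Cohort size and prevalence.** 200 samples × 1,000 genes per cohort,
  EGFR-mutant prevalence 0.15, RAS-mutant prevalence 0.30 among wild-type —
  the order of the real training cohort (~190 samples, ~15% mutant).
- **Signature.** 150 planted genes (101 up / 49 down, the 690:330
  proportion) shifted by ±2 SD in carriers, on unit-variance Gaussian
  noise. Carriers are all EGFR mutants except a configurable 80% of mutants
  in the magnoid stratum (planted false negatives, reflecting the observed
  scarcity of mSig+ among magnoid mutants), plus 40% of RAS mutants, who
  receive the *identical* planted shift — one shared signature, not two.
  There is no quantitative published false-negative or carrier rate for
  these groups; the defaults are free parameters chosen once as plausible
  and documented as such.
- **Subtypes.** Three strata (bronchioid/magnoid/squamoid at 45/25/30%
  marginally) with 30-gene lineage-marker blocks shifted +1.5 SD; signature
  carriers draw a bronchioid-heavy subtype distribution (75/10/15%),
  producing the bronchioid enrichment of mSig+ without hard-coding it.
- **Comutations** are drawn per subtype: TP53 at 0.92 in squamoid (the
  reported >90%), STK11/KEAP1 enriched in magnoid (the 19p-depleted
  profile), CDKN2A intermediate. Empirical frequencies converge to the
  table (verified at n=5,000 within 3 binomial SDs).
- **Survival** is exponential (baseline 0.012/month, roughly a 65% 3-year
  survival for carriers) with the non-carrier hazard multiplied by 2.5,
  uniform censoring on (0, 60] months, and administrative censoring applied
  downstream at 36 months.
- **Platform shift** re-expresses a cohort with per-gene additive offsets
  (SD = `shift_sd`) and log-normal positive scale jitter shared by all
  samples, relabelling the platform.

What the generator does *not* emulate: probe-level array physics, count
noise of RNA-seq, gene-gene correlation beyond the planted blocks,
expression-coupled comutation effects, and non-proportional hazards.
Passing tests therefore demonstrate the pipeline's correctness and its
behavior under the assumed structure, not the real-data performance
figures, which require the original cohorts.

## Problem sizes and determinism

The default study conditions — 200-sample cohorts, 1,000 genes, 20
replicates for recovery/NPV/null-AUROC summaries, 500 null simulations for
Cox calibration, exact-test enumeration over all 2×2 tables with margins
≤ 12 — were chosen so the whole pipeline, test suite, and acceptance script
run in minutes on one CPU while keeping the Monte-Carlo summaries stable to
well under their acceptance margins. Every stochastic component takes an
explicit seed (simulation configs, fold assignment, the acceptance script's
`--seed`), and all tie-breaks are deterministic, so repeated runs are
bit-identical.

## Known limitations

- Real cohorts (GEO/TCGA) are not downloaded or processed; the published
  real-data performance values are not reproduced here.
- The per-class active-gene accounting of the original nearest-centroid
  selection method has variants; the signed-rank split implemented here is
  the documented default.
- Whether the original training sensitivity/specificity were resubstitution
  or cross-validated is ambiguous; both modes are available
  (`classify` on the training matrix vs `cross_validate`).
- Quantile normalization is within-cohort only; no cross-cohort reference
  distribution is maintained when merging cohorts.
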