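# egfr-msig

Expression-based classification of EGFR-mutant-like lung adenocarcinoma
(LUAD), and the integrative analyses built on it.

Identical driver mutations can signal differently depending on comutations
and lineage context, and many LUAD patients remain "oncogene-negative"
under mutation-only taxonomies. This package implements the *EGFR mutation
signature* (mSig) approach to that problem: a nearest-centroid classifier
trained on the transcriptional footprint of EGFR kinase mutations, which —
applied back to a cohort — identifies EGFR-wild-type tumors with
mutant-like signaling (mSig+), stratifies 3-year survival, and splits
RAS-mutant tumors into EGFR-like (K-EGFR), oxidative-stress-related (K-Ox),
and TP53-associated (K-TP53) signaling classes.

It is written for computational biologists who want a tested, reusable
implementation of the method: the library (`src/egfr_msig/`) carries every
computational step, numbered scripts under `analysis/` run the full
narrative on synthetic cohorts, and a CLI (`egfr-msig`) exposes each stage.

## The method

Genes are ranked by the SAM d-statistic for EGFR-mutant vs wild-type:

    d_g = (x̄_mt,g − x̄_wt,g) / (s_g + s0)

with s_g the pooled two-class scale and s0 the exchangeability constant.
The signature takes the top n_up genes with d > 0 and top n_down with
d < 0 (defaults 690/330 = 1,020 genes; 101/49 = 150 at the desk-scale
synthetic size), fits unshrunken class centroids c_mt, c_wt and pooled
within-class scales s_g, and scores a sample by

    mSig score(x) = (1/m) Σ_g [ ((x_g−c_wt,g)/s_g)² − ((x_g−c_mt,g)/s_g)² ]

calling mSig+ when the score exceeds 0. Calls feed three downstream layers:
confusion metrics/AUROC against mutation status (mutant mSig+ = true
positive), Kaplan-Meier / log-rank / Cox LRT survival contrasts at a
36-month horizon, and the rule-based RAS subclassification
(mSig+ → K-EGFR; mSig− + STK11/KEAP1 → K-Ox; mSig− + TP53 → K-TP53).

The real study cohorts require controlled-access downloads, so a
synthetic-cohort generator (`egfr_msig.simulate`) reproduces the assumed
structure — subtype lineage blocks, a planted multi-gene signature shared
by EGFR mutants and a RAS-mutant subgroup, subtype-dependent comutations,
platform batch shifts, and signature-coupled survival — making every stage
testable at desk scale. See `docs/methods.md` for model details and
parameter rationale.

## Worked example

```bash
python analysis/01_simulate_cohorts.py     # training + validation cohorts
python analysis/02_train_signature.py      # SAM ranking + centroid model
python analysis/03_evaluate_classifier.py  # CV, held-out, cross-platform
python analysis/04_integrate_subtypes.py   # RAS classes, comutations
python analysis/05_survival.py             # 36-month KM / log-rank / Cox
```

Output of the run at the default seed:

```
training: 200 samples, 27 EGFR-mt, 48 signature carriers
model: 101 up + 49 down genes; planted-gene recovery 150/150 (100.0%)
validation: AUROC=0.836 sens=0.83 spec=0.84 PPV=0.47 NPV=0.966
validation_platformB: AUROC=0.836 sens=0.83 spec=0.84 PPV=0.47 NPV=0.966
cross-validation: AUROC=0.873 NPV=0.987 (10 folds)
RAS classes: {'not_RAS_mutant': 136, 'K_EGFR': 28, 'K_Ox': 14, 'RAS_unclassified': 12, 'K_TP53': 10}
mSig+ vs keap1_mutant: OR=0.10 p=0.006 (exclusive)
mSig+ fraction by subtype: {'bronchioid': 0.35, 'magnoid': 0.08, 'squamoid': 0.23}
egfr_mt_vs_wt: log-rank chi2=1.19 (df=1) p=0.274; Cox LRT p=0.255
msig_three_group: log-rank chi2=14.46 (df=2) p=0.001; Cox LRT p=0.000
```

Reading this: the classifier recovers the planted 150-gene signature
exactly and carries the expected asymmetric profile — high negative
predictive value (0.97–0.99) with modest PPV, because mSig+ deliberately
captures RAS-mutant tumors with EGFR-like signaling (the 28 K-EGFR calls)
as "false" positives against mutation truth. Performance is unchanged on
the batch-shifted platform after harmonization. mSig+ concentrates in the
bronchioid-like subtype and is mutually exclusive with KEAP1/STK11
comutation; and while EGFR mutation alone separates survival weakly, the
3-group mSig stratification separates strongly, with the wild-type mSig+
group tracking the favorable mutant-like outcome.

Each stage is also available as a CLI subcommand over TSV/JSON artifacts
(`egfr-msig simulate|preprocess|train|classify|evaluate|integrate|survival`),
e.g.:

```bash
egfr-msig simulate --seed 7 --out-prefix cohort
egfr-msig train --expression cohort.expression.tsv \
    --annotation cohort.annotation.tsv --model msig.json
```

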