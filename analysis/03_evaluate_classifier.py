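#!/usr/bin/env python
"""Evaluate the trained mSig classifier.

Three views of performance against EGFR mutation status, using the
mutation-vs-signature confusion convention (mutant mSig+ = true positive):

  1. 10-fold cross-validation on the training cohort, with gene ranking,
     selection, and centroid fitting repeated inside each fold;
  2. held-out classification of the same-platform validation cohort;
  3. held-out classification of the batch-shifted platform-B copy after
     gene-space harmonization.

Writes per-view metrics JSON and the per-sample calls for downstream
stages.
"""

import argparse
import json
import os

import numpy as np

import egfr_msig as em
from egfr_msig.clanc import results_to_frame

RECIPE = ("median_center_genes", "zscore_genes")


def held_out_metrics(expr_path, ann_path, model):
    matrix = em.read_expression(expr_path)
    annotations = em.read_annotation(ann_path)
    harmonized, missing = em.harmonize_gene_space(matrix, model)
    results = em.classify(harmonized, model)
    calls = [r.msig_call == "mSig+" for r in results]
    truth = [a.egfr_mutant for a in annotations]
    report = em.confusion_metrics(calls, truth)
    report.auroc = em.auroc([r.msig_score for r in results], truth)
    return report, results, missing


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=7)
    parser.add_argument("--cohorts", default="results/cohorts")
    parser.add_argument("--model", default="results/model/msig_model.json")
    parser.add_argument("--outdir", default="results/evaluation")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    model = em.read_signature_model(args.model)
    config = em.PipelineConfig(n_signature_genes=150, n_up=101, n_down=49,
                               seed=args.seed)

    train_matrix = em.apply_recipe(
        em.read_expression(os.path.join(args.cohorts, "training.expression.tsv")),
        RECIPE,
    )
    train_ann = em.read_annotation(
        os.path.join(args.cohorts, "training.annotation.tsv")
    )
    labels = np.array([a.egfr_mutant for a in train_ann])
    cv = em.cross_validate(train_matrix, labels, config)

    summary = {"cross_validation": cv.to_dict()}
    for name in ("validation", "validation_platformB"):
        report, results, missing = held_out_metrics(
            os.path.join(args.cohorts, f"{name}.expression.tsv"),
            os.path.join(args.cohorts, f"{name}.annotation.tsv"),
            model,
        )
        summary[name] = report.to_dict()
        summary[name]["n_model_genes_missing"] = len(missing)
        results_to_frame(results).to_csv(
            os.path.join(args.outdir, f"{name}.calls.tsv"), sep="\t", index=False
        )
        print(
            f"{name}: AUROC={report.auroc:.3f} sens={report.sensitivity:.2f} "
            f"spec={report.specificity:.2f} PPV={report.ppv:.2f} "
            f"NPV={report.npv:.3f}"
        )
    print(
        f"cross-validation: AUROC={cv.auroc:.3f} NPV={cv.npv:.3f} "
        f"({len(cv.fold_metrics)} folds)"
    )
    with open(os.path.join(args.outdir, "metrics.json"), "w") as handle:
        json.dump(summary, handle, indent=1)
    print(f"wrote metrics + calls to {args.outdir}/")


if __name__ == "__main__":
    main()
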