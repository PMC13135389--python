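#!/usr/bin/env python
"""Integrative layer: RAS subclassification and comutation structure.

Joins validation-cohort mSig calls with the annotation table to (1) assign
every RAS-mutant sample to K-EGFR / K-Ox / K-TP53, (2) test mSig status
against each comutation with Fisher's exact odds ratios, (3) test the
subtype x mSig association by chi-square, and (4) build the subtype-by-
oncogene-class framework cross-tab.
"""

import argparse
import os

import pandas as pd

import egfr_msig as em
from egfr_msig.clanc import ClassificationResult
from egfr_msig.containers import annotation_frame


def load_calls(path):
    frame = pd.read_csv(path, sep="\t")
    return [
        ClassificationResult(
            sample_id=str(r.sample_id),
            msig_score=float(r.msig_score),
            msig_call=str(r.msig_call),
            distance_mt=float(r.distance_mt),
            distance_wt=float(r.distance_wt),
        )
        for r in frame.itertuples(index=False)
    ]


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--cohorts", default="results/cohorts")
    parser.add_argument(
        "--calls", default="results/evaluation/validation.calls.tsv"
    )
    parser.add_argument("--outdir", default="results/integration")
    args = parser.parse_args()
    os.makedirs(args.outdir, exist_ok=True)

    annotations = em.read_annotation(
        os.path.join(args.cohorts, "validation.annotation.tsv")
    )
    results = load_calls(args.calls)
    ras = em.assign_ras_classes(annotations, results)
    pd.DataFrame([vars(r) for r in ras]).to_csv(
        os.path.join(args.outdir, "ras_classes.tsv"), sep="\t", index=False
    )
    counts = pd.Series([r.ras_class for r in ras]).value_counts()
    print("RAS classes:", dict(counts))

    ann = annotation_frame(annotations)
    msig_pos = ann["sample_id"].map(
        {r.sample_id: r.msig_call == "mSig+" for r in results}
    ).astype(bool)
    rows = []
    for gene in ("tp53_mutant", "stk11_mutant", "keap1_mutant", "cdkn2a_altered"):
        flag = ann[gene].astype(bool)
        table = [
            [int((msig_pos & flag).sum()), int((msig_pos & ~flag).sum())],
            [int((~msig_pos & flag).sum()), int((~msig_pos & ~flag).sum())],
        ]
        assoc = em.fisher_or(table)
        rows.append(
            {
                "alteration": gene,
                "odds_ratio": assoc.odds_ratio,
                "p_value": assoc.p_value,
                "correction_applied": assoc.correction_applied,
            }
        )
        direction = "exclusive" if assoc.odds_ratio < 1 else "co-occurring"
        print(
            f"mSig+ vs {gene}: OR={assoc.odds_ratio:.2f} "
            f"p={assoc.p_value:.2g} ({direction})"
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(args.outdir, "msig_comutation_associations.tsv"),
        sep="\t", index=False,
    )

    subtype_table = pd.crosstab(ann["subtype"], msig_pos)
    chi = em.chi_square_association(subtype_table.to_numpy())
    print(
        f"subtype x mSig: chi2={chi.statistic:.1f} (df={chi.dof}) "
        f"p={chi.p_value:.2g}"
    )

    framework = em.summarize_framework(annotations, results, ras)
    framework.to_csv(os.path.join(args.outdir, "framework_crosstab.tsv"), sep="\t")
    print(
        "mSig+ fraction by subtype:",
        {k: round(v, 2) for k, v in framework["msig_pos_fraction"].items()},
    )
    print(f"wrote integration tables to {args.outdir}/")


if __name__ == "__main__":
    main()
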