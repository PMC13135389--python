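"""Rule-based RAS subclassification and association testing.

RAS-mutant tumors are split by their signaling context: K-EGFR when they
carry the EGFR-like expression signature (mSig+), K-Ox when mSig− with
STK11 and/or KEAP1 comutation (metabolic/oxidative-stress axis), K-TP53
when mSig− with TP53 mutation, and unclassified otherwise.  Precedence is
K-EGFR > K-Ox > K-TP53: the signature is the primary axis, and the
metabolic clause wins conflicts because STK11/KEAP1 lesions tie those
tumors to the oxidative-stress program mechanistically.

Association testing wraps the field-standard exact and asymptotic tests
(Fisher's exact with a Haldane-Anscombe-corrected odds ratio, Pearson chi
square without continuity correction, classical one-way ANOVA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import math

import numpy as np
import pandas as pd
from scipy import stats

from .containers import CohortAnnotation, annotation_frame
from .clanc import ClassificationResult
from .exceptions import JoinError

RAS_CLASSES = ("K_EGFR", "K_Ox", "K_TP53", "RAS_unclassified", "not_RAS_mutant")


@dataclass
class RasClassLabel:
    """Per-sample RAS class with the rule clause that fired."""

    sample_id: str
    ras_class: str
    rule_fired: str


@dataclass
class AssociationResult:
    """2x2 (or r x c) association: odds ratio, p-value, and provenance."""

    table: np.ndarray
    odds_ratio: float
    p_value: float
    test: str
    correction_applied: bool = False
    statistic: float = math.nan
    dof: int = 0


def assign_ras_class(
    annotation: CohortAnnotation, msig: ClassificationResult
) -> RasClassLabel:
    """Classify one RAS-mutant sample into K-EGFR / K-Ox / K-TP53.

    Total over valid inputs; non-RAS-mutant samples are passed through as
    ``not_RAS_mutant``.
    """
    if annotation.sample_id != msig.sample_id:
        raise JoinError(
            f"annotation sample {annotation.sample_id!r} does not match "
            f"classification sample {msig.sample_id!r}"
        )
    if not annotation.ras_mutant:
        return RasClassLabel(annotation.sample_id, "not_RAS_mutant", "not RAS-mutant")
    positive = msig.msig_call == "mSig+"
    if positive:
        return RasClassLabel(annotation.sample_id, "K_EGFR", "mSig+ -> K-EGFR")
    if annotation.stk11_mutant or annotation.keap1_mutant:
        lesions = [
            name
            for name, flag in (("STK11", annotation.stk11_mutant),
                               ("KEAP1", annotation.keap1_mutant))
            if flag
        ]
        return RasClassLabel(
            annotation.sample_id, "K_Ox", f"mSig- and {'/'.join(lesions)} -> K-Ox"
        )
    if annotation.tp53_mutant:
        return RasClassLabel(annotation.sample_id, "K_TP53", "mSig- and TP53 -> K-TP53")
    return RasClassLabel(
        annotation.sample_id, "RAS_unclassified", "mSig- with no qualifying comutation"
    )


def assign_ras_classes(
    annotations: Sequence[CohortAnnotation],
    results: Sequence[ClassificationResult],
) -> list[RasClassLabel]:
    """Vectorized convenience over matched annotation/classification lists."""
    by_sample = {r.sample_id: r for r in results}
    missing = [a.sample_id for a in annotations if a.sample_id not in by_sample]
    if missing:
        raise JoinError(f"no mSig call for sample(s): {missing[:5]}")
    return [assign_ras_class(a, by_sample[a.sample_id]) for a in annotations]


def fisher_or(table: Sequence[Sequence[int]]) -> AssociationResult:
    """Two-sided Fisher exact p and the odds ratio for a 2x2 table.

    The p-value sums hypergeometric probabilities no greater than that of
    the observed table.  When any cell is zero the odds ratio uses the
    Haldane-Anscombe +0.5 correction and the flag is set.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError(f"need a non-negative 2x2 table, got shape {t.shape}")
    if not np.allclose(t, np.round(t)):
        raise ValueError("table cells must be integers")
    t = t.astype(int)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    a, b, c, d = t.ravel()
    corrected = 0 in (a, b, c, d)
    if corrected:
        a, b, c, d = (x + 0.5 for x in (a, b, c, d))
    odds = (a * d) / (b * c) if (b * c) != 0 else math.inf
    return AssociationResult(
        table=t,
        odds_ratio=float(odds),
        p_value=float(min(p, 1.0)),
        test="fisher_exact",
        correction_applied=corrected,
    )


def chi_square_association(contingency: Sequence[Sequence[int]]) -> AssociationResult:
    """Pearson chi-square (no continuity correction) on an r x c table."""
    t = np.asarray(contingency, dtype=float)
    if t.ndim != 2 or (t < 0).any():
        raise ValueError("need a non-negative 2-D contingency table")
    expected = stats.contingency.expected_freq(t)
    if (expected == 0).any():
        raise ValueError("chi-square undefined: a cell has expected count 0")
    stat, p, dof, _ = stats.chi2_contingency(t, correction=False)
    odds = math.nan
    if t.shape == (2, 2) and t[0, 1] * t[1, 0] > 0:
        odds = float((t[0, 0] * t[1, 1]) / (t[0, 1] * t[1, 0]))
    return AssociationResult(
        table=t.astype(int),
        odds_ratio=odds,
        p_value=float(p),
        test="chi_square",
        statistic=float(stat),
        dof=int(dof),
    )


def anova_expression_by_group(
    values: Sequence[float], groups: Sequence[str]
) -> tuple[float, float]:
    """Classical one-way ANOVA F and p for expression across groups."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    arrays = [values[groups == g] for g in pd.unique(groups)]
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    singleton = [g for g, arr in zip(pd.unique(groups), arrays) if len(arr) < 2]
    if singleton:
        raise ValueError(f"group(s) with fewer than 2 members: {singleton}")
    f, p = stats.f_oneway(*arrays)
    return float(f), float(p)


def summarize_framework(
    annotations: Sequence[CohortAnnotation],
    results: Sequence[ClassificationResult],
    ras_classes: Sequence[RasClassLabel],
) -> pd.DataFrame:
    """Cross-tab of subtype x oncogene class with per-subtype proportions.

    Rows are subtypes; for each oncogene class column the table reports the
    count and the within-subtype proportion, plus the subtype's mSig+
    fraction.
    """
    ann = annotation_frame(annotations)
    calls = pd.DataFrame([vars(r) for r in results]).set_index("sample_id")
    ras = pd.DataFrame([vars(r) for r in ras_classes]).set_index("sample_id")
    unmatched = sorted(
        set(ann.index).symmetric_difference(calls.index)
        | set(ann.index).symmetric_difference(ras.index)
    )
    if unmatched:
        raise JoinError(f"unmatched sample id(s): {unmatched[:5]}")
    joined = ann.join(calls[["msig_call"]]).join(ras[["ras_class"]])

    def oncogene_class(row) -> str:
        if row.egfr_mutant:
            return "EGFR_mt"
        if row.ras_class != "not_RAS_mutant":
            return row.ras_class
        return "oncogene_negative"

    joined["oncogene_class"] = joined.apply(oncogene_class, axis=1)
    counts = pd.crosstab(joined["subtype"], joined["oncogene_class"])
    proportions = counts.div(counts.sum(axis=1), axis=0)
    proportions.columns = [f"prop_{c}" for c in proportions.columns]
    msig_frac = (
        joined.assign(msig_pos=joined["msig_call"] == "mSig+")
        .groupby("subtype")["msig_pos"]
        .mean()
        .rename("msig_pos_fraction")
    )
    table = pd.concat([counts, proportions, msig_frac], axis=1)
    table.insert(0, "n", counts.sum(axis=1))
    return table
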