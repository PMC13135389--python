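"""Performance assessment of mSig calls.

Confusion counts follow the mutation-vs-signature convention: an
EGFR-mutant sample called mSig+ is a true positive, a wild-type sample
called mSig− a true negative, a wild-type mSig+ a false positive, and a
mutant mSig− a false negative.  AUROC is the Mann-Whitney probability with
ties counted one half.  Cross-validation is stratified and performs gene
ranking, selection, and centroid fitting inside each training fold so no
information leaks into the held-out calls.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .config import PipelineConfig
from .containers import ExpressionMatrix
from . import clanc, sam


@dataclass
class PerformanceReport:
    """Confusion counts, derived fractions, AUROC, and per-fold copies."""

    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    accuracy: float
    auroc: float = math.nan
    fold_metrics: list = field(default_factory=list)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator); reported as NaN",
                      stacklevel=3)
        return math.nan
    return num / den


def confusion_metrics(
    calls: Sequence[bool], truth: Sequence[bool], seed: int = 0
) -> PerformanceReport:
    """Score boolean mSig+ calls against boolean mutant truth."""
    calls = np.asarray(calls, dtype=bool)
    truth = np.asarray(truth, dtype=bool)
    if calls.shape != truth.shape:
        raise ValueError(
            f"calls length {calls.shape} != truth length {truth.shape}"
        )
    tp = int((calls & truth).sum())
    fp = int((calls & ~truth).sum())
    tn = int((~calls & ~truth).sum())
    fn = int((~calls & truth).sum())
    return PerformanceReport(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        sensitivity=_ratio(tp, tp + fn, "sensitivity"),
        specificity=_ratio(tn, tn + fp, "specificity"),
        ppv=_ratio(tp, tp + fp, "PPV"),
        npv=_ratio(tn, tn + fn, "NPV"),
        accuracy=_ratio(tp + tn, tp + fp + tn + fn, "accuracy"),
        seed=seed,
    )


def auroc(scores: Sequence[float], truth: Sequence[bool]) -> float:
    """Area under the ROC curve: P(score_pos > score_neg) with ½ for ties."""
    truth = np.asarray(truth, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if truth.all() or not truth.any():
        raise ValueError("AUROC needs both classes present in truth")
    return float(roc_auc_score(truth.astype(int), scores))


def train_signature(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    config: PipelineConfig,
    sam_params: sam.SamParams | None = None,
) -> clanc.SignatureModel:
    """Rank genes by SAM d, split top up/down sets, fit centroids.

    When the matrix holds fewer genes than the configured 1,020-gene
    signature, the up/down counts are scaled down proportionally (the
    690:330 asymmetry is preserved); the realized counts are recorded in
    ``training_meta``.
    """
    params = sam_params or sam.SamParams(s0_policy=config.s0_policy, s0=config.s0_fixed)
    scores = sam.sam_d_statistics(matrix, labels, params)
    n_up, n_down = config.n_up, config.n_down
    n_pos = sum(1 for s in scores if s.d > 0)
    n_neg = sum(1 for s in scores if s.d < 0)
    if n_up > n_pos or n_down > n_neg:
        total = config.n_signature_genes
        shrink = min(n_pos / (n_up / total), n_neg / (n_down / total), total) / total
        n_up = max(1, int(n_up * shrink))
        n_down = max(1, int(n_down * shrink))
    up, down = clanc.select_signature_genes(scores, n_up, n_down)
    return clanc.fit_centroids(
        matrix,
        labels,
        up,
        down,
        training_meta={
            "recipe": [],  # matrix assumed pre-normalized by the caller
            "seed": config.seed,
            "s0_policy": params.s0_policy,
            "requested_n_up": config.n_up,
            "requested_n_down": config.n_down,
        },
    )


def cross_validate(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    config: PipelineConfig,
    sam_params: sam.SamParams | None = None,
) -> PerformanceReport:
    """Stratified k-fold CV with per-fold ranking/selection/fitting.

    Out-of-fold calls are pooled and scored once; per-fold confusion
    reports ride along in ``fold_metrics``.
    """
    labels = np.asarray(labels, dtype=bool)
    minority = int(min(labels.sum(), (~labels).sum()))
    if config.cv_folds > minority:
        raise ValueError(
            f"cv_folds={config.cv_folds} exceeds minority-class count "
            f"{minority}; use at most {minority} folds"
        )
    splitter = StratifiedKFold(
        n_splits=config.cv_folds, shuffle=True, random_state=config.seed % (2**32)
    )
    pooled_calls = np.zeros(matrix.n_samples, dtype=bool)
    pooled_scores = np.zeros(matrix.n_samples, dtype=float)
    fold_metrics = []
    for train_idx, test_idx in splitter.split(np.zeros(matrix.n_samples), labels):
        train_m = matrix.subset_samples([matrix.sample_ids[i] for i in train_idx])
        test_m = matrix.subset_samples([matrix.sample_ids[i] for i in test_idx])
        model = train_signature(train_m, labels[train_idx], config, sam_params)
        results = clanc.classify(test_m, model)
        for local, i in enumerate(test_idx):
            pooled_calls[i] = results[local].msig_call == "mSig+"
            pooled_scores[i] = results[local].msig_score
        fold = confusion_metrics(
            [r.msig_call == "mSig+" for r in results], labels[test_idx], seed=config.seed
        )
        fold_metrics.append(fold.to_dict())
    report = confusion_metrics(pooled_calls, labels, seed=config.seed)
    report.auroc = auroc(pooled_scores, labels)
    report.fold_metrics = fold_metrics
    return report
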