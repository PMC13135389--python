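"""Nearest-centroid mSig core.

A signature model holds class-specific gene sets (overexpressed and
underexpressed in mutants), unshrunken class centroids, a pooled
within-class scale per gene, and a decision threshold.  A sample is scored
by its standardized squared distance to each centroid (averaged over the
genes available, so scores remain comparable when platforms share only part
of the gene space); the continuous mSig score is distance(WT) −
distance(mutant), and calls are mSig+ when the score strictly exceeds the
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .containers import ExpressionMatrix
from .exceptions import CoverageError
from . import preprocess
from .sam import GeneScore

SCALE_FLOOR = 1e-6


@dataclass
class SignatureModel:
    """Trained mSig artifact: gene sets, centroids, scales, threshold."""

    up_genes: list[str]
    down_genes: list[str]
    centroid_mt: dict[str, float]
    centroid_wt: dict[str, float]
    pooled_scale: dict[str, float]
    threshold: float = 0.0
    class_priors: tuple[float, float] = (0.5, 0.5)  # (mt, wt)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        up, down = set(self.up_genes), set(self.down_genes)
        if not self.up_genes and not self.down_genes:
            raise ValueError("signature model must contain at least one gene")
        if up & down:
            raise ValueError(f"up/down gene sets overlap: {sorted(up & down)[:5]}")
        genes = self.genes
        for table, name in (
            (self.centroid_mt, "centroid_mt"),
            (self.centroid_wt, "centroid_wt"),
            (self.pooled_scale, "pooled_scale"),
        ):
            missing = [g for g in genes if g not in table]
            if missing:
                raise ValueError(f"{name} missing gene(s): {missing[:5]}")
        bad_scale = [g for g in genes if self.pooled_scale[g] <= 0]
        if bad_scale:
            raise ValueError(f"non-positive pooled_scale for: {bad_scale[:5]}")
        for g in self.up_genes:
            if not self.centroid_mt[g] > self.centroid_wt[g]:
                raise ValueError(f"up gene {g!r} has centroid_mt <= centroid_wt")
        for g in self.down_genes:
            if not self.centroid_mt[g] < self.centroid_wt[g]:
                raise ValueError(f"down gene {g!r} has centroid_mt >= centroid_wt")
        total = self.class_priors[0] + self.class_priors[1]
        if self.class_priors[0] < 0 or self.class_priors[1] < 0 or abs(total - 1) > 1e-9:
            raise ValueError("class_priors must be non-negative and sum to 1")

    @property
    def genes(self) -> list[str]:
        return list(self.up_genes) + list(self.down_genes)

    @property
    def n_signature_genes(self) -> int:
        return len(self.up_genes) + len(self.down_genes)


@dataclass
class ClassificationResult:
    """Per-sample continuous mSig score and the dichotomous call."""

    sample_id: str
    msig_score: float
    msig_call: str  # "mSig+" or "mSig-"
    distance_mt: float
    distance_wt: float


def select_signature_genes(
    scores: Sequence[GeneScore], n_up: int, n_down: int
) -> tuple[list[str], list[str]]:
    """Split the signature: top n_up genes by descending d, top n_down ascending.

    Only genes whose d carries the right sign are eligible; a deficit on
    either side raises with the shortfall named.
    """
    pos = sorted((s for s in scores if s.d > 0), key=lambda s: (-s.d, s.gene_id))
    neg = sorted((s for s in scores if s.d < 0), key=lambda s: (s.d, s.gene_id))
    if len(pos) < n_up:
        raise ValueError(
            f"need {n_up} genes with d > 0 but only {len(pos)} available "
            f"(deficit {n_up - len(pos)})"
        )
    if len(neg) < n_down:
        raise ValueError(
            f"need {n_down} genes with d < 0 but only {len(neg)} available "
            f"(deficit {n_down - len(neg)})"
        )
    return [s.gene_id for s in pos[:n_up]], [s.gene_id for s in neg[:n_down]]


def fit_centroids(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    up_genes: Sequence[str],
    down_genes: Sequence[str],
    threshold: float = 0.0,
    class_priors: tuple[float, float] = (0.5, 0.5),
    training_meta: Mapping | None = None,
) -> SignatureModel:
    """Class mean centroids and pooled within-class SDs for the selected genes.

    Genes violating the directionality invariant (an "up" gene whose mutant
    centroid does not exceed the wild-type centroid, or conversely) are
    dropped with a warning; the returned model records the counts actually
    kept.  Pooled scales are floored at 1e-6.
    """
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present to fit centroids")
    if labels.sum() < 2 or (~labels).sum() < 2:
        raise ValueError("both classes need >= 2 samples to fit centroids")
    selected = list(up_genes) + list(down_genes)
    sub = matrix.subset_genes(selected)  # raises KeyError listing absentees
    mt = sub.values[:, labels]
    wt = sub.values[:, ~labels]
    cm = mt.mean(axis=1)
    cw = wt.mean(axis=1)
    n1, n2 = mt.shape[1], wt.shape[1]
    # pooled within-class SD over all n samples (average of the per-class
    # population variances weighted by class size)
    ss = ((mt - cm[:, None]) ** 2).sum(axis=1) + ((wt - cw[:, None]) ** 2).sum(axis=1)
    scale = np.maximum(np.sqrt(ss / (n1 + n2)), SCALE_FLOOR)

    keep_up, keep_down, dropped = [], [], []
    for i, g in enumerate(selected):
        is_up = i < len(up_genes)
        if is_up and cm[i] > cw[i]:
            keep_up.append(g)
        elif not is_up and cm[i] < cw[i]:
            keep_down.append(g)
        else:
            dropped.append(g)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} gene(s) violating centroid directionality",
            stacklevel=2,
        )
    index = {g: i for i, g in enumerate(selected)}
    kept = keep_up + keep_down
    meta = dict(training_meta or {})
    meta.update(
        n_up=len(keep_up), n_down=len(keep_down), n_dropped_direction=len(dropped)
    )
    return SignatureModel(
        up_genes=keep_up,
        down_genes=keep_down,
        centroid_mt={g: float(cm[index[g]]) for g in kept},
        centroid_wt={g: float(cw[index[g]]) for g in kept},
        pooled_scale={g: float(scale[index[g]]) for g in kept},
        threshold=threshold,
        class_priors=class_priors,
        training_meta=meta,
    )


def classify(
    matrix: ExpressionMatrix,
    model: SignatureModel,
    min_gene_coverage: float = 0.5,
) -> list[ClassificationResult]:
    """Nearest-centroid calls for every sample in ``matrix``.

    distance_k = mean over available genes of ((x_g − centroid_k,g)/s_g)²
    minus 2·ln(2·prior_k)/n_used, so equal priors contribute nothing and a
    sample sitting exactly on a centroid has distance 0;
    msig_score = distance_wt − distance_mt (the prior normalization cancels
    in the score's prior term).  Calls are mSig+ only for scores strictly
    above the threshold (ties resolve to the conservative mSig−).
    """
    available = [g for g in model.genes if g in set(matrix.gene_ids)]
    coverage = len(available) / model.n_signature_genes
    if coverage < min_gene_coverage:
        raise CoverageError(
            f"only {coverage:.1%} of model genes present "
            f"(floor {min_gene_coverage:.1%})"
        )
    sub = matrix.subset_genes(available)
    cm = np.array([model.centroid_mt[g] for g in available])
    cw = np.array([model.centroid_wt[g] for g in available])
    sc = np.array([model.pooled_scale[g] for g in available])
    n_used = len(available)
    prior_mt, prior_wt = model.class_priors
    with np.errstate(divide="ignore"):
        pen_mt = -2.0 * np.log(2.0 * prior_mt)
        pen_wt = -2.0 * np.log(2.0 * prior_wt)
    z_mt = (sub.values - cm[:, None]) / sc[:, None]
    z_wt = (sub.values - cw[:, None]) / sc[:, None]
    dist_mt = (z_mt**2).sum(axis=0) / n_used + pen_mt / n_used
    dist_wt = (z_wt**2).sum(axis=0) / n_used + pen_wt / n_used
    results = []
    for j, sample in enumerate(sub.sample_ids):
        score = float(dist_wt[j] - dist_mt[j])
        results.append(
            ClassificationResult(
                sample_id=sample,
                msig_score=score,
                msig_call="mSig+" if score > model.threshold else "mSig-",
                distance_mt=float(dist_mt[j]),
                distance_wt=float(dist_wt[j]),
            )
        )
    return results


def harmonize_gene_space(
    matrix: ExpressionMatrix, model: SignatureModel
) -> tuple[ExpressionMatrix, list[str]]:
    """Restrict a cohort to the model's gene space and re-normalize.

    Rows are subset and ordered to the model genes present; the training
    recipe recorded in ``training_meta`` is re-applied within the cohort.
    Returns the harmonized matrix and the list of model genes the cohort is
    missing.
    """
    present = [g for g in model.genes if g in set(matrix.gene_ids)]
    missing = [g for g in model.genes if g not in set(matrix.gene_ids)]
    if not present:
        raise CoverageError("no model genes present in matrix")
    sub = matrix.subset_genes(present)
    recipe = model.training_meta.get("recipe")
    if recipe:
        sub = preprocess.apply_recipe(sub, recipe)
    return sub, missing


def results_to_frame(results: Sequence[ClassificationResult]):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in results])
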