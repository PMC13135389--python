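"""Gene ranking by association with mutation status.

The primary ranking is the SAM d-statistic: the mutant-minus-wild-type mean
difference divided by a pooled per-gene scale plus an exchangeability
("fudge") constant s0 that damps the otherwise explosive statistics of
low-variance genes.  A pooled-variance two-sample t ranking is provided for
feature selection in the style of the machine-learning comparators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .containers import ExpressionMatrix
from .exceptions import ConfigError
from .config import S0_POLICIES


@dataclass
class SamParams:
    """Settings for the SAM statistic: s0 and how to choose it."""

    s0: float = 0.0
    s0_policy: str = "fixed"
    n_permutations: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.s0 < 0:
            raise ConfigError("s0 must be >= 0")
        if self.n_permutations < 0:
            raise ConfigError("n_permutations must be >= 0")
        if self.s0_policy not in S0_POLICIES:
            raise ConfigError(f"s0_policy must be one of {S0_POLICIES}")


@dataclass
class GeneScore:
    """Per-gene two-class association scores and the resulting rank."""

    gene_id: str
    d: float
    t: float
    mean_mt: float
    mean_wt: float
    s: float
    rank: int = 0


def _class_stats(matrix: ExpressionMatrix, labels: np.ndarray):
    labels = np.asarray(labels, dtype=bool)
    if labels.shape != (matrix.n_samples,):
        raise ValueError(
            f"labels length {labels.shape} does not match {matrix.n_samples} samples"
        )
    n1 = int(labels.sum())
    n2 = int((~labels).sum())
    if n1 < 2 or n2 < 2:
        raise ValueError(
            f"both classes need >= 2 samples (mutant={n1}, wild-type={n2})"
        )
    mt = matrix.values[:, labels]
    wt = matrix.values[:, ~labels]
    return mt, wt, n1, n2


def pooled_scale(mt: np.ndarray, wt: np.ndarray) -> np.ndarray:
    """SAM per-gene scale: pooled SD times sqrt(1/n1 + 1/n2)."""
    n1, n2 = mt.shape[1], wt.shape[1]
    ss = ((mt - mt.mean(axis=1, keepdims=True)) ** 2).sum(axis=1) + (
        (wt - wt.mean(axis=1, keepdims=True)) ** 2
    ).sum(axis=1)
    return np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))


def sam_d_statistics(
    matrix: ExpressionMatrix,
    labels: np.ndarray,
    params: SamParams | None = None,
) -> list[GeneScore]:
    """Compute d_g = (mean_mt - mean_wt) / (s_g + s0) for every gene.

    ``labels`` is True for mutant samples.  s0 is taken from ``params``
    (resolved through :func:`estimate_s0` for the non-fixed policies).
    Results are ranked by descending d with deterministic ties broken by
    gene id.
    """
    params = params or SamParams()
    mt, wt, n1, n2 = _class_stats(matrix, labels)
    mean_mt = mt.mean(axis=1)
    mean_wt = wt.mean(axis=1)
    s = pooled_scale(mt, wt)
    raw_d = np.divide(
        mean_mt - mean_wt, s, out=np.zeros_like(s), where=s > 0
    )
    s0 = estimate_s0(s, raw_d, params.s0_policy, fixed=params.s0)
    denom = s + s0
    d = np.divide(
        mean_mt - mean_wt, denom, out=np.zeros_like(denom), where=denom > 0
    )
    # pooled t shares the numerator; its scale has no fudge term
    t = np.divide(mean_mt - mean_wt, s, out=np.zeros_like(s), where=s > 0)
    order = sorted(
        range(matrix.n_genes), key=lambda i: (-d[i], matrix.gene_ids[i])
    )
    scores = [
        GeneScore(
            gene_id=matrix.gene_ids[i],
            d=float(d[i]),
            t=float(t[i]),
            mean_mt=float(mean_mt[i]),
            mean_wt=float(mean_wt[i]),
            s=float(s[i]),
        )
        for i in range(matrix.n_genes)
    ]
    for rank, i in enumerate(order, start=1):
        scores[i].rank = rank
    return scores


def estimate_s0(
    per_gene_scales: np.ndarray,
    per_gene_raw_d: np.ndarray,
    policy: str,
    fixed: float = 0.0,
) -> float:
    """Resolve the fudge constant s0 under the configured policy.

    ``tusher_percentile_scan`` scans s0 candidates at the 0,5,...,100th
    percentiles of the per-gene scales and keeps the candidate minimizing
    the coefficient of variation of the median |d| across scale bins; ties
    resolve to the smaller s0.
    """
    s = np.asarray(per_gene_scales, dtype=float)
    if policy == "fixed":
        return float(fixed)
    if s.size == 0:
        raise ValueError("cannot estimate s0 from zero genes")
    if policy == "median_s":
        return float(np.median(s))
    if policy != "tusher_percentile_scan":
        raise ConfigError(f"unknown s0 policy {policy!r}")
    if s.size < 10:
        raise ValueError("percentile scan needs >= 10 genes")
    diff = np.asarray(per_gene_raw_d, dtype=float) * s  # recover numerators
    candidates = np.percentile(s, np.arange(0, 101, 5))
    n_bins = min(10, max(2, s.size // 5))
    quantile_edges = np.quantile(s, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(quantile_edges, s, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = float(candidates[0]), np.inf
    for s0 in candidates:
        d = diff / (s + s0) if s0 > 0 else np.divide(
            diff, s, out=np.zeros_like(s), where=s > 0
        )
        medians = np.array(
            [np.median(np.abs(d[bins == b])) for b in range(n_bins) if (bins == b).any()]
        )
        mean = medians.mean()
        cv = medians.std(ddof=0) / mean if mean > 0 else np.inf
        if cv < best_cv - 1e-15 or (abs(cv - best_cv) <= 1e-15 and s0 < best_s0):
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def ttest_rank(matrix: ExpressionMatrix, labels: np.ndarray, n_top: int) -> list[str]:
    """Top ``n_top`` genes by ascending two-sided pooled-t p-value.

    Ties break deterministically by descending |t| then gene id.
    """
    if n_top > matrix.n_genes:
        raise ValueError(f"n_top={n_top} exceeds {matrix.n_genes} genes")
    mt, wt, _, _ = _class_stats(matrix, labels)
    t, p = stats.ttest_ind(mt, wt, axis=1, equal_var=True)
    t = np.nan_to_num(t, nan=0.0)
    p = np.nan_to_num(p, nan=1.0)
    order = sorted(
        range(matrix.n_genes),
        key=lambda i: (p[i], -abs(t[i]), matrix.gene_ids[i]),
    )
    return [matrix.gene_ids[i] for i in order[:n_top]]


def scores_to_frame(scores: list[GeneScore]):
    """TSV-ready table of GeneScore records sorted by rank."""
    import pandas as pd

    frame = pd.DataFrame([vars(s) for s in scores])
    return frame.sort_values("rank").reset_index(drop=True)
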