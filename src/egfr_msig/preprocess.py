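"""Normalization applied to expression matrices before signature work.

Three steps compose into a recipe: per-gene median centering, per-gene
z-scoring, and cross-sample quantile normalization (mean-of-order-statistics
reference, with ties within a column receiving the mean of the reference
values they span — the convention of the standard Bioconductor
implementation).
"""

from __future__ import annotations

import warnings
from typing import Callable, Iterable

import numpy as np
from scipy.stats import rankdata

from .containers import ExpressionMatrix
from .exceptions import ConfigError


def median_center_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Subtract each gene's median across samples; row medians become 0."""
    if matrix.n_samples < 1 or matrix.n_genes < 1:
        raise ValueError("median centering requires a non-empty matrix")
    centered = matrix.values - np.median(matrix.values, axis=1, keepdims=True)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), centered)


def zscore_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene to mean 0, sample SD 1 (ddof=1).

    Constant genes cannot be scaled; their rows are set to zero and a
    warning is emitted instead of raising.
    """
    if matrix.n_samples < 2:
        raise ValueError("z-scoring requires at least 2 samples")
    values = matrix.values
    means = values.mean(axis=1, keepdims=True)
    sds = values.std(axis=1, ddof=1, keepdims=True)
    constant = sds[:, 0] == 0.0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene(s) set to zero during z-scoring",
            stacklevel=2,
        )
    safe_sds = np.where(sds == 0.0, 1.0, sds)
    scaled = (values - means) / safe_sds
    scaled[constant] = 0.0
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), scaled)


def quantile_normalize_samples(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Force every sample column onto the mean-of-order-statistics distribution.

    The reference is the across-sample mean of the sorted columns.  A tie
    group within a column receives the mean of the reference values its
    ranks span.  With a single sample the matrix is returned unchanged with
    a warning.
    """
    if matrix.n_samples < 2:
        warnings.warn("quantile normalization is a no-op on a single sample",
                      stacklevel=2)
        return matrix.copy()
    values = matrix.values
    order_stats = np.sort(values, axis=0)
    reference = order_stats.mean(axis=1)  # length n_genes
    cumref = np.concatenate(([0.0], np.cumsum(reference)))
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        col = values[:, j]
        lo = rankdata(col, method="min").astype(int) - 1
        hi = rankdata(col, method="max").astype(int)  # exclusive upper index
        # mean of reference[lo:hi] for each entry, via cumulative sums
        out[:, j] = (cumref[hi] - cumref[lo]) / (hi - lo)
    return ExpressionMatrix(list(matrix.gene_ids), list(matrix.sample_ids), out)


STEPS: dict[str, Callable[[ExpressionMatrix], ExpressionMatrix]] = {
    "median_center_genes": median_center_genes,
    "zscore_genes": zscore_genes,
    "quantile_normalize_samples": quantile_normalize_samples,
}


def apply_recipe(matrix: ExpressionMatrix, steps: Iterable[str]) -> ExpressionMatrix:
    """Apply an ordered, duplicate-free list of normalization steps."""
    steps = list(steps)
    if not steps:
        raise ConfigError("normalization recipe must name at least one step")
    if len(set(steps)) != len(steps):
        raise ConfigError(f"duplicate step in recipe: {steps}")
    unknown = [s for s in steps if s not in STEPS]
    if unknown:
        raise ConfigError(f"unknown recipe step(s): {unknown}; known: {sorted(STEPS)}")
    for step in steps:
        matrix = STEPS[step](matrix)
    return matrix
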