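"""Core in-memory containers: expression matrices and cohort annotations.

Expression values are dense, log-scale, genes x samples.  The matrix is a
thin validated wrapper around a numpy array plus ordered identifier lists;
``to_frame``/``from_frame`` bridge to pandas for I/O and downstream joins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import IdentifierError

SUBTYPES = ("bronchioid", "magnoid", "squamoid", "unknown")


def _check_unique(ids: Sequence[str], kind: str) -> None:
    seen: set[str] = set()
    dups = {i for i in ids if i in seen or seen.add(i)}  # type: ignore[func-returns-value]
    if dups:
        raise IdentifierError(f"duplicate {kind} identifier(s): {sorted(dups)[:5]}")


@dataclass
class ExpressionMatrix:
    """Genes x samples log-scale expression with unique ordered identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values must be finite after load")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict (and reorder) rows to ``genes``; all must be present."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids), self.values[rows])

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise KeyError(f"samples absent from matrix: {missing[:5]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples), self.values[:, cols])

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(
            list(self.gene_ids), list(self.sample_ids), self.values.copy()
        )


@dataclass
class CohortAnnotation:
    """Per-sample mutation, subtype, platform, and survival annotation.

    ``ras_mutant`` means any canonical KRAS/NRAS/HRAS activating call.
    Survival time is in months; ``event`` True means death observed.
    """

    sample_id: str
    egfr_mutant: bool
    ras_mutant: bool
    tp53_mutant: bool
    stk11_mutant: bool
    keap1_mutant: bool
    cdkn2a_altered: bool
    subtype: str
    platform: str
    survival_months: float
    event: bool

    def __post_init__(self) -> None:
        if self.subtype not in SUBTYPES:
            raise ValueError(
                f"unknown subtype {self.subtype!r}; expected one of {SUBTYPES}"
            )
        if self.survival_months < 0:
            raise ValueError(
                f"negative survival_months ({self.survival_months}) for "
                f"sample {self.sample_id}"
            )


def annotation_frame(annotations: Sequence[CohortAnnotation]) -> pd.DataFrame:
    """Tabular view of an annotation list, indexed by sample_id."""
    frame = pd.DataFrame([vars(a) for a in annotations])
    return frame.set_index("sample_id", drop=False)
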