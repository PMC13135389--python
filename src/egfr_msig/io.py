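"""Readers and writers for the pipeline's on-disk artifacts.

Expression and annotation tables are tab-delimited text; the trained
signature model is a single JSON document with an explicit schema-version
field.  Readers validate and refuse malformed input rather than coercing.
"""

from __future__ import annotations

import json
from typing import Sequence

import numpy as np
import pandas as pd

from .containers import CohortAnnotation, ExpressionMatrix, annotation_frame
from .exceptions import FormatError, IdentifierError
from . import clanc

MODEL_SCHEMA_VERSION = 1

_BOOL_COLUMNS = (
    "egfr_mutant",
    "ras_mutant",
    "tp53_mutant",
    "stk11_mutant",
    "keap1_mutant",
    "cdkn2a_altered",
    "event",
)

_ANNOTATION_COLUMNS = (
    "sample_id",
    "egfr_mutant",
    "ras_mutant",
    "tp53_mutant",
    "stk11_mutant",
    "keap1_mutant",
    "cdkn2a_altered",
    "subtype",
    "platform",
    "survival_months",
    "event",
)


def read_expression(path: str, impute_missing: bool = False) -> ExpressionMatrix:
    """Load a genes-x-samples TSV (first column gene ids, first row sample ids).

    Missing values are refused unless ``impute_missing`` is set, in which
    case each gap is filled with the gene-wise median.
    """
    with open(path) as handle:
        header = handle.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        sample_ids = header.split("\t")[1:]
        n_cols = len(sample_ids)
        gene_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, line in enumerate(handle, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != n_cols + 1:
                raise FormatError(
                    f"{path}:{lineno}: expected {n_cols + 1} fields, got {len(fields)}"
                )
            gene_ids.append(fields[0])
            row: list[float] = []
            for col, cell in enumerate(fields[1:]):
                if cell == "" or cell.upper() in ("NA", "NAN"):
                    row.append(np.nan)
                    continue
                try:
                    row.append(float(cell))
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-numeric value {cell!r} in column "
                        f"{sample_ids[col]!r} for gene {fields[0]!r}"
                    ) from None
            rows.append(row)
    values = np.asarray(rows, dtype=float)
    if values.size and np.isnan(values).any():
        if not impute_missing:
            n_missing = int(np.isnan(values).sum())
            raise FormatError(
                f"{path}: {n_missing} missing value(s); pass impute_missing=True "
                "to fill with gene-wise medians"
            )
        medians = np.nanmedian(values, axis=1, keepdims=True)
        values = np.where(np.isnan(values), medians, values)
    return ExpressionMatrix(gene_ids, sample_ids, values)


def write_expression(matrix: ExpressionMatrix, path: str) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def _parse_bool(cell: str, column: str, lineno: int, path: str) -> bool:
    text = str(cell).strip().upper()
    if text in ("1", "TRUE", "T"):
        return True
    if text in ("0", "FALSE", "F"):
        return False
    raise FormatError(
        f"{path}:{lineno}: column {column!r}: boolean must be 0/1 or TRUE/FALSE, "
        f"got {cell!r}"
    )


def read_annotation(path: str) -> list[CohortAnnotation]:
    """Load a per-sample annotation TSV into validated records."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _ANNOTATION_COLUMNS if c not in table.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {missing}")
    records: list[CohortAnnotation] = []
    for offset, row in enumerate(table.itertuples(index=False)):
        lineno = offset + 2
        kwargs = {
            col: _parse_bool(getattr(row, col), col, lineno, path)
            for col in _BOOL_COLUMNS
        }
        try:
            survival = float(row.survival_months)
        except ValueError:
            raise FormatError(
                f"{path}:{lineno}: non-numeric survival_months "
                f"{row.survival_months!r}"
            ) from None
        try:
            record = CohortAnnotation(
                sample_id=str(row.sample_id),
                subtype=str(row.subtype),
                platform=str(row.platform),
                survival_months=survival,
                **kwargs,
            )
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from None
        records.append(record)
    sample_ids = [r.sample_id for r in records]
    if len(set(sample_ids)) != len(sample_ids):
        dups = sorted({s for s in sample_ids if sample_ids.count(s) > 1})
        raise IdentifierError(f"{path}: duplicate sample id(s): {dups[:5]}")
    return records


def write_annotation(annotations: Sequence[CohortAnnotation], path: str) -> None:
    frame = annotation_frame(annotations).reset_index(drop=True)
    for col in _BOOL_COLUMNS:
        frame[col] = frame[col].astype(int)
    frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_signature_model(model: "clanc.SignatureModel", path: str) -> None:
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "up_genes": list(model.up_genes),
        "down_genes": list(model.down_genes),
        "centroid_mt": {g: float(v) for g, v in model.centroid_mt.items()},
        "centroid_wt": {g: float(v) for g, v in model.centroid_wt.items()},
        "pooled_scale": {g: float(v) for g, v in model.pooled_scale.items()},
        "threshold": float(model.threshold),
        "class_priors": [float(p) for p in model.class_priors],
        "training_meta": dict(model.training_meta),
    }
    with open(path, "w") as handle:
        json.dump(doc, handle, indent=1)


def read_signature_model(path: str) -> "clanc.SignatureModel":
    with open(path) as handle:
        try:
            doc = json.load(handle)
        except json.JSONDecodeError as exc:
            raise FormatError(f"{path}: not valid JSON: {exc}") from None
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema_version {version!r} does not match expected "
            f"{MODEL_SCHEMA_VERSION}"
        )
    required = ("up_genes", "down_genes", "centroid_mt", "centroid_wt", "pooled_scale")
    missing = [key for key in required if key not in doc]
    if missing:
        raise FormatError(f"{path}: missing block(s): {missing}")
    model = clanc.SignatureModel(
        up_genes=list(doc["up_genes"]),
        down_genes=list(doc["down_genes"]),
        centroid_mt={g: float(v) for g, v in doc["centroid_mt"].items()},
        centroid_wt={g: float(v) for g, v in doc["centroid_wt"].items()},
        pooled_scale={g: float(v) for g, v in doc["pooled_scale"].items()},
        threshold=float(doc.get("threshold", 0.0)),
        class_priors=tuple(doc.get("class_priors", (0.5, 0.5))),
        training_meta=dict(doc.get("training_meta", {})),
    )
    return model
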