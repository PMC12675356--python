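"""Readers and writers for the pipeline's tabular formats.

TSV is the canonical on-disk format (tab delimiter); CSV is accepted via
``sep=","``.  Expression matrices are genes x samples with the gene id in
the first column; clinical tables are one row per sample.  Signatures and
fitted models are JSON.
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    FixedSignature,
    SignatureModel,
    Unit,
    ValidationError,
)

logger = logging.getLogger(__name__)

PathLike = Union[str, Path]


def read_expression(path: PathLike, unit: Unit | str = Unit.counts, sep: str = "\t") -> ExpressionMatrix:
    """Load a genes x samples matrix; first column gene id, header row sample ids."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    nonnum = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if nonnum:
        raise ValidationError(
            f"{path}: non-numeric cells in columns {nonnum}"
        )
    return ExpressionMatrix(df.astype(float), unit)


def write_expression(expr: ExpressionMatrix, path: PathLike, sep: str = "\t") -> None:
    expr.values.to_csv(path, sep=sep, index_label="gene_id")


def read_clinical(path: PathLike, sep: str = "\t") -> ClinicalTable:
    """Load a per-sample clinical table keyed by ``sample_id``.

    ``response`` is derived from ``recist`` (CR/PR -> 1, SD/PD -> 0) when
    only the RECIST column is present.
    """
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'sample_id'")
    df = df.set_index("sample_id")
    return ClinicalTable(df)


def write_clinical(clin: ClinicalTable, path: PathLike, sep: str = "\t") -> None:
    clin.table.to_csv(path, sep=sep, index_label="sample_id")


def read_gene_lengths(path: PathLike, sep: str = "\t") -> pd.Series:
    """Two-column TSV gene_id, length_bp -> Series of lengths."""
    df = pd.read_csv(path, sep=sep)
    if not {"gene_id", "length_bp"} <= set(df.columns):
        raise ValidationError(f"{path}: need columns gene_id, length_bp")
    s = df.set_index("gene_id")["length_bp"].astype(float)
    if (s <= 0).any():
        bad = s.index[s <= 0].tolist()
        raise ValidationError(f"non-positive gene lengths: {bad}")
    return s


def write_gene_lengths(lengths: pd.Series, path: PathLike, sep: str = "\t") -> None:
    lengths.rename("length_bp").to_csv(path, sep=sep, index_label="gene_id")


def align(expr: ExpressionMatrix, clin: ClinicalTable) -> tuple[ExpressionMatrix, ClinicalTable]:
    """Restrict both objects to their shared samples, in the matrix's order."""
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not shared:
        raise ValidationError("expression and clinical tables share no samples")
    dropped_expr = sorted(set(expr.sample_ids) - set(shared))
    dropped_clin = sorted(set(clin.sample_ids) - set(shared))
    if dropped_expr:
        logger.info("align: dropped %d expression-only samples: %s", len(dropped_expr), dropped_expr)
    if dropped_clin:
        logger.info("align: dropped %d clinical-only samples: %s", len(dropped_clin), dropped_clin)
    return expr.subset_samples(shared), clin.subset(shared)


def read_signature(path: PathLike) -> FixedSignature:
    with open(path) as fh:
        obj = json.load(fh)
    for key in ("name", "genes"):
        if key not in obj:
            raise ValidationError(f"{path}: signature JSON missing field {key!r}")
    return FixedSignature(name=obj["name"], genes=list(obj["genes"]))


def write_signature(sig: FixedSignature, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump({"name": sig.name, "genes": sig.genes}, fh, indent=2)
        fh.write("\n")


_MODEL_FIELDS = ("genes", "weights", "intercept", "penalty", "lambda", "train_means", "train_sds", "meta")


def write_model(model: SignatureModel, path: PathLike) -> None:
    obj = {
        "genes": model.genes,
        "weights": model.weights.tolist(),
        "intercept": model.intercept,
        "penalty": model.penalty,
        "lambda": model.lam,
        "train_means": model.train_means.tolist(),
        "train_sds": model.train_sds.tolist(),
        "meta": model.meta,
    }
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2)
        fh.write("\n")


def read_model(path: PathLike) -> SignatureModel:
    with open(path) as fh:
        obj = json.load(fh)
    missing = [k for k in _MODEL_FIELDS if k not in obj]
    if missing:
        raise ValidationError(f"{path}: model JSON missing fields {missing}")
    return SignatureModel(
        genes=list(obj["genes"]),
        weights=np.asarray(obj["weights"], dtype=float),
        intercept=float(obj["intercept"]),
        penalty=obj["penalty"],
        lam=float(obj["lambda"]),
        train_means=np.asarray(obj["train_means"], dtype=float),
        train_sds=np.asarray(obj["train_sds"], dtype=float),
        meta=dict(obj["meta"]),
    )
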