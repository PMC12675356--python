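"""Normalization to log2(TPM+1), per-cohort standardization, name prefilter.

The working expression scale throughout the pipeline is log2(TPM+1).
Training and test cohorts are standardized separately (each gene to mean 0,
variance 1 within its own cohort) — justified when the responder fraction is
similar across cohorts; a single new sample is instead scored with the
frozen training moments via :func:`apply_standardization`, and models carry
that provenance in their metadata.
"""
from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, StandardizationParams, Unit, ValidationError

logger = logging.getLogger(__name__)

NONINFORMATIVE_PREFIXES = ("HIST", "LOC")


def counts_to_log2tpm1(expr: ExpressionMatrix, gene_lengths: pd.Series) -> ExpressionMatrix:
    """Convert raw counts to log2(TPM + 1).

    Per sample j: rate_ij = count_ij / length_i(kb);
    TPM_ij = 1e6 * rate_ij / sum_i rate_ij; each sample's TPM column sums to
    1e6 before the log transform.
    """
    if expr.unit is not Unit.counts:
        raise ValidationError(f"expected counts, got unit={expr.unit.value}")
    missing = [g for g in expr.gene_ids if g not in gene_lengths.index]
    if missing:
        raise ValidationError(f"genes missing from length map: {missing}")
    lengths_kb = gene_lengths.loc[expr.gene_ids].to_numpy(dtype=float) / 1e3
    if (lengths_kb <= 0).any():
        raise ValidationError("gene lengths must be > 0")
    counts = expr.values.to_numpy(dtype=float)
    rates = counts / lengths_kb[:, None]
    colsums = rates.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        bad = [expr.sample_ids[i] for i in zero]
        raise ValidationError(f"all-zero samples (TPM undefined): {bad}")
    tpm = 1e6 * rates / colsums
    out = pd.DataFrame(np.log2(tpm + 1.0), index=expr.values.index, columns=expr.values.columns)
    return ExpressionMatrix(out, Unit.log2tpm1)


def standardize(expr: ExpressionMatrix) -> tuple[ExpressionMatrix, StandardizationParams]:
    """Scale each gene to mean 0, variance 1 (n-1 denominator) within the cohort.

    Zero-variance genes are dropped with a warning and excluded from the
    returned parameters.
    """
    if expr.n_samples < 2:
        raise ValidationError("standardization needs >= 2 samples")
    vals = expr.values.to_numpy(dtype=float)
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=1)
    keep = sds > 0
    if not keep.all():
        dropped = [g for g, k in zip(expr.gene_ids, keep) if not k]
        logger.warning("standardize: dropped %d zero-variance genes: %s", len(dropped), dropped[:20])
    z = (vals[keep] - means[keep][:, None]) / sds[keep][:, None]
    genes = [g for g, k in zip(expr.gene_ids, keep) if k]
    out = ExpressionMatrix(
        pd.DataFrame(z, index=genes, columns=expr.sample_ids), Unit.standardized
    )
    params = StandardizationParams(gene_ids=genes, means=means[keep], sds=sds[keep])
    return out, params


def apply_standardization(expr: ExpressionMatrix, params: StandardizationParams) -> ExpressionMatrix:
    """Scale with FROZEN moments (the supplied params), not the data's own.

    Supports a single-sample matrix, which :func:`standardize` cannot.
    """
    missing = [g for g in params.gene_ids if g not in expr.values.index]
    if missing:
        raise ValidationError(f"genes missing from matrix: {missing}")
    sub = expr.values.loc[params.gene_ids].to_numpy(dtype=float)
    z = (sub - params.means[:, None]) / params.sds[:, None]
    out = pd.DataFrame(z, index=params.gene_ids, columns=expr.sample_ids)
    return ExpressionMatrix(out, Unit.standardized)


def filter_noninformative_genes(gene_ids: Iterable[str]) -> list[str]:
    """Drop genes whose symbol starts with HIST or LOC (case-sensitive); order kept."""
    return [g for g in gene_ids if not g.startswith(NONINFORMATIVE_PREFIXES)]
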