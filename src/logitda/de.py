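"""Differential-expression prefilter: responders vs non-responders on raw counts.

The built-in test is a negative-binomial Wald test on size-factor-normalized
counts with a per-gene method-of-moments dispersion — a lightweight
count-model screen, deliberately simpler than shrinkage-based DE packages.
The pipeline only consumes the surviving gene list, so an externally
computed DE table (e.g. from DESeq2) can be dropped in via
:func:`read_de_table`.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import ExpressionMatrix, Unit, ValidationError

DISPERSION_FLOOR = 1e-8
_PSEUDO = 0.5  # pseudocount on class means for a finite log fold change


def size_factors(expr: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios normalization factors, scaled to geometric mean 1.

    For each sample, the factor is the median over reference genes (those
    with all-positive counts) of count / geometric-mean(count across
    samples).
    """
    counts = expr.values.to_numpy(dtype=float)
    if expr.n_samples == 1:
        return pd.Series([1.0], index=expr.sample_ids)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValidationError(
            "no gene has all-positive counts; median-of-ratios undefined "
            "(consider a pseudo-reference fallback)"
        )
    ref = counts[positive]
    log_geomean = np.log(ref).mean(axis=1)
    ratios = np.log(ref) - log_geomean[:, None]
    factors = np.exp(np.median(ratios, axis=0))
    factors = factors / np.exp(np.log(factors).mean())  # geometric mean 1
    return pd.Series(factors, index=expr.sample_ids)


@dataclass
class DEResult:
    """Per-gene DE statistics: log2fc (responders vs non), p, BH-adjusted p."""

    table: pd.DataFrame  # index gene_id; columns log2fc, pvalue, padj

    def __post_init__(self) -> None:
        need = {"log2fc", "pvalue", "padj"}
        if not need <= set(self.table.columns):
            raise ValidationError(f"DE table needs columns {sorted(need)}")
        if ((self.table["padj"] + 1e-12) < self.table["pvalue"]).any():
            raise ValidationError("padj < pvalue: BH can only increase p")


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _class_moments(norm: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, int]:
    sub = norm[:, mask]
    return sub.mean(axis=1), sub.var(axis=1, ddof=1), int(mask.sum())


def de_test(
    expr: ExpressionMatrix,
    response: np.ndarray,
    method: str = "nb_wald",
) -> DEResult:
    """Two-class DE test per gene; positive log2fc = higher in responders.

    ``nb_wald``: NB means per class on normalized counts, pooled
    method-of-moments dispersion floored at ``DISPERSION_FLOOR``, Wald test
    on the log mean ratio (delta-method SE).  ``log_ttest``: Welch t-test on
    log2(normalized count + 1) — a fast, model-free fallback.
    """
    y = np.asarray(response, dtype=int)
    if expr.n_samples != y.size:
        raise ValidationError("response length does not match sample count")
    pos, neg = y == 1, y == 0
    if pos.sum() < 2 or neg.sum() < 2:
        raise ValidationError("both classes need >= 2 samples for DE testing")

    sf = size_factors(expr).to_numpy()
    norm = expr.values.to_numpy(dtype=float) / sf[None, :]

    if method == "nb_wald":
        mu1, s1, n1 = _class_moments(norm, pos)
        mu0, s0, n0 = _class_moments(norm, neg)
        # pooled per-gene dispersion phi: Var = mu + phi mu^2, method of moments
        with np.errstate(divide="ignore", invalid="ignore"):
            phi1 = (s1 - mu1) / np.square(mu1)
            phi0 = (s0 - mu0) / np.square(mu0)
        phi1 = np.where(np.isfinite(phi1), phi1, 0.0)
        phi0 = np.where(np.isfinite(phi0), phi0, 0.0)
        phi = ((n1 - 1) * phi1 + (n0 - 1) * phi0) / (n1 + n0 - 2)
        phi = np.maximum(phi, DISPERSION_FLOOR)
        m1, m0 = mu1 + _PSEUDO, mu0 + _PSEUDO
        log2fc = np.log2(m1 / m0)
        se2 = (1.0 / m1 + phi) / n1 + (1.0 / m0 + phi) / n0
        z = (np.log(m1) - np.log(m0)) / np.sqrt(se2)
        pvalue = 2.0 * stats.norm.sf(np.abs(z))
    elif method == "log_ttest":
        logn = np.log2(norm + 1.0)
        a, b = logn[:, pos], logn[:, neg]
        t, pvalue = stats.ttest_ind(a, b, axis=1, equal_var=False)
        pvalue = np.where(np.isnan(pvalue), 1.0, pvalue)
        log2fc = a.mean(axis=1) - b.mean(axis=1)
    else:
        raise ValidationError(f"unknown DE method {method!r}")

    padj = bh_adjust(pvalue)
    table = pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvalue, "padj": padj}, index=expr.values.index
    )
    return DEResult(table)


def de_filter(de: DEResult, fdr_threshold: float = 0.10) -> list[str]:
    """Genes with BH-adjusted p strictly below the threshold, input order kept."""
    mask = de.table["padj"] < fdr_threshold
    return de.table.index[mask].tolist()


def read_de_table(path, sep: str = "\t") -> DEResult:
    """Import an externally computed DE table (gene_id, log2fc, pvalue, padj)."""
    df = pd.read_csv(path, sep=sep)
    if "gene_id" not in df.columns:
        raise ValidationError(f"{path}: missing column gene_id")
    return DEResult(df.set_index("gene_id"))


def write_de_table(de: DEResult, path, sep: str = "\t") -> None:
    de.table.to_csv(path, sep=sep, index_label="gene_id")
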