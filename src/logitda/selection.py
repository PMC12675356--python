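"""Feature selection: DE prefilter -> BW-ratio top-p -> domain-adaptation filter.

The three stages run in a fixed order on the training cohort, with the
final, unsupervised stage comparing each candidate gene's marginal
log2(TPM+1) distribution between the training cohort and the *unlabeled*
test cohort via the two-sample Kolmogorov-Smirnov statistic D.  Genes with
D above the threshold alpha_da are discarded as non-transferable.  Test
response labels are never read at any stage.

The BW-ratio (between- over within-group sum of squares) is invariant to
per-gene affine rescaling, so it is computed directly on log2(TPM+1);
standardization only matters later, for classifier training.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import ks_2samp

from .datatypes import ExpressionMatrix, ValidationError
from .de import DEResult, de_filter, de_test
from .preprocess import filter_noninformative_genes

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Knobs of the three-stage selection.

    ``fdr_threshold`` gates the DE stage (BH-adjusted p, strict <);
    ``p`` keeps the top-p genes by BW-ratio; ``alpha_da`` is the KS-distance
    ceiling of the domain-adaptation filter (smaller = stricter).
    """

    fdr_threshold: float = 0.10
    p: int = 150
    alpha_da: float = 0.2
    da_metric: str = "ks"
    de_method: str = "nb_wald"
    da_enabled: bool = True

    def __post_init__(self) -> None:
        if self.p < 1:
            raise ValidationError("p must be >= 1")
        if not 0 < self.alpha_da <= 1:
            raise ValidationError("alpha_da must be in (0, 1]")
        if self.da_metric != "ks":
            raise ValidationError(f"unsupported DA metric {self.da_metric!r}")


def bw_ratio(values: np.ndarray, response: np.ndarray) -> float:
    """Between- over within-group sum of squares across the two classes.

    Within-SS == 0 with between-SS > 0 returns +inf (ranks first); the 0/0
    degenerate case returns 0.
    """
    x = np.asarray(values, dtype=float)
    y = np.asarray(response, dtype=int)
    if x.shape != y.shape:
        raise ValidationError("values and response lengths differ")
    masks = [y == 1, y == 0]
    if not all(m.any() for m in masks):
        raise ValidationError("both classes must be non-empty")
    grand = x.mean()
    between = sum(m.sum() * (x[m].mean() - grand) ** 2 for m in masks)
    within = sum(((x[m] - x[m].mean()) ** 2).sum() for m in masks)
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return between / within


def bw_ratios(expr: ExpressionMatrix, response: np.ndarray) -> pd.Series:
    """Vectorized per-gene BW-ratio over a genes x samples matrix."""
    x = expr.values.to_numpy(dtype=float)
    y = np.asarray(response, dtype=int)
    pos, neg = y == 1, y == 0
    if not (pos.any() and neg.any()):
        raise ValidationError("both classes must be non-empty")
    n1, n0 = pos.sum(), neg.sum()
    m1, m0 = x[:, pos].mean(axis=1), x[:, neg].mean(axis=1)
    grand = x.mean(axis=1)
    between = n1 * (m1 - grand) ** 2 + n0 * (m0 - grand) ** 2
    within = ((x[:, pos] - m1[:, None]) ** 2).sum(axis=1) + (
        (x[:, neg] - m0[:, None]) ** 2
    ).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        bw = between / within
    bw = np.where(within == 0, np.where(between > 0, np.inf, 0.0), bw)
    return pd.Series(bw, index=expr.values.index)


def rank_top_p(scores: pd.Series, p: int) -> list[str]:
    """Top-p genes by score, descending; ties broken by gene id ascending."""
    if p < 1:
        raise ValidationError("p must be >= 1")
    order = sorted(scores.index, key=lambda g: (-scores[g], g))
    if p > len(order):
        warnings.warn(
            f"requested top-{p} genes but only {len(order)} available", stacklevel=2
        )
    return order[:p]


def ks_distance(train_values: np.ndarray, test_values: np.ndarray) -> float:
    """Two-sample Kolmogorov-Smirnov statistic D = sup |F_train - F_test|."""
    a = np.asarray(train_values, dtype=float)
    b = np.asarray(test_values, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("KS distance needs >= 2 values per cohort")
    return float(ks_2samp(a, b, method="asymp").statistic)


def ks_distances(train: ExpressionMatrix, test: ExpressionMatrix, genes: list[str]) -> pd.Series:
    out = {}
    test_genes = set(test.gene_ids)
    for g in genes:
        if g not in test_genes:
            continue
        out[g] = ks_distance(
            train.values.loc[g].to_numpy(), test.values.loc[g].to_numpy()
        )
    return pd.Series(out, dtype=float)


def da_filter(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    genes: list[str],
    alpha_da: float,
) -> tuple[list[str], pd.Series]:
    """Keep genes whose cross-cohort KS distance is <= alpha_da; order kept.

    Genes absent from the test matrix are dropped with a warning (the same
    rule the fixed-signature harness applies to missing genes).
    """
    absent = [g for g in genes if g not in set(test.gene_ids)]
    if absent:
        warnings.warn(f"DA filter: genes absent from test cohort dropped: {absent}", stacklevel=2)
    dists = ks_distances(train, test, genes)
    kept = [g for g in genes if g in dists.index and dists[g] <= alpha_da]
    return kept, dists


@dataclass
class GeneScoreTable:
    """Per-gene audit trail of the selection pipeline.

    Selection flags are monotone: passed_da => in_top_p => passed_name_filter
    => passed_de.
    """

    table: pd.DataFrame
    selected: list[str] = field(default_factory=list)

    FLAGS = ("passed_de", "passed_name_filter", "in_top_p", "passed_da")

    def __post_init__(self) -> None:
        f = self.table[list(self.FLAGS)].astype(bool)
        for earlier, later in zip(self.FLAGS, self.FLAGS[1:]):
            if (f[later] & ~f[earlier]).any():
                raise ValidationError(f"flag {later} set without {earlier}")


def select_features(
    train_counts: ExpressionMatrix,
    train_log2tpm1: ExpressionMatrix,
    test_log2tpm1: ExpressionMatrix,
    response: np.ndarray,
    config: SelectionConfig,
    de_result: DEResult | None = None,
) -> tuple[list[str], GeneScoreTable]:
    """Run the full selection pipeline on the training cohort.

    Stages, in order: DE filter (BH FDR < threshold) -> HIST/LOC name filter
    -> BW-ratio ranking (keep top-p) -> DA filter at alpha_da against the
    unlabeled test cohort.  ``de_result`` may supply an externally computed
    DE table.  With ``config.da_enabled`` False the DA stage is skipped
    (ablation mode) and the top-p list is returned.
    """
    y = np.asarray(response, dtype=int)
    de = de_result if de_result is not None else de_test(train_counts, y, config.de_method)

    de_genes = de_filter(de, config.fdr_threshold)
    if not de_genes:
        raise ValidationError("empty selection after stage: DE filter")
    named = filter_noninformative_genes(de_genes)
    if not named:
        raise ValidationError("empty selection after stage: name filter")

    bw = bw_ratios(train_log2tpm1.subset_genes(named), y)
    top = rank_top_p(bw, min(config.p, len(named)))

    if config.da_enabled:
        kept, dists = da_filter(train_log2tpm1, test_log2tpm1, top, config.alpha_da)
        if not kept:
            raise ValidationError("empty selection after stage: DA filter")
    else:
        kept, dists = top, pd.Series(dtype=float)

    genes = de.table.index
    de_set, named_set, top_set, kept_set = map(set, (de_genes, named, top, kept))
    table = pd.DataFrame(
        {
            "log2fc": de.table["log2fc"],
            "pvalue": de.table["pvalue"],
            "padj": de.table["padj"],
            "bw_ratio": bw.reindex(genes),
            "ks_distance": dists.reindex(genes),
            "passed_de": genes.isin(de_set),
            "passed_name_filter": genes.isin(named_set),
            "in_top_p": genes.isin(top_set),
            "passed_da": genes.isin(kept_set) if config.da_enabled else genes.isin(kept_set),
        },
        index=genes,
    )
    if not config.da_enabled:
        # without the DA stage the final flag mirrors in_top_p
        table["passed_da"] = table["in_top_p"]
    score = GeneScoreTable(table, selected=kept)
    logger.info(
        "selection: %d DE -> %d named -> %d top-p -> %d after DA",
        len(de_genes), len(named), len(top), len(kept),
    )
    return kept, score
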