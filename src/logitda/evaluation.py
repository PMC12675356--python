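"""Prediction metrics and the fixed-/integrated-signature benchmarking harness.

AUC uses the Mann-Whitney formulation (fraction of positive/negative pairs
ranked concordantly, ties counted 1/2).  Fixed published signatures are
benchmarked with the same ridge-logit + repeated-CV protocol as the learned
signature: genes missing from either cohort are dropped with a logged note,
never imputed.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .classifier import CVResult, cross_validate, fit_penalized_logit, predict_proba_matrix
from .datatypes import (
    ClinicalTable,
    EvalReport,
    ExpressionMatrix,
    FixedSignature,
    SignatureModel,
    ValidationError,
)
from .preprocess import standardize

logger = logging.getLogger(__name__)


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("AUC needs both classes present")
    ranks = stats.rankdata(s)  # midranks handle ties
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def confusion_metrics(
    scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5
) -> EvalReport:
    """Threshold at ``score >= threshold`` (boundary counts as positive)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    pred = (s >= threshold).astype(int)
    tp = int(((pred == 1) & (y == 1)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    n = y.size
    acc = (tp + tn) / n if n else 0.0
    denom = 2 * tp + fp + fn
    f1 = 2 * tp / denom if denom else 0.0
    try:
        auc = roc_auc(s, y)
    except ValidationError:
        auc = float("nan")
    return EvalReport(
        auc=auc, accuracy=acc, f1=f1, tp=tp, tn=tn, fp=fp, fn=fn,
        threshold=threshold, n_samples=n,
    )


def evaluate_fixed_signature(
    train_log2: ExpressionMatrix,
    test_log2: ExpressionMatrix,
    clinical_train: ClinicalTable,
    clinical_test: ClinicalTable,
    signature: FixedSignature,
    lambda_grid: list[float],
    seed: int = 0,
    k_folds: int = 5,
    repeats: int = 100,
    threshold: float = 0.5,
) -> tuple[SignatureModel, EvalReport, CVResult]:
    """Train a ridge logit on a fixed gene list and evaluate on the test cohort.

    Both cohorts are standardized separately (per-cohort ST).  Genes absent
    from either cohort, or with zero variance in either, are dropped and
    recorded in the report notes.
    """
    notes: list[str] = []
    present = [
        g for g in signature.genes
        if g in set(train_log2.gene_ids) and g in set(test_log2.gene_ids)
    ]
    dropped = [g for g in signature.genes if g not in present]
    if dropped:
        notes.append(f"dropped genes missing from a cohort: {dropped}")
        logger.info("signature %s: dropped %s", signature.name, dropped)
    if not present:
        raise ValidationError(f"signature {signature.name!r}: no genes present in both cohorts")

    train_std, std_params = standardize(train_log2.subset_genes(present))
    test_std, _ = standardize(test_log2.subset_genes(present))
    usable = [g for g in train_std.gene_ids if g in set(test_std.gene_ids)]
    if len(usable) < len(present):
        zv = sorted(set(present) - set(usable))
        notes.append(f"dropped zero-variance genes: {zv}")
    if not usable:
        raise ValidationError(f"signature {signature.name!r}: no usable genes remain")

    y_train = clinical_train.response.loc[train_std.sample_ids].to_numpy()
    X = train_std.values.loc[usable].to_numpy().T
    cv = cross_validate(X, y_train, lambda_grid, k_folds, repeats, seed, "l2")
    lam = float(cv.chosen["lam"])
    w, b = fit_penalized_logit(X, y_train, lam, "l2")

    idx = [std_params.gene_ids.index(g) for g in usable]
    model = SignatureModel(
        genes=usable,
        weights=w,
        intercept=b,
        penalty="l2",
        lam=lam,
        train_means=std_params.means[idx],
        train_sds=std_params.sds[idx],
        meta={
            "signature": signature.name,
            "seed": int(seed),
            "cv_auc": float(cv.chosen["mean_auc"]),
            "cv_se_auc": float(cv.chosen["se_auc"]),
            "standardization": "per-cohort",
        },
    )
    scores = predict_proba_matrix(model, test_std)
    y_test = clinical_test.response.loc[scores.index].to_numpy()
    report = confusion_metrics(scores.to_numpy(), y_test, threshold)
    report.notes.extend(notes)
    return model, report, cv


def integrate_signatures(a: FixedSignature, b: FixedSignature) -> FixedSignature:
    """Set union keeping a's order then b's novel genes; named "a+b"."""
    seen = set(a.genes)
    genes = list(a.genes) + [g for g in b.genes if g not in seen]
    return FixedSignature(name=f"{a.name}+{b.name}", genes=genes)


_GROUPS = (("CR/PR", ("CR", "PR")), ("SD", ("SD",)), ("PD", ("PD",)))


def score_group_comparison(scores: pd.Series, recist: pd.Series) -> pd.DataFrame:
    """Pairwise two-sided Mann-Whitney tests of signature scores across
    CR/PR vs SD, CR/PR vs PD, and SD vs PD.

    Exact p-values when both groups have n <= 20; normal approximation with
    tie correction otherwise.
    """
    groups = {
        name: scores.loc[recist[recist.isin(codes)].index.intersection(scores.index)]
        for name, codes in _GROUPS
    }
    rows = []
    pairs = [("CR/PR", "SD"), ("CR/PR", "PD"), ("SD", "PD")]
    for ga, gb in pairs:
        a, b = groups[ga].to_numpy(), groups[gb].to_numpy()
        if a.size == 0 or b.size == 0:
            rows.append({"group_a": ga, "group_b": gb, "n_a": a.size, "n_b": b.size,
                         "u_statistic": np.nan, "pvalue": np.nan, "note": "not applicable (empty group)"})
            continue
        method = "exact" if (a.size <= 20 and b.size <= 20) else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        rows.append({"group_a": ga, "group_b": gb, "n_a": a.size, "n_b": b.size,
                     "u_statistic": float(res.statistic), "pvalue": float(min(res.pvalue, 1.0)),
                     "note": method})
    return pd.DataFrame(rows)
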