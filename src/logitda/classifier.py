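"""Penalized logistic regression, repeated stratified CV, and the LogitDA grid search.

The classifier minimizes

    (1/n) sum_i log(1 + exp(-y_i (b0 + x_i . w))) + lambda * R(w)

with y in {-1,+1}, R = ||w||_2^2 (ridge) or ||w||_1 (lasso) and an
unpenalized intercept.  Fits are delegated to scikit-learn with the exact
C <-> lambda mapping for this objective (C = 1/(2 n lambda) for ridge,
1/(n lambda) for lasso).

Model selection follows the LogitDA protocol: for each (p, alpha_da) grid
point the three-stage feature selection runs once on the full training
cohort, then lambda is tuned by repeated stratified k-fold CV maximizing the
pooled out-of-fold AUC; the winning triple is refit on all training samples.
Test-cohort labels are never read.  The selection-before-CV protocol makes
CV AUC optimistically biased (selection sees the labels); ``nested=True``
reselects features inside every training fold for an unbiased estimate.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    SignatureModel,
    StandardizationParams,
    ValidationError,
)
from .de import de_test
from .preprocess import apply_standardization, counts_to_log2tpm1, standardize
from .selection import SelectionConfig, select_features

logger = logging.getLogger(__name__)


def default_lambda_grid() -> list[float]:
    """30 points log-spaced in [1e-3, 10], bracketing typical ridge optima."""
    return list(np.logspace(-3, 1, 30))


def default_p_grid() -> list[int]:
    return list(range(15, 201, 5)) + list(range(210, 501, 10))


def default_alpha_da_grid() -> list[float]:
    return [round(0.2 + 0.1 * i, 1) for i in range(7)]


@dataclass
class GridConfig:
    """Search space and CV protocol for the LogitDA grid search."""

    p_grid: list[int] = field(default_factory=default_p_grid)
    alpha_da_grid: list[float] = field(default_factory=default_alpha_da_grid)
    lambda_grid: list[float] = field(default_factory=default_lambda_grid)
    k_folds: int = 5
    repeats: int = 100
    seed: int = 0
    objective: str = "auc"
    penalty: str = "l2"
    fdr_threshold: float = 0.10
    de_method: str = "nb_wald"
    da_enabled: bool = True
    nested: bool = False

    def __post_init__(self) -> None:
        if not (self.p_grid and self.alpha_da_grid and self.lambda_grid):
            raise ValidationError("grids must be non-empty")
        if self.k_folds < 2:
            raise ValidationError("k_folds must be >= 2 (or n for leave-one-out)")


def fit_penalized_logit(
    X: np.ndarray, y: np.ndarray, lam: float, penalty: str = "l2"
) -> tuple[np.ndarray, float]:
    """Fit the penalized logit; returns (weights, intercept).

    Deterministic: convex objective, cold start, tight tolerances.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[1] < 1:
        raise ValidationError("X must be samples x features with >= 1 feature")
    if not np.isfinite(X).all():
        raise ValidationError("non-finite values in X")
    classes = np.unique(y)
    if classes.size < 2:
        raise ValidationError("both classes must be present")
    n = X.shape[0]
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if lam == 0:
        clf = LogisticRegression(C=np.inf, solver="lbfgs", tol=1e-10, max_iter=10000)
    elif penalty == "l2":
        C = 1.0 / (2.0 * n * lam)
        clf = LogisticRegression(C=C, solver="lbfgs", tol=1e-10, max_iter=10000)
    elif penalty == "l1":
        C = 1.0 / (n * lam)
        clf = LogisticRegression(
            C=C, l1_ratio=1, solver="saga", tol=1e-10, max_iter=50000, random_state=0
        )
    else:
        raise ValidationError(f"unknown penalty {penalty!r}")
    clf.fit(X, y)
    return clf.coef_.ravel().copy(), float(clf.intercept_[0])


def predict_proba(model: SignatureModel, X_standardized: np.ndarray) -> np.ndarray:
    """sigmoid(b0 + X w) for samples x features input aligned to model.genes."""
    X = np.asarray(X_standardized, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != len(model.genes):
        raise ValidationError(
            f"feature count {X.shape[1]} != model gene count {len(model.genes)}"
        )
    z = model.intercept + X @ model.weights
    return 1.0 / (1.0 + np.exp(-z))


def predict_proba_matrix(model: SignatureModel, expr: ExpressionMatrix) -> pd.Series:
    """Score a standardized genes x samples matrix; errors on missing genes."""
    missing = [g for g in model.genes if g not in set(expr.gene_ids)]
    if missing:
        raise ValidationError(f"genes missing from matrix: {missing}")
    X = expr.values.loc[model.genes].to_numpy(dtype=float).T
    return pd.Series(predict_proba(model, X), index=expr.sample_ids)


def _splitter(y: np.ndarray, k: int, rs: int):
    n = y.size
    if k == n:
        return LeaveOneOut().split(np.zeros(n))
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValidationError(
            f"cannot stratify {k} folds with class counts {counts.tolist()}"
        )
    return StratifiedKFold(n_splits=k, shuffle=True, random_state=rs).split(np.zeros(n), y)


@dataclass
class CVResult:
    """Per-lambda repeated-CV summary; exactly one row is chosen."""

    table: pd.DataFrame  # columns: lam, mean_auc, se_auc, mean_accuracy, chosen

    @property
    def chosen(self) -> pd.Series:
        return self.table[self.table["chosen"]].iloc[0]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    lambda_grid: list[float],
    k: int = 5,
    repeats: int = 100,
    seed: int = 0,
    penalty: str = "l2",
) -> CVResult:
    """Repeated stratified k-fold CV over a lambda grid.

    Per repeat, out-of-fold probabilities are pooled and scored once (AUC,
    accuracy at 0.5); mean and SE over repeats are reported per lambda.  The
    chosen lambda maximizes mean AUC, ties going to the larger lambda.
    """
    from .evaluation import roc_auc  # local import: evaluation imports this module

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = y.size
    lambdas = list(lambda_grid)
    eff_repeats = 1 if k == n else repeats  # LOO folds are deterministic
    rng = np.random.default_rng(seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=eff_repeats)

    aucs = np.empty((eff_repeats, len(lambdas)))
    accs = np.empty_like(aucs)
    for r, rs in enumerate(repeat_seeds):
        folds = list(_splitter(y, k, int(rs)))
        oof = np.empty((n, len(lambdas)))
        for tr, te in folds:
            if np.unique(y[tr]).size < 2:
                raise ValidationError("a training fold lost one class entirely")
            for j, lam in enumerate(lambdas):
                w, b = fit_penalized_logit(X[tr], y[tr], lam, penalty)
                oof[te, j] = 1.0 / (1.0 + np.exp(-(b + X[te] @ w)))
        for j in range(len(lambdas)):
            aucs[r, j] = roc_auc(oof[:, j], y)
            accs[r, j] = float(((oof[:, j] >= 0.5).astype(int) == y).mean())

    mean_auc = aucs.mean(axis=0)
    se_auc = aucs.std(axis=0, ddof=1) / np.sqrt(eff_repeats) if eff_repeats > 1 else np.zeros(len(lambdas))
    mean_acc = accs.mean(axis=0)
    # max mean AUC; ties -> larger lambda (more regularized)
    best = max(range(len(lambdas)), key=lambda j: (mean_auc[j], lambdas[j]))
    table = pd.DataFrame(
        {
            "lam": lambdas,
            "mean_auc": mean_auc,
            "se_auc": se_auc,
            "mean_accuracy": mean_acc,
            "chosen": [j == best for j in range(len(lambdas))],
        }
    )
    return CVResult(table)


def _selection_cache(train_counts, train_log2tpm1, test_log2tpm1, y, cfg: GridConfig):
    """Precompute the stage outputs shared across (p, alpha_da) grid points."""
    from .de import de_filter
    from .preprocess import filter_noninformative_genes
    from .selection import bw_ratios, ks_distances, rank_top_p

    de = de_test(train_counts, y, cfg.de_method)
    de_genes = de_filter(de, cfg.fdr_threshold)
    named = filter_noninformative_genes(de_genes)
    if not named:
        return None
    bw = bw_ratios(train_log2tpm1.subset_genes(named), y)
    full_order = rank_top_p(bw, len(named))
    dists = ks_distances(train_log2tpm1, test_log2tpm1, named) if cfg.da_enabled else None
    return full_order, dists


def grid_search_logitda(
    train_counts: ExpressionMatrix,
    train_clinical: ClinicalTable,
    test_counts: ExpressionMatrix,
    gene_lengths: pd.Series,
    grid: GridConfig,
) -> tuple[SignatureModel, pd.DataFrame]:
    """Joint grid search over (p, alpha_da, lambda); returns the refit model.

    The test cohort enters only through the unsupervised DA stage; with
    ``grid.da_enabled`` False it has no influence at all.  Ties are broken
    toward smaller p, then larger lambda.
    """
    y = train_clinical.response.loc[train_counts.sample_ids].to_numpy()
    train_log2 = counts_to_log2tpm1(train_counts, gene_lengths)
    test_log2 = counts_to_log2tpm1(test_counts, gene_lengths)
    train_std, std_params = standardize(train_log2)

    cache = _selection_cache(train_counts, train_log2, test_log2, y, grid)
    if cache is None:
        raise ValidationError("no genes survive the DE + name-filter stages")
    full_order, dists = cache

    alpha_grid = grid.alpha_da_grid if grid.da_enabled else [float("nan")]
    rows = []
    candidates = []
    for p in sorted(set(grid.p_grid)):
        top = full_order[: min(p, len(full_order))]
        for alpha in alpha_grid:
            if grid.da_enabled:
                kept = [g for g in top if g in dists.index and dists[g] <= alpha]
            else:
                kept = list(top)
            kept = [g for g in kept if g in set(train_std.gene_ids)]
            if not kept:
                logger.warning("grid point (p=%s, alpha_da=%s): empty selection, skipped", p, alpha)
                continue
            X = train_std.values.loc[kept].to_numpy().T
            if grid.nested:
                cv = _nested_cross_validate(train_counts, test_log2, gene_lengths, y, p, alpha, grid)
            else:
                cv = cross_validate(
                    X, y, grid.lambda_grid, grid.k_folds, grid.repeats, grid.seed, grid.penalty
                )
            ch = cv.chosen
            rows.append(
                {
                    "p": p,
                    "alpha_da": alpha,
                    "lam": ch["lam"],
                    "mean_auc": ch["mean_auc"],
                    "se_auc": ch["se_auc"],
                    "mean_accuracy": ch["mean_accuracy"],
                    "n_genes": len(kept),
                }
            )
            candidates.append((ch["mean_auc"], -p, ch["lam"], p, alpha, ch["lam"], kept))
    if not rows:
        raise ValidationError("every grid point produced an empty selection")

    best = max(candidates, key=lambda t: (t[0], t[1], t[2]))
    _, _, _, best_p, best_alpha, best_lam, best_genes = best

    X_full = train_std.values.loc[best_genes].to_numpy().T
    w, b = fit_penalized_logit(X_full, y, best_lam, grid.penalty)
    idx = [std_params.gene_ids.index(g) for g in best_genes]
    model = SignatureModel(
        genes=list(best_genes),
        weights=w,
        intercept=b,
        penalty=grid.penalty,
        lam=float(best_lam),
        train_means=std_params.means[idx],
        train_sds=std_params.sds[idx],
        meta={
            "p": int(best_p),
            "alpha_da": None if not grid.da_enabled else float(best_alpha),
            "cv_auc": float(best[0]),
            "seed": int(grid.seed),
            "da_enabled": bool(grid.da_enabled),
            "nested": bool(grid.nested),
            "standardization": "per-cohort",
        },
    )
    cv_table = pd.DataFrame(rows)
    cv_table["chosen"] = [
        (r["p"] == best_p)
        and (r["lam"] == best_lam)
        and (not grid.da_enabled or r["alpha_da"] == best_alpha)
        for r in rows
    ]
    return model, cv_table


def _nested_cross_validate(
    train_counts: ExpressionMatrix,
    test_log2: ExpressionMatrix,
    gene_lengths: pd.Series,
    y: np.ndarray,
    p: int,
    alpha: float,
    grid: GridConfig,
) -> CVResult:
    """Honest CV: reselect features and re-standardize inside every fold.

    The DA stage still compares against the external unlabeled test cohort;
    only the label-using stages (DE, BW) are confined to the training fold.
    """
    from .evaluation import roc_auc

    n = y.size
    lambdas = list(grid.lambda_grid)
    eff_repeats = 1 if grid.k_folds == n else grid.repeats
    rng = np.random.default_rng(grid.seed)
    repeat_seeds = rng.integers(0, 2**31 - 1, size=eff_repeats)
    sel_cfg = SelectionConfig(
        fdr_threshold=grid.fdr_threshold,
        p=p,
        alpha_da=alpha if grid.da_enabled else 1.0,
        de_method=grid.de_method,
        da_enabled=grid.da_enabled,
    )
    all_samples = train_counts.sample_ids
    full_log2 = counts_to_log2tpm1(train_counts, gene_lengths)

    aucs = np.empty((eff_repeats, len(lambdas)))
    accs = np.empty_like(aucs)
    for r, rs in enumerate(repeat_seeds):
        oof = np.empty((n, len(lambdas)))
        for tr, te in _splitter(y, grid.k_folds, int(rs)):
            tr_ids = [all_samples[i] for i in tr]
            te_ids = [all_samples[i] for i in te]
            fold_counts = train_counts.subset_samples(tr_ids)
            fold_log2 = full_log2.subset_samples(tr_ids)
            genes, _ = select_features(
                fold_counts, fold_log2, test_log2, y[tr], sel_cfg
            )
            fold_std, fold_params = standardize(fold_log2.subset_genes(genes))
            genes = fold_std.gene_ids  # zero-variance genes dropped
            Xtr = fold_std.values.to_numpy().T
            Xte = (
                apply_standardization(full_log2.subset_samples(te_ids), fold_params)
                .values.to_numpy()
                .T
            )
            for j, lam in enumerate(lambdas):
                w, b = fit_penalized_logit(Xtr, y[tr], lam, grid.penalty)
                oof[te, j] = 1.0 / (1.0 + np.exp(-(b + Xte @ w)))
        for j in range(len(lambdas)):
            aucs[r, j] = roc_auc(oof[:, j], y)
            accs[r, j] = float(((oof[:, j] >= 0.5).astype(int) == y).mean())

    mean_auc = aucs.mean(axis=0)
    se_auc = aucs.std(axis=0, ddof=1) / np.sqrt(eff_repeats) if eff_repeats > 1 else np.zeros(len(lambdas))
    best = max(range(len(lambdas)), key=lambda j: (mean_auc[j], lambdas[j]))
    table = pd.DataFrame(
        {
            "lam": lambdas,
            "mean_auc": mean_auc,
            "se_auc": se_auc,
            "mean_accuracy": accs.mean(axis=0),
            "chosen": [j == best for j in range(len(lambdas))],
        }
    )
    return CVResult(table)
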