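"""Penalized logit fits, repeated CV, and the (p, alpha_da, lambda) grid search."""
import numpy as np
import pytest
from scipy.optimize import minimize

from logitda import (
    GridConfig,
    SelectionConfig,
    SignatureModel,
    ValidationError,
    counts_to_log2tpm1,
    cross_validate,
    fit_penalized_logit,
    predict_proba,
    select_features,
    simulate_cohorts,
    standardize,
)
from logitda.classifier import grid_search_logitda
from logitda.simulate import SimulationConfig, null_config


def objective(theta, X, y, lam, penalty):
    """The exact training objective, for the independent optimizer oracle."""
    b0, w = theta[0], theta[1:]
    yy = 2 * y - 1
    margins = -yy * (b0 + X @ w)
    loss = np.logaddexp(0.0, margins).mean()
    reg = lam * (np.sum(w**2) if penalty == "l2" else np.sum(np.abs(w)))
    return loss + reg


@pytest.fixture(scope="module")
def tiny_data():
    rng = np.random.default_rng(3)
    X = rng.normal(size=(8, 2))
    y = np.array([1, 0, 1, 0, 1, 0, 1, 0])
    return X, y


class TestFitPenalizedLogit:
    def test_huge_penalty_shrinks_to_prevalence(self, tiny_data):
        X, y = tiny_data
        w, b = fit_penalized_logit(X, y, lam=1e6, penalty="l2")
        assert np.abs(w).max() < 1e-3
        p = predict_proba(
            SignatureModel(["f0", "f1"], w, b, "l2", 1e6, [0, 0], [1, 1]), X
        )
        assert np.abs(p - y.mean()).max() < 1e-3

    def test_ridge_matches_numeric_optimizer(self, tiny_data):
        X, y = tiny_data
        lam = 0.1
        w, b = fit_penalized_logit(X, y, lam, "l2")
        res = minimize(
            objective, np.zeros(3), args=(X, y, lam, "l2"), method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000},
        )
        np.testing.assert_allclose([b, *w], res.x, atol=1e-4)

    def test_ridge_solution_unique_across_starts(self, tiny_data):
        """Convexity: random-start numeric optimization lands on the same point."""
        X, y = tiny_data
        lam = 0.05
        w, b = fit_penalized_logit(X, y, lam, "l2")
        rng = np.random.default_rng(7)
        for _ in range(5):
            res = minimize(
                objective, rng.normal(scale=2.0, size=3), args=(X, y, lam, "l2"),
                method="BFGS", options={"gtol": 1e-12},
            )
            np.testing.assert_allclose([b, *w], res.x, atol=1e-6)

    def test_lasso_zero_above_lambda_max(self, tiny_data):
        X, y = tiny_data
        lam_max = np.abs(X.T @ (y - y.mean())).max() / len(y)
        w, b = fit_penalized_logit(X, y, 1.5 * lam_max, "l1")
        np.testing.assert_array_equal(w, 0.0)
        w2, _ = fit_penalized_logit(X, y, 0.5 * lam_max, "l1")
        assert np.abs(w2).max() > 0

    def test_single_class_rejected(self, tiny_data):
        X, _ = tiny_data
        with pytest.raises(ValidationError):
            fit_penalized_logit(X, np.ones(8, dtype=int), 0.1, "l2")

    def test_nonfinite_rejected(self, tiny_data):
        X, y = tiny_data
        bad = X.copy()
        bad[0, 0] = np.nan
        with pytest.raises(ValidationError):
            fit_penalized_logit(bad, y, 0.1, "l2")


class TestPredictProba:
    def model(self, w, b):
        k = len(w)
        return SignatureModel([f"g{i}" for i in range(k)], w, b, "l2", 0.1,
                              np.zeros(k), np.ones(k))

    def test_zero_weights_give_half(self):
        p = predict_proba(self.model([0.0, 0.0], 0.0), np.random.default_rng(0).normal(size=(5, 2)))
        np.testing.assert_allclose(p, 0.5)

    def test_monotone_in_positive_weight_feature(self):
        m = self.model([2.0], 0.0)
        x = np.linspace(-3, 3, 11)[:, None]
        p = predict_proba(m, x)
        assert (np.diff(p) > 0).all()

    def test_training_round_trip(self, tiny_data):
        X, y = tiny_data
        w, b = fit_penalized_logit(X, y, 0.1, "l2")
        m = self.model(w, b)
        p1 = predict_proba(m, X)
        p2 = 1 / (1 + np.exp(-(b + X @ w)))
        np.testing.assert_allclose(p1, p2, atol=1e-15)

    def test_feature_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            predict_proba(self.model([1.0], 0.0), np.zeros((3, 2)))


class TestCrossValidate:
    def test_pure_noise_auc_near_half(self):
        # a single n=100 dataset carries ~0.08 AUC sampling noise, so
        # calibration is checked on the mean over replicate null datasets
        aucs = []
        for rep in range(12):
            rng = np.random.default_rng(100 + rep)
            X = rng.normal(size=(100, 20))
            y = (rng.uniform(size=100) < 0.3).astype(int)
            cv = cross_validate(X, y, [0.1, 1.0], k=5, repeats=3, seed=rep)
            aucs.append(cv.chosen["mean_auc"])
        assert abs(np.mean(aucs) - 0.5) <= 0.05

    def test_determinism_and_seed_sensitivity(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 5))
        y = np.array([0, 1] * 20)
        a = cross_validate(X, y, [0.1, 1.0], k=5, repeats=4, seed=9)
        b = cross_validate(X, y, [0.1, 1.0], k=5, repeats=4, seed=9)
        c = cross_validate(X, y, [0.1, 1.0], k=5, repeats=4, seed=10)
        assert a.table.equals(b.table)
        assert not a.table.equals(c.table)

    def test_strong_signal_recovers_high_auc(self):
        rng = np.random.default_rng(21)
        n = 200
        y = (rng.uniform(size=n) < 0.3).astype(int)
        X = rng.normal(size=(n, 10))
        X[:, :3] += 1.5 * y[:, None]
        cv = cross_validate(X, y, [0.01, 0.1, 1.0], k=5, repeats=5, seed=3)
        assert cv.chosen["mean_auc"] >= 0.85

    def test_tie_prefers_larger_lambda(self):
        # constant features: every lambda yields identical (all-tied) scores
        X = np.zeros((20, 2))
        y = np.array([0, 1] * 10)
        cv = cross_validate(X, y, [0.1, 1.0, 10.0], k=5, repeats=2, seed=0)
        assert cv.chosen["lam"] == 10.0

    def test_unstratifiable_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        y = np.array([1, 1, 0, 0, 0, 0, 0, 0, 0, 0])
        with pytest.raises(ValidationError):
            cross_validate(X, y, [0.1], k=5, repeats=1, seed=0)


@pytest.fixture(scope="module")
def grid_sim():
    cfg = SimulationConfig(
        n_genes=300, n_train=80, n_test=60, n_informative=20, n_shifted=10,
        frac_informative_shifted=0.5, seed=13,
    )
    return simulate_cohorts(cfg)


class TestGridSearch:
    LAM = [0.03, 0.3, 3.0]

    def test_degenerate_grid_equals_manual_composition(self, grid_sim):
        sim = grid_sim
        grid = GridConfig(
            p_grid=[15], alpha_da_grid=[0.4], lambda_grid=self.LAM,
            repeats=3, seed=5,
        )
        model, cv_table = grid_search_logitda(
            sim.train_counts, sim.train_clinical, sim.test_counts, sim.gene_lengths, grid
        )
        # manual: select once, CV over lambda, refit at chosen lambda
        train_log2 = counts_to_log2tpm1(sim.train_counts, sim.gene_lengths)
        test_log2 = counts_to_log2tpm1(sim.test_counts, sim.gene_lengths)
        y = sim.train_clinical.response.to_numpy()
        genes, _ = select_features(
            sim.train_counts, train_log2, test_log2, y,
            SelectionConfig(p=15, alpha_da=0.4),
        )
        std, _ = standardize(train_log2)
        X = std.values.loc[[g for g in genes if g in set(std.gene_ids)]].to_numpy().T
        cv = cross_validate(X, y, self.LAM, k=5, repeats=3, seed=5)
        assert model.lam == cv.chosen["lam"]
        assert sorted(model.genes) == sorted(g for g in genes if g in set(std.gene_ids))
        w, b = fit_penalized_logit(
            std.values.loc[model.genes].to_numpy().T, y, model.lam, "l2"
        )
        np.testing.assert_allclose(model.weights, w, atol=1e-10)
        np.testing.assert_allclose(model.intercept, b, atol=1e-10)

    def test_without_da_test_cohort_has_no_influence(self, grid_sim):
        sim = grid_sim
        grid = GridConfig(
            p_grid=[15, 30], alpha_da_grid=[0.3], lambda_grid=self.LAM,
            repeats=2, seed=1, da_enabled=False,
        )
        m1, t1 = grid_search_logitda(
            sim.train_counts, sim.train_clinical, sim.test_counts, sim.gene_lengths, grid
        )
        other = simulate_cohorts(
            SimulationConfig(n_genes=300, n_train=10, n_test=40, n_informative=0,
                             n_shifted=0, seed=99)
        )
        m2, t2 = grid_search_logitda(
            sim.train_counts, sim.train_clinical, other.test_counts, sim.gene_lengths, grid
        )
        assert m1.genes == m2.genes
        np.testing.assert_array_equal(m1.weights, m2.weights)
        assert t1.equals(t2)

    def test_deterministic_given_seed(self, grid_sim):
        sim = grid_sim
        grid = GridConfig(p_grid=[20], alpha_da_grid=[0.3], lambda_grid=self.LAM,
                          repeats=2, seed=8)
        m1, _ = grid_search_logitda(
            sim.train_counts, sim.train_clinical, sim.test_counts, sim.gene_lengths, grid
        )
        m2, _ = grid_search_logitda(
            sim.train_counts, sim.train_clinical, sim.test_counts, sim.gene_lengths, grid
        )
        assert m1.genes == m2.genes
        np.testing.assert_array_equal(m1.weights, m2.weights)

    def test_nested_variant_runs_and_reports_lower_auc(self, grid_sim):
        """Reselecting inside folds removes the selection optimism."""
        sim = grid_sim
        base = dict(p_grid=[20], alpha_da_grid=[0.4], lambda_grid=[0.3], repeats=2, seed=2)
        m_plain, t_plain = grid_search_logitda(
            sim.train_counts, sim.train_clinical, sim.test_counts, sim.gene_lengths,
            GridConfig(**base),
        )
        m_nested, t_nested = grid_search_logitda(
            sim.train_counts, sim.train_clinical, sim.test_counts, sim.gene_lengths,
            GridConfig(nested=True, **base),
        )
        assert m_nested.meta["nested"]
        assert t_nested["mean_auc"].iloc[0] <= t_plain["mean_auc"].iloc[0] + 0.05
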