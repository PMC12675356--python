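"""BW-ratio, KS distance, the DA filter, and the composed selection pipeline."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from logitda import (
    SelectionConfig,
    ValidationError,
    bw_ratio,
    bw_ratios,
    counts_to_log2tpm1,
    da_filter,
    ks_distance,
    rank_top_p,
    select_features,
    simulate_cohorts,
)
from logitda.datatypes import ClinicalTable
from logitda.simulate import SimulationConfig, signal_config

from conftest import make_expr


def bw_oracle(values, response):
    x, y = np.asarray(values, float), np.asarray(response, int)
    grand = x.mean()
    between = within = 0.0
    for cls in (0, 1):
        grp = x[y == cls]
        between += len(grp) * (grp.mean() - grand) ** 2
        for v in grp:
            within += (v - grp.mean()) ** 2
    if within == 0:
        return float("inf") if between > 0 else 0.0
    return between / within


def ks_oracle(a, b):
    a, b = np.asarray(a, float), np.asarray(b, float)
    return max(
        abs((a <= x).mean() - (b <= x).mean()) for x in np.concatenate([a, b])
    )


class TestBWRatio:
    def test_hand_computed_example(self):
        assert bw_ratio([0, 2, 1, 3], [1, 1, 0, 0]) == pytest.approx(0.25)

    def test_equal_class_means_zero(self):
        assert bw_ratio([1, 3, 1, 3], [1, 1, 0, 0]) == 0.0

    def test_zero_within_ss_is_infinite(self):
        assert bw_ratio([0, 0, 1, 1], [1, 1, 0, 0]) == float("inf")

    def test_empty_class_rejected(self):
        with pytest.raises(ValidationError):
            bw_ratio([1.0, 2.0], [1, 1])

    @given(st.integers(0, 2**31 - 1), st.integers(4, 50))
    @settings(max_examples=40, deadline=None)
    def test_matches_double_loop_oracle(self, seed, n):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=n)
        y = np.zeros(n, dtype=int)
        y[: rng.integers(1, n)] = 1
        assert bw_ratio(x, y) == pytest.approx(bw_oracle(x, y), abs=1e-12)

    def test_vectorized_matches_scalar(self, small_sim_log2, small_sim):
        train, _ = small_sim_log2
        y = small_sim.train_clinical.response.to_numpy()
        vec = bw_ratios(train, y)
        for g in train.gene_ids[:25]:
            assert vec[g] == pytest.approx(
                bw_ratio(train.values.loc[g].to_numpy(), y), rel=1e-10
            )

    def test_affine_rescaling_invariance(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=30)
        y = (rng.uniform(size=30) < 0.4).astype(int)
        assert bw_ratio(3.5 * x - 7.0, y) == pytest.approx(bw_ratio(x, y), rel=1e-10)


class TestRankTopP:
    def test_sorts_descending(self):
        s = pd.Series({"A": 0.5, "B": 0.9, "C": 0.1})
        assert rank_top_p(s, 2) == ["B", "A"]

    def test_lexicographic_tie_break(self):
        s = pd.Series({"B": 0.5, "A": 0.5})
        assert rank_top_p(s, 1) == ["A"]

    def test_truncation_warns(self):
        s = pd.Series({"A": 0.5})
        with pytest.warns(UserWarning):
            assert rank_top_p(s, 5) == ["A"]


class TestKSDistance:
    def test_identical_vectors_zero(self):
        assert ks_distance([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert ks_distance([0, 1, 2, 3], [10, 11, 12, 13]) == 1.0

    def test_shifted_quartet(self):
        assert ks_distance([1, 2, 3, 4], [2, 3, 4, 5]) == pytest.approx(0.25)

    def test_short_vector_rejected(self):
        with pytest.raises(ValidationError):
            ks_distance([1.0], [1.0, 2.0])

    @given(st.integers(0, 2**31 - 1), st.integers(2, 40), st.integers(2, 40))
    @settings(max_examples=40, deadline=None)
    def test_matches_ecdf_oracle_and_symmetry(self, seed, n, m):
        rng = np.random.default_rng(seed)
        a = rng.normal(size=n)
        b = rng.normal(loc=rng.normal(), size=m)
        d = ks_distance(a, b)
        assert d == pytest.approx(ks_oracle(a, b), abs=1e-12)
        assert d == pytest.approx(ks_distance(b, a), abs=1e-15)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(9)
        a, b = rng.normal(size=25), rng.normal(1.0, 2.0, size=30)
        d = ks_distance(a, b)
        assert ks_distance(np.exp(a), np.exp(b)) == pytest.approx(d, abs=1e-15)
        assert ks_distance(a**3, b**3) == pytest.approx(d, abs=1e-15)


class TestDAFilter:
    def test_alpha_one_retains_all(self, small_sim_log2):
        train, test = small_sim_log2
        kept, _ = da_filter(train, test, train.gene_ids, alpha_da=1.0)
        assert kept == train.gene_ids

    def test_train_equals_test_retains_all(self, small_sim_log2):
        train, _ = small_sim_log2
        kept, dists = da_filter(train, train, train.gene_ids, alpha_da=0.2)
        assert kept == train.gene_ids
        assert (dists == 0).all()

    def test_absent_test_gene_dropped_with_warning(self, small_sim_log2):
        train, test = small_sim_log2
        reduced = test.subset_genes(test.gene_ids[1:])
        with pytest.warns(UserWarning, match="absent"):
            kept, _ = da_filter(train, reduced, train.gene_ids[:5], alpha_da=1.0)
        assert train.gene_ids[0] not in kept

    def test_location_shifted_genes_removed(self):
        """Strong test-only location shifts are detected; unshifted genes mostly kept."""
        cfg = SimulationConfig(
            n_genes=2000, n_train=100, n_test=100, n_informative=0,
            n_shifted=50, shift_location=2.0, seed=5,
        )
        sim = simulate_cohorts(cfg)
        train = counts_to_log2tpm1(sim.train_counts, sim.gene_lengths)
        test = counts_to_log2tpm1(sim.test_counts, sim.gene_lengths)
        kept, _ = da_filter(train, test, train.gene_ids, alpha_da=0.2)
        kept_set = set(kept)
        shifted = set(sim.truth.shifted_genes)
        unshifted = set(train.gene_ids) - shifted
        frac_shifted_removed = 1 - len(kept_set & shifted) / len(shifted)
        frac_unshifted_removed = 1 - len(kept_set & unshifted) / len(unshifted)
        assert frac_shifted_removed >= 0.9
        assert frac_unshifted_removed <= 0.2


class TestSelectFeatures:
    def test_recovers_transferable_informative_genes(self):
        sim = simulate_cohorts(signal_config(seed=7))
        train = counts_to_log2tpm1(sim.train_counts, sim.gene_lengths)
        test = counts_to_log2tpm1(sim.test_counts, sim.gene_lengths)
        y = sim.train_clinical.response.to_numpy()
        genes, score = select_features(
            sim.train_counts, train, test, y, SelectionConfig(p=150, alpha_da=0.2)
        )
        informative = set(sim.truth.informative_genes)
        shifted = set(sim.truth.shifted_genes)
        unshifted = informative - shifted
        recall = len(set(genes) & unshifted) / len(unshifted)
        contamination = len(set(genes) & shifted) / len(genes)
        assert recall >= 0.5
        assert contamination <= 0.1
        # flags are monotone along the pipeline
        f = score.table
        assert not (f["passed_da"] & ~f["in_top_p"]).any()
        assert not (f["in_top_p"] & ~f["passed_name_filter"]).any()
        assert not (f["passed_name_filter"] & ~f["passed_de"]).any()

    def test_degenerate_config_reduces_to_de_and_name_filter(self, small_sim, small_sim_log2):
        train, test = small_sim_log2
        y = small_sim.train_clinical.response.to_numpy()
        cfg = SelectionConfig(p=small_sim.train_counts.n_genes, alpha_da=1.0)
        genes, score = select_features(small_sim.train_counts, train, test, y, cfg)
        expected = score.table.index[
            score.table["passed_de"] & score.table["passed_name_filter"]
        ]
        assert set(genes) == set(expected)

    def test_da_disabled_reproduces_top_p_only(self, small_sim, small_sim_log2):
        train, test = small_sim_log2
        y = small_sim.train_clinical.response.to_numpy()
        with_da = SelectionConfig(p=10, alpha_da=0.2, da_enabled=True)
        without = SelectionConfig(p=10, alpha_da=0.2, da_enabled=False)
        g_da, _ = select_features(small_sim.train_counts, train, test, y, with_da)
        g_no, score = select_features(small_sim.train_counts, train, test, y, without)
        assert len(g_no) == 10
        assert set(g_da) <= set(g_no)
        assert score.table["ks_distance"].isna().all()

    def test_test_labels_never_influence_selection(self, small_sim, small_sim_log2):
        """The unsupervised contract: scrambling test labels changes nothing."""
        train, test = small_sim_log2
        y = small_sim.train_clinical.response.to_numpy()
        cfg = SelectionConfig(p=20, alpha_da=0.4)
        before, _ = select_features(small_sim.train_counts, train, test, y, cfg)
        scrambled = small_sim.test_clinical.table.copy()
        scrambled["response"] = np.random.default_rng(0).permutation(
            scrambled["response"].to_numpy()
        )
        ClinicalTable(scrambled.drop(columns="recist"))  # still a valid table
        after, _ = select_features(small_sim.train_counts, train, test, y, cfg)
        assert before == after
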