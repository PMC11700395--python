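"""Spearman scoring, CV planning, the CV runner and nonparametric tests."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu, spearmanr

from xferdrp.evaluation import (CVPlan, make_cv_plan, paired_wilcoxon,
                                rank_sum_test, run_cv, spearman,
                                subsample_sweep)
from xferdrp.preprocess import PreprocessConfig

from conftest import make_dataset


def brute_force_spearman(x, y):
    """Independent oracle: O(n^2) average ranks + analytic Pearson."""
    def avg_ranks(v):
        v = np.asarray(v, float)
        return np.array([(np.sum(v < vi) + 1 + np.sum(v <= vi)) / 2 for vi in v])

    rx, ry = avg_ranks(x), avg_ranks(y)
    dx, dy = rx - rx.mean(), ry - ry.mean()
    denom = np.sqrt(np.sum(dx ** 2) * np.sum(dy ** 2))
    return np.dot(dx, dy) / denom if denom else np.nan


class TestSpearman:
    def test_identity_and_reversal(self):
        assert spearman([1, 2, 3, 4, 5], [1, 2, 3, 4, 5]) == 1.0
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]) == -1.0

    def test_single_swap_gives_half(self):
        assert spearman([1, 2, 3], [1, 3, 2]) == pytest.approx(0.5)

    def test_constant_vector_returns_zero_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            assert spearman([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch_and_short_vectors_raise(self):
        with pytest.raises(ValueError):
            spearman([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            spearman([1, 2], [1, 2])

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(3, 30)
            x = rng.integers(0, 5, n).astype(float)
            y = rng.integers(0, 5, n).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            assert spearman(x, y) == pytest.approx(
                spearmanr(x, y).statistic, abs=1e-12)

    @given(st.lists(st.integers(-50, 50), min_size=4, max_size=25, unique=True),
           st.sampled_from([np.exp, np.cbrt, lambda v: 3 * v + 1]))
    def test_invariant_under_strictly_increasing_transform(self, xs, f):
        xs = [float(x) for x in xs]
        rng = np.random.default_rng(abs(hash(tuple(xs))) % 2 ** 31)
        ys = rng.standard_normal(len(xs))
        base = spearman(xs, ys)
        assert spearman(f(np.asarray(xs)), ys) == pytest.approx(base, abs=1e-12)


class TestCVPlan:
    def test_ten_samples_five_folds_is_exact_partition(self):
        plan = make_cv_plan(np.arange(10.0), k=5, repetitions=3, seed=1,
                            strat_bins=2)
        for rep in range(3):
            counts = np.bincount(plan.assignments[rep], minlength=5)
            assert np.all(counts == 2)

    def test_determinism_and_hash_stability(self):
        auc = np.random.default_rng(3).random(22)
        a = make_cv_plan(auc, 3, 10, 42, 3)
        b = make_cv_plan(auc, 3, 10, 42, 3)
        np.testing.assert_array_equal(a.assignments, b.assignments)
        assert a.plan_hash == b.plan_hash
        c = make_cv_plan(auc, 3, 10, 43, 3)
        assert c.plan_hash != a.plan_hash

    def test_fold_and_bin_balance_n22_k3(self):
        auc = np.random.default_rng(7).random(22)
        plan = make_cv_plan(auc, 3, 10, 5, 3)
        order = np.argsort(auc, kind="stable")
        bins = np.empty(22, dtype=int)
        for b in range(3):
            bins[order[(22 * b) // 3:(22 * (b + 1)) // 3]] = b
        for rep in range(10):
            a = plan.assignments[rep]
            fold_sizes = np.bincount(a, minlength=3)
            assert fold_sizes.max() - fold_sizes.min() <= 1
            assert sorted(fold_sizes) == [7, 7, 8]
            for b in range(3):
                per_bin = np.bincount(a[bins == b], minlength=3)
                assert per_bin.max() - per_bin.min() <= 1

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            make_cv_plan(np.arange(4.0), k=5, repetitions=1, seed=0,
                         strat_bins=1)


class _OraclePredictor:
    def __init__(self, lookup):
        self.lookup = lookup

    def predict(self, expr):
        return np.array([self.lookup[s] for s in expr.sample_ids])


class _ConstantPredictor:
    def predict(self, expr):
        return np.full(expr.n_samples, 5.0)


class TestRunCV:
    @pytest.fixture
    def ds(self):
        return make_dataset(10, 22, seed=4)

    @pytest.fixture
    def plan(self, ds):
        return make_cv_plan(ds.response.auc, 3, 10, 99, 3)

    def test_oracle_predictor_scores_one_every_repetition(self, ds, plan):
        lookup = dict(zip(ds.response.sample_ids, ds.response.auc))
        res = run_cv(ds, lambda tr, seed: _OraclePredictor(lookup), plan)
        np.testing.assert_array_equal(res.per_rep_scc, np.ones(10))

    def test_constant_predictor_scores_zero_with_warnings(self, ds, plan):
        with pytest.warns(UserWarning, match="constant"):
            res = run_cv(ds, lambda tr, seed: _ConstantPredictor(), plan)
        np.testing.assert_array_equal(res.per_rep_scc, np.zeros(10))

    def test_random_predictor_near_null(self, ds, plan):
        class Rand:
            def __init__(self, seed):
                self.rng = np.random.default_rng(seed)

            def predict(self, expr):
                return self.rng.random(expr.n_samples)

        res = run_cv(ds, lambda tr, seed: Rand(seed), plan)
        assert abs(res.mean_scc) < 0.25

    def test_result_statistics_recomputable(self, ds, plan):
        lookup = dict(zip(ds.response.sample_ids, ds.response.auc))
        res = run_cv(ds, lambda tr, seed: _OraclePredictor(lookup), plan,
                     label="oracle")
        assert res.mean_scc == pytest.approx(res.per_rep_scc.mean())
        assert res.sd_scc == pytest.approx(res.per_rep_scc.std(ddof=1))
        assert res.plan_hash == plan.plan_hash
        frame = res.to_frame()
        assert list(frame.columns) == ["label", "repetition", "scc"]
        assert len(frame) == 10

    def test_fit_on_train_mode_runs(self, ds, plan):
        lookup = dict(zip(ds.response.sample_ids, ds.response.auc))
        res = run_cv(ds, lambda tr, seed: _OraclePredictor(lookup), plan,
                     PreprocessConfig(standardize_mode="fit_on_train"))
        np.testing.assert_array_equal(res.per_rep_scc, np.ones(10))


def wilcoxon_enumeration_oracle(a, b):
    """Literal 2^n sign enumeration of the signed-rank null (two-sided)."""
    from scipy.stats import rankdata

    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    signs = np.array(list(itertools.product([0, 1], repeat=n)))
    sums = signs @ ranks
    p_le = np.mean(sums <= w_obs + 1e-12)
    p_ge = np.mean(sums >= w_obs - 1e-12)
    return min(1.0, 2 * min(p_le, p_ge))


class TestPairedWilcoxon:
    def test_five_positive_differences(self):
        assert paired_wilcoxon([2, 3, 4, 5, 6], [1, 1, 1, 1, 1]) == 0.0625

    def test_equal_vectors_give_p_one_with_warning(self):
        with pytest.warns(UserWarning, match="zero"):
            assert paired_wilcoxon([1.0] * 6, [1.0] * 6) == 1.0

    def test_nine_positive_one_smallest_negative(self):
        d = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, -0.5])
        assert paired_wilcoxon(d + 10, np.full(10, 10.0)) == 0.00390625

    def test_matches_enumeration_on_random_instances(self):
        rng = np.random.default_rng(17)
        for n in (5, 7, 9, 12):
            for _ in range(25):
                a = rng.integers(-4, 5, n).astype(float)
                b = rng.integers(-4, 5, n).astype(float)
                if np.all(a == b):
                    continue
                assert paired_wilcoxon(a, b) == pytest.approx(
                    wilcoxon_enumeration_oracle(a, b), abs=1e-12)

    def test_large_n_normal_approximation_reasonable(self):
        rng = np.random.default_rng(2)
        a = rng.standard_normal(40) + 1.0
        b = rng.standard_normal(40)
        p = paired_wilcoxon(a, b)
        assert 0 < p < 0.01

    def test_short_input_raises(self):
        with pytest.raises(ValueError):
            paired_wilcoxon([1, 2], [2, 1])


class TestRankSum:
    def test_two_vs_two_extreme(self):
        assert rank_sum_test([1, 2], [3, 4]) == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        assert rank_sum_test([1, 2], [1, 2]) == 1.0

    def test_empty_group_raises(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            m, n = rng.integers(2, 6), rng.integers(2, 6)
            pool = rng.permutation(100)[:m + n].astype(float)
            a, b = pool[:m], pool[m:]
            expected = mannwhitneyu(a, b, alternative="two-sided",
                                    method="exact").pvalue
            assert rank_sum_test(a, b) == pytest.approx(expected, abs=1e-12)


class TestSubsampleSweep:
    def test_row_count_and_determinism(self):
        ds = make_dataset(8, 22, seed=1)

        def experiment(subset, cell_seed):
            plan = make_cv_plan(subset.response.auc, 3, 4, cell_seed, 3)
            lookup = dict(zip(subset.response.sample_ids, subset.response.auc))
            return run_cv(subset, lambda tr, s: _OraclePredictor(lookup), plan)

        t1 = subsample_sweep(ds, [10, 13, 15, 18, 20], 3, experiment, seed=5)
        t2 = subsample_sweep(ds, [10, 13, 15, 18, 20], 3, experiment, seed=5)
        assert len(t1) == 15
        assert t1.equals(t2)

    def test_size_equal_to_n_raises(self):
        ds = make_dataset(5, 10, seed=2)
        with pytest.raises(ValueError):
            subsample_sweep(ds, [10], 1, lambda s, c: None, seed=0)
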