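"""Subset sampling, accuracy rewards, bandit ranking and the t-test baseline."""

import numpy as np
import pytest
from scipy import stats

from banditsel.ranking import (
    FeatureSubset,
    LabeledTable,
    evaluate_subset,
    fit_ridge_logistic,
    rank_subsets,
    sample_subsets,
    ttest_rank,
    accuracy_curve,
)


class TestLabeledTable:
    def test_drops_rows_with_missing_values(self, rng):
        values = rng.normal(size=(6, 3))
        values[2, 1] = np.nan
        table = LabeledTable(values, np.array([0, 1, 0, 1, 0, 1]),
                             ["a", "b", "c"], [f"s{i}" for i in range(6)])
        assert table.n == 5
        assert table.n_dropped == 1

    def test_requires_both_classes(self, rng):
        with pytest.raises(ValueError):
            LabeledTable(rng.normal(size=(4, 2)), np.zeros(4, int),
                         ["a", "b"], list("wxyz"))

    def test_dataframe_round_trip(self, separable_table):
        df = separable_table.to_dataframe("cls")
        back = LabeledTable.from_dataframe(df, "cls")
        np.testing.assert_allclose(back.values, separable_table.values)
        np.testing.assert_array_equal(back.labels, separable_table.labels)


class TestSampleSubsets:
    def test_shape_and_range(self):
        subs = sample_subsets(10474, 100, 30, seed=0)
        assert len(subs) == 100
        assert all(len(s) == 30 for s in subs)
        assert all(0 <= i < 10474 for s in subs for i in s.indices)
        # without replacement: no repeats inside a subset
        assert all(len(set(s.indices)) == 30 for s in subs)

    def test_full_universe_when_size_equals_p(self):
        (s,) = sample_subsets(3, 1, 3, seed=1)
        assert sorted(s.indices) == [0, 1, 2]

    def test_reproducible(self):
        assert sample_subsets(50, 5, 4, seed=9) == sample_subsets(50, 5, 4, seed=9)

    def test_oversized_subset_rejected_without_replacement(self):
        with pytest.raises(ValueError):
            sample_subsets(3, 1, 5)


class TestEvaluateSubset:
    def test_separable_feature_reaches_perfect_accuracy(self, separable_table, rng):
        acc = evaluate_subset(separable_table, FeatureSubset([0]), rng=rng)
        assert acc == 1.0

    def test_noise_features_score_at_chance(self, rng):
        # a fresh noise table per repetition: within one fixed table,
        # complement splits are pessimistically biased (train and test class
        # means anticorrelate), so chance level holds across tables
        accs = []
        for _ in range(300):
            table = LabeledTable(
                rng.normal(size=(40, 3)),
                np.r_[np.zeros(20, int), np.ones(20, int)],
                ["a", "b", "c"], [f"s{i}" for i in range(40)],
            )
            accs.append(evaluate_subset(table, FeatureSubset([1, 2]), rng=rng))
        assert np.mean(accs) == pytest.approx(0.5, abs=0.05)

    def test_accuracy_is_a_proportion(self, separable_table, rng):
        for _ in range(10):
            acc = evaluate_subset(separable_table, FeatureSubset([3, 4]), rng=rng)
            assert 0.0 <= acc <= 1.0

    def test_sklearn_estimator_accepted(self, separable_table, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        clf = sklearn.LogisticRegression(max_iter=500)
        acc = evaluate_subset(separable_table, FeatureSubset([0]),
                              classifier=clf, rng=rng)
        assert acc == 1.0


class TestRidgeLogistic:
    def test_matches_sklearn_coefficients(self, rng):
        sklearn = pytest.importorskip("sklearn.linear_model")
        X = rng.normal(size=(200, 3))
        y = (X @ [1.0, -2.0, 0.5] + 0.3 * rng.normal(size=200) > 0).astype(int)
        ridge = 1.0
        beta = fit_ridge_logistic(X, y, ridge=ridge)
        clf = sklearn.LogisticRegression(C=1.0 / ridge, max_iter=2000, tol=1e-10)
        clf.fit(X, y)
        np.testing.assert_allclose(beta[1:], clf.coef_[0], atol=2e-4)
        np.testing.assert_allclose(beta[0], clf.intercept_[0], atol=2e-4)

    def test_stable_under_perfect_separation(self, rng):
        X = np.r_[rng.normal(-3, 0.1, (10, 1)), rng.normal(3, 0.1, (10, 1))]
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        beta = fit_ridge_logistic(X, y, ridge=1.0)
        assert np.isfinite(beta).all()


class TestRankSubsets:
    def test_single_subset_gets_probability_one(self, separable_table):
        ens = rank_subsets(separable_table, [FeatureSubset([0])], T=5, seed=0)
        np.testing.assert_array_equal(ens.probs, [1.0])

    def test_informative_subset_beats_noise(self, separable_table):
        ens = rank_subsets(
            separable_table,
            [FeatureSubset([1, 2]), FeatureSubset([0])],
            T=2000,
            seed=0,
        )
        assert ens.ranked_indices()[0] == 1
        assert ens.probs.sum() == pytest.approx(1.0, abs=1e-9)
        assert set(np.flatnonzero(ens.thresholded)) <= set(np.flatnonzero(ens.probs))

    def test_selected_features_modes(self, separable_table):
        subsets = [FeatureSubset([0, 1]), FeatureSubset([2, 3])]
        ens = rank_subsets(separable_table, subsets, T=500, seed=1)
        top = ens.selected_features(separable_table, thresholded=False)
        assert top == frozenset(subsets[int(ens.ranked_indices()[0])]
                                .feature_ids(separable_table))
        survivors = ens.selected_features(separable_table, thresholded=True)
        expected = frozenset().union(
            *(frozenset(ens.subsets[i].feature_ids(separable_table))
              for i in np.flatnonzero(ens.thresholded > 0))
        )
        assert survivors == expected and len(survivors) > 0

    def test_no_spurious_concentration_on_pure_noise(self, rng):
        # all-noise arms: the final distribution stays near uniform
        table = LabeledTable(
            rng.normal(size=(40, 60)),
            np.r_[np.zeros(20, int), np.ones(20, int)],
            [f"f{j}" for j in range(60)],
            [f"s{i}" for i in range(40)],
        )
        subsets = sample_subsets(60, 50, 5, seed=rng)
        ens = rank_subsets(table, subsets, T=2000, seed=4)
        gamma_over_k = (1 / np.log(2001)) / 50
        assert ens.probs.min() >= gamma_over_k - 1e-12
        assert ens.probs.max() <= gamma_over_k + 0.1

    def test_reproducible_given_seed(self, separable_table):
        subsets = [FeatureSubset([0]), FeatureSubset([1, 2]), FeatureSubset([3])]
        a = rank_subsets(separable_table, subsets, T=300, seed=5)
        b = rank_subsets(separable_table, subsets, T=300, seed=5)
        np.testing.assert_array_equal(a.probs, b.probs)


class TestTTestRank:
    def test_dominant_feature_ranks_first(self, separable_table):
        assert ttest_rank(separable_table, 1).order[0] == 0

    def test_matches_scipy_welch(self, noise_table):
        ranking = ttest_rank(noise_table, 3)
        X, y = noise_table.values, noise_table.labels
        ref = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=False).statistic
        np.testing.assert_allclose(ranking.tstats, ref, rtol=1e-10)

    def test_pooled_variant_matches_scipy(self, noise_table):
        ranking = ttest_rank(noise_table, 3, equal_var=True)
        X, y = noise_table.values, noise_table.labels
        ref = stats.ttest_ind(X[y == 1], X[y == 0], equal_var=True).statistic
        np.testing.assert_allclose(ranking.tstats, ref, rtol=1e-10)

    def test_invariant_to_affine_rescaling(self, noise_table):
        base = ttest_rank(noise_table, 4)
        scaled = LabeledTable(
            noise_table.values * 3.7 - 12.0,
            noise_table.labels,
            noise_table.feature_ids,
            noise_table.sample_ids,
        )
        np.testing.assert_array_equal(ttest_rank(scaled, 4).order, base.order)

    def test_top_p_returns_everything(self, noise_table):
        ranking = ttest_rank(noise_table, noise_table.p)
        assert len(ranking.top_feature_ids(noise_table)) == noise_table.p

    def test_zero_variance_feature_stays_finite(self):
        values = np.c_[np.ones(8), np.r_[np.zeros(4), np.ones(4)]]
        table = LabeledTable(values, np.r_[np.zeros(4, int), np.ones(4, int)],
                             ["const", "good"], [f"s{i}" for i in range(8)])
        ranking = ttest_rank(table, 1)
        assert np.isfinite(ranking.tstats).all()
        assert ranking.order[0] == 1

    def test_permuted_labels_behave_like_random_selection(self, rng):
        # under label permutation the top-k sets should barely overlap:
        # the mean I-overlap stays near the random-draw baseline
        from banditsel.stability import SelectionCollection, i_overlap

        n, p, k = 30, 200, 10
        values = rng.normal(size=(n, p))
        base_labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
        sels = []
        for _ in range(20):
            table = LabeledTable(values, rng.permutation(base_labels),
                                 [f"f{j}" for j in range(p)],
                                 [f"s{i}" for i in range(n)])
            sels.append(ttest_rank(table, k).top_feature_ids(table))
        obs = i_overlap(SelectionCollection(sels, [f"f{j}" for j in range(p)]))
        # random k-of-p sets overlap ~ k/(2p-k) on average
        assert obs < 3 * k / (2 * p - k)


class TestAccuracyCurve:
    def test_length_and_guard(self, separable_table, rng):
        ens = rank_subsets(separable_table, [FeatureSubset([0])], T=5, seed=0)
        curve = accuracy_curve(separable_table, ens, repetitions=3, rng=rng)
        assert curve.shape == (1,)
        with pytest.raises(ValueError):
            accuracy_curve(separable_table, ens, repetitions=0, rng=rng)

    def test_informative_subset_tops_the_curve(self, separable_table, rng):
        subsets = [FeatureSubset([0]), FeatureSubset([3, 4])]
        ens = rank_subsets(separable_table, subsets, T=1000, seed=2)
        curve = accuracy_curve(separable_table, ens, repetitions=20, rng=rng)
        assert curve[0] > curve[1]
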