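"""Generators: distributional correctness, geometry, determinism."""

import numpy as np
import pytest

from banditsel.ranking import FeatureSubset, ttest_rank
from banditsel.stability import CategoryMap
from banditsel.synthdata import (
    FunctionalSimConfig,
    GaussianTwoClassConfig,
    fit_logistic_error,
    gen_functional_data,
    gen_functional_subsets,
    gen_small_n_large_p,
)


class TestSmallNLargeP:
    def test_default_dimensions(self):
        table = gen_small_n_large_p(GaussianTwoClassConfig(), seed=0)
        assert (table.n, table.p) == (10, 100)
        assert GaussianTwoClassConfig().n_over_p == pytest.approx(0.1)
        assert sorted(np.bincount(table.labels)) == [5, 5]

    def test_null_configuration_gives_indistinguishable_classes(self, rng):
        cfg = GaussianTwoClassConfig(n=2000, p=4, shape_gamma=1.0,
                                     mu_base=np.zeros(4))
        table = gen_small_n_large_p(cfg, rng)
        diff = (table.values[table.labels == 1].mean(axis=0)
                - table.values[table.labels == 0].mean(axis=0))
        assert np.abs(diff).max() < 0.2  # ~3 s.e. at n=1000/class

    def test_empirical_class_means_match_mu_to_shape_power(self):
        mu = np.array([0.2, 0.5, 1.0])
        cfg = GaussianTwoClassConfig(n=10_000, p=3, mu_base=mu, shape_gamma=0.9)
        table = gen_small_n_large_p(cfg, seed=3)
        se = 1.0 / np.sqrt(5000)
        for cls, sign in ((1, 1.0), (0, -1.0)):
            emp = table.values[table.labels == cls].mean(axis=0)
            np.testing.assert_array_less(np.abs(emp - sign * mu**0.9), 3 * se)

    def test_negative_means_rejected_with_fractional_exponent(self):
        cfg = GaussianTwoClassConfig(p=2, mu_base=np.array([-0.5, 0.2]))
        with pytest.raises(ValueError):
            gen_small_n_large_p(cfg, seed=0)

    def test_pure_function_of_config_and_seed(self):
        cfg = GaussianTwoClassConfig()
        a = gen_small_n_large_p(cfg, 5)
        b = gen_small_n_large_p(cfg, 5)
        np.testing.assert_array_equal(a.values, b.values)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_informative_coordinates_have_larger_t_statistics(self):
        cfg = GaussianTwoClassConfig.sparse_signal(k=5, magnitude=1.0, p=30)
        gaps = []
        for seed in range(50):
            table = gen_small_n_large_p(cfg, seed)
            t = np.abs(ttest_rank(table, 1).tstats)
            gaps.append(t[:5].mean() - t[5:].mean())
        assert np.mean(gaps) > 0.5


class TestFunctionalData:
    def test_geometry_and_redundancy(self):
        table, cmap, theta = gen_functional_data(FunctionalSimConfig(), seed=0)
        assert table.p == 9
        assert len(set(cmap.mapping.values())) == 3
        corr = np.corrcoef(table.values.T)
        for c in range(3):
            block = corr[3 * c : 3 * c + 3, 3 * c : 3 * c + 3]
            assert block.min() > 0.95

    def test_zero_noise_gives_identical_columns(self):
        cfg = FunctionalSimConfig(within_category_noise=0.0)
        table, _, _ = gen_functional_data(cfg, seed=1)
        np.testing.assert_array_equal(table.values[:, 0], table.values[:, 1])

    def test_label_frequency_matches_logistic_mean_response(self):
        cfg = FunctionalSimConfig(n_samples=10_000)
        table, _, theta = gen_functional_data(cfg, seed=2)
        reps = table.values[:, ::3]
        expected = (1 / (1 + np.exp(-(reps @ theta)))).mean()
        se = np.sqrt(expected * (1 - expected) / cfg.n_samples)
        assert table.labels.mean() == pytest.approx(expected, abs=3 * se + 0.01)

    def test_optimal_subsets_cover_all_categories(self):
        cfg = FunctionalSimConfig()
        _, cmap, _ = gen_functional_data(cfg, seed=3)
        subsets = gen_functional_subsets(cfg, seed=3)
        table, _, _ = gen_functional_data(cfg, seed=3)
        assert len(subsets) == 15
        assert all(len(s) == 3 for s in subsets)
        for s in subsets[:3]:
            cats = cmap.categories(s.feature_ids(table))
            assert cats == frozenset({"C1", "C2", "C3"})
        for s in subsets[3:]:
            cats = cmap.categories(s.feature_ids(table))
            assert len(cats) in (1, 2)

    def test_optimal_subsets_share_identical_category_set(self):
        cfg = FunctionalSimConfig()
        _, cmap, _ = gen_functional_data(cfg, seed=4)
        table, _, _ = gen_functional_data(cfg, seed=4)
        subsets = gen_functional_subsets(cfg, seed=4)
        sets = [cmap.categories(s.feature_ids(table)) for s in subsets[:3]]
        assert sets[0] == sets[1] == sets[2]

    def test_functional_similarity_dominates_feature_level(self):
        # runs that each pick some optimal subset disagree on features but
        # agree perfectly on categories: the functional-level similarity
        # must exceed the feature-level one in (nearly) every seed
        from banditsel.stability import (
            SelectionCollection,
            functional_collection,
            i_overlap,
        )

        cfg = FunctionalSimConfig()
        wins = 0
        for seed in range(50):
            table, cmap, _ = gen_functional_data(cfg, seed=seed)
            rng = np.random.default_rng(seed)
            sels = []
            for _ in range(10):
                subs = gen_functional_subsets(cfg, rng)
                pick = subs[int(rng.integers(3))]  # one optimal subset per run
                sels.append(frozenset(pick.feature_ids(table)))
            coll = SelectionCollection(sels, table.feature_ids)
            feat = i_overlap(coll)
            func = i_overlap(functional_collection(coll, cmap))
            wins += func >= feat and func == 1.0
        assert wins >= 45


class TestFitLogisticError:
    def test_wellspecified_fit_is_consistent_at_large_n(self):
        cfg = FunctionalSimConfig(n_samples=5000)
        table, cmap, theta = gen_functional_data(cfg, seed=0)
        err = fit_logistic_error(table, FeatureSubset([0, 3, 6]), theta, cmap)
        assert err < 0.35

    def test_missing_category_error_bounded_away_from_zero(self):
        cfg = FunctionalSimConfig(n_samples=5000)
        table, cmap, theta = gen_functional_data(cfg, seed=1)
        err = fit_logistic_error(table, FeatureSubset([0, 1, 2]), theta, cmap)
        assert err > 1.0

    def test_null_coefficients_recovered_as_null(self):
        cfg = FunctionalSimConfig(theta_star=np.zeros(3), n_samples=4000)
        table, cmap, theta = gen_functional_data(cfg, seed=2)
        err = fit_logistic_error(table, FeatureSubset([0, 3, 6]), theta, cmap)
        assert err < 0.15

    def test_empty_subset_rejected(self):
        cfg = FunctionalSimConfig()
        table, cmap, theta = gen_functional_data(cfg, seed=0)
        with pytest.raises(ValueError):
            fit_logistic_error(table, FeatureSubset([]), theta, cmap)
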