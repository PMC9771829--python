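import numpy as np
import pytest
from scipy import stats

from neurobag import _kernels
from neurobag.bagsel import (
    BagConfig,
    classification_scores,
    global_significance,
    permutation_null,
    run_feature_bagging,
    score_significance,
)

Y34 = np.array([1.0] * 17 + [-1.0] * 17)


def _noise_features(seed=0, n=34, f=80):
    return np.random.default_rng(seed).standard_normal((n, f))


class TestKernels:
    def test_numba_and_numpy_paths_agree(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((14, 40))
        y = np.array([1.0] * 7 + [-1.0] * 7)
        bags = _kernels.draw_bags(rng, 200, 40, 6)
        np.testing.assert_allclose(
            _kernels.lssvm_loo_accuracy(x, y, bags, 1.0),
            _kernels.lssvm_loo_accuracy_np(x, y, bags, 1.0),
        )
        np.testing.assert_allclose(
            _kernels.centroid_loo_accuracy(x, y, bags),
            _kernels.centroid_loo_accuracy_np(x, y, bags),
        )

    def test_closed_form_loo_equals_explicit_refits(self):
        """The PRESS-based LOO predictions must match refitting the ridge
        classifier from scratch for every held-out subject."""
        rng = np.random.default_rng(1)
        x = rng.standard_normal((10, 20))
        y = np.array([1.0] * 5 + [-1.0] * 5)
        bags = _kernels.draw_bags(rng, 30, 20, 4)
        lam = 1.0

        def explicit(bag):
            xb = x[:, bag]
            n = len(y)
            correct = 0
            for i in range(n):
                m = np.ones(n, bool)
                m[i] = False
                z = np.hstack([xb[m], np.ones((n - 1, 1))])
                a = z.T @ z
                a[np.arange(len(bag)), np.arange(len(bag))] += lam
                coef = np.linalg.solve(a, z.T @ y[m])
                pred = 1.0 if np.hstack([xb[i], 1.0]) @ coef >= 0 else -1.0
                correct += pred == y[i]
            return correct / n

        oracle = np.array([explicit(b) for b in bags])
        np.testing.assert_allclose(
            _kernels.lssvm_loo_accuracy(x, y, bags, lam), oracle
        )

    def test_kfold_matches_explicit_refits(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal((20, 15))
        y = np.array([1.0] * 10 + [-1.0] * 10)
        bags = _kernels.draw_bags(rng, 10, 15, 4)
        folds = np.tile(np.arange(5), 4)
        fast = _kernels.lssvm_kfold_accuracy_np(x, y, bags, 1.0, folds)

        def explicit(bag):
            xb = x[:, bag]
            correct = 0
            for f in range(5):
                test = folds == f
                z = np.hstack([xb[~test], np.ones(((~test).sum(), 1))])
                a = z.T @ z
                a[np.arange(len(bag)), np.arange(len(bag))] += 1.0
                coef = np.linalg.solve(a, z.T @ y[~test])
                zt = np.hstack([xb[test], np.ones((test.sum(), 1))])
                pred = np.where(zt @ coef >= 0, 1.0, -1.0)
                correct += (pred == y[test]).sum()
            return correct / len(y)

        np.testing.assert_allclose(fast, [explicit(b) for b in bags])

    def test_bags_are_distinct_within_and_uniform_across(self):
        bags = _kernels.draw_bags(np.random.default_rng(3), 30000, 25, 5)
        assert all(len(set(b)) == 5 for b in bags[:500])
        counts = np.bincount(bags.ravel(), minlength=25)
        expected = 30000 * 5 / 25
        assert np.abs(counts - expected).max() < 5 * np.sqrt(expected)


class TestBaggingAndScores:
    def test_scores_sum_to_bag_size(self, planted_features, small_bag_config):
        res = run_feature_bagging(planted_features, config=small_bag_config)
        sc = classification_scores(res)
        assert sc.scores.sum() == pytest.approx(small_bag_config.bag_size)
        assert (sc.scores >= 0).all() and (sc.scores <= 1).all()

    def test_pure_noise_scores_are_uniform_and_accuracy_near_chance(self):
        """Uninformative features: the mean bag accuracy matches the
        permuted-label distribution (both share the classifier's small
        leave-one-out pessimism and the cohort's chance-level separability),
        and scores stay close to bag_size / n_features."""
        x = _noise_features(seed=4)
        cfg = BagConfig(n_draw=3000, bag_size=5, seed=1)
        observed_mean = run_feature_bagging(x, Y34, cfg).accuracies.mean()
        rng = np.random.default_rng(99)
        perm_means = np.array([
            run_feature_bagging(x, rng.permutation(Y34), cfg, seed=k)
            .accuracies.mean()
            for k in range(30)
        ])
        z = abs(observed_mean - perm_means.mean()) / perm_means.std(ddof=1)
        assert z < 4.0
        assert abs(observed_mean - 0.5) < 0.1
        res = run_feature_bagging(x, Y34, BagConfig(n_draw=20000, bag_size=5, seed=1))
        sc = classification_scores(res)
        expected = 5 / 80
        # equal scores hold in expectation; within one finite cohort,
        # chance-level separability spreads them around bag_size/n_features
        # (the distributional match to the permutation null is checked in
        # test_symmetric_dataset_scores_indistinguishable_from_null)
        assert sc.scores.mean() == pytest.approx(expected)
        assert np.median(sc.scores) == pytest.approx(expected, rel=0.25)

    def test_perfect_feature_gives_unit_accuracy_and_top_score(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal((34, 40))
        x[:, 7] = Y34 * 5.0 + 0.01 * rng.standard_normal(34)
        for seed in range(10):
            res = run_feature_bagging(x, Y34, BagConfig(n_draw=2000, bag_size=4),
                                      seed=seed)
            contains = (res.bags == 7).any(axis=1)
            assert (res.accuracies[contains] == 1.0).all()
            sc = classification_scores(res)
            assert sc.scores.argmax() == 7

    def test_bag_size_equal_to_feature_count_degenerates(self):
        x = _noise_features(seed=6, f=10)
        res = run_feature_bagging(x, Y34, BagConfig(n_draw=200, bag_size=10))
        assert np.ptp(res.accuracies) == 0.0
        assert (np.sort(res.bags, axis=1) == np.arange(10)).all()

    def test_percentile_zero_selects_all_bags(self):
        x = _noise_features(seed=7, f=30)
        res = run_feature_bagging(x, Y34, BagConfig(n_draw=500, bag_size=3))
        sc = classification_scores(res, percentile=0.0)
        assert sc.n_selected == 500
        np.testing.assert_allclose(sc.scores, sc.membership_total / 500)

    def test_deterministic_given_seed(self, planted_features):
        cfg = BagConfig(n_draw=1000, seed=13)
        a = run_feature_bagging(planted_features, config=cfg)
        b = run_feature_bagging(planted_features, config=cfg)
        np.testing.assert_array_equal(a.accuracies, b.accuracies)
        np.testing.assert_array_equal(a.bags, b.bags)

    def test_hinge_svm_accuracies_track_least_squares_svm(self, planted_features):
        """Robustness check across classifier families: per-bag
        LOO accuracies of the hinge-loss SVM and the least-squares SVM are
        strongly correlated."""
        cfg_fast = BagConfig(n_draw=100, bag_size=5, seed=2)
        fast = run_feature_bagging(planted_features, config=cfg_fast)
        slow = run_feature_bagging(
            planted_features,
            config=BagConfig(n_draw=100, bag_size=5, seed=2, classifier="hinge-svm"),
        )
        r = stats.pearsonr(fast.accuracies, slow.accuracies).statistic
        assert r > 0.8

    def test_classifier_families_run_and_detect_planted_effect(self, planted_features):
        cols = list(planted_features.scores.columns)
        F0 = 2.0**1.5

        planted = {cols.index(("amplitude", F0 * 4, 0)),
                   cols.index(("phase", F0 * 2, 1))}
        for family in ("nearest-centroid", "lda", "stump"):
            res = run_feature_bagging(
                planted_features, config=BagConfig(n_draw=4000, classifier=family)
            )
            sc = classification_scores(res)
            top = set(np.argsort(sc.scores)[::-1][:8])
            assert planted & top, family

    def test_kfold_cv_scheme(self, planted_features):
        res = run_feature_bagging(
            planted_features, config=BagConfig(n_draw=500, cv="5fold", seed=3)
        )
        assert res.accuracies.shape == (500,)
        assert (res.accuracies >= 0).all() and (res.accuracies <= 1).all()


class TestSignificance:
    def test_extreme_score_gets_minimum_addone_pvalue(self):
        null = np.random.default_rng(8).uniform(0, 0.5, size=(100, 20))
        obs = np.full(20, 0.01)
        obs[3] = 0.99  # larger than every pooled null value
        sel = score_significance(obs, null)
        assert sel.p[3] == pytest.approx(1.0 / (null.size + 1))

    def test_q_one_flags_every_feature(self):
        null = np.random.default_rng(9).uniform(size=(100, 10))
        sel = score_significance(np.full(10, 0.5), null, q=1.0)
        assert sel.significant.all()

    def test_global_significance_edge_cases(self):
        counts = np.zeros(999, dtype=int)
        assert global_significance(0, counts) == 1.0  # count 0 can never win
        assert global_significance(1, counts) == pytest.approx(0.001)
        counts2 = np.array([0] * 998 + [3])
        assert global_significance(3, counts2) == pytest.approx(2 / 1000)

    def test_permutation_null_determinism_and_shape(self):
        x = _noise_features(seed=10, f=25)
        cfg = BagConfig(n_draw=500, bag_size=3, seed=21)
        a = permutation_null(x, Y34, cfg, n_perm=100)
        b = permutation_null(x, Y34, cfg, n_perm=100)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (100, 25)
        np.testing.assert_allclose(a.sum(axis=1), 3.0)

    def test_symmetric_dataset_scores_indistinguishable_from_null(self):
        """For label-exchangeable data, observed and permuted score
        distributions agree (two-sample KS)."""
        x = _noise_features(seed=11, f=60)
        cfg = BagConfig(n_draw=4000, bag_size=5, seed=5)
        obs = classification_scores(run_feature_bagging(x, Y34, cfg)).scores
        null = permutation_null(x, Y34, cfg, n_perm=100)
        ks = stats.ks_2samp(obs, null.ravel())
        assert ks.pvalue > 0.01
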