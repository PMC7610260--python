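import itertools

import numpy as np
import pytest
from scipy import stats

import fingerdx as fx
from fingerdx.evaluation import UndefinedAUCError, _candidate_cuts


def auc_by_pair_counting(scores, labels):
    """Independent oracle: count concordant case-control pairs, ties half."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    total = wins = 0.0
    for c in cases:
        for k in ctrls:
            total += 1
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / total


class TestAUC:
    def test_worked_example(self):
        assert fx.auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == 0.75

    def test_perfect_separation_and_all_ties(self):
        assert fx.auc([1, 2, 3, 4], [0, 0, 1, 1]) == 1.0
        assert fx.auc([5.0] * 6, [0, 0, 0, 1, 1, 1]) == 0.5

    def test_single_class_raises(self):
        with pytest.raises(UndefinedAUCError):
            fx.auc([0.1, 0.2], [1, 1])

    def test_matches_pair_counting_on_exhaustive_small_instances(self, rng):
        """Mann-Whitney formulation == brute-force concordance, all labelings."""
        for n in (2, 4, 6, 8, 10):
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            for labels in itertools.product([0, 1], repeat=n):
                labels = np.array(labels)
                if labels.min() == labels.max():
                    continue
                assert fx.auc(scores, labels) == pytest.approx(
                    auc_by_pair_counting(scores, labels), abs=1e-12)

    def test_matches_sklearn_on_random_data(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            s = rng.normal(size=30)
            assert fx.auc(s, y) == pytest.approx(roc_auc_score(y, s))


class TestDeLong:
    def test_interval_contains_point_estimate(self, rng):
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        s = rng.normal(size=60) + y
        a, lo, hi = fx.delong_ci(s, y)
        assert lo <= a <= hi

    def test_interval_width_shrinks_with_n(self, rng):
        widths = []
        for n in (50, 500):
            y = np.r_[np.zeros(n, int), np.ones(n, int)]
            s = rng.normal(size=2 * n) + 1.5 * y
            _, lo, hi = fx.delong_ci(s, y)
            widths.append(hi - lo)
        assert widths[1] < widths[0]

    def test_degenerate_auc_gives_point_interval(self):
        y = np.array([0, 0, 1, 1])
        a, lo, hi = fx.delong_ci(np.array([0.0, 0.1, 0.9, 1.0]), y)
        assert a == lo == hi == 1.0

    def test_variance_matches_pROC_reference(self):
        """Frozen oracle: variance/CI from R pROC (DeLong method) on a fixed set.

        Reference computed once with pROC 1.19 for controls (1,2,3,4,5) and
        cases (2.5,4.5,5.5,6): AUC 0.80, variance 0.02875, 95% CI lower
        bound 0.4676719375 (identity scale, clipped at 1 above).
        """
        scores = np.array([1, 2, 3, 4, 5, 2.5, 4.5, 5.5, 6.0])
        labels = np.array([0, 0, 0, 0, 0, 1, 1, 1, 1])
        assert fx.auc(scores, labels) == pytest.approx(0.80)
        assert fx.delong_variance(scores, labels) == pytest.approx(0.02875, rel=1e-9)
        a, lo, hi = fx.delong_ci(scores, labels)
        assert lo == pytest.approx(0.4676719375, abs=1e-8)
        assert hi == 1.0

    def test_identical_scores_give_p_one(self, rng):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        s = rng.normal(size=20)
        assert fx.delong_test(s, s.copy(), y) == 1.0

    def test_signal_vs_noise_is_significant(self, rng):
        y = np.r_[np.zeros(100, int), np.ones(100, int)]
        s_good = y + rng.normal(0, 0.1, 200)
        s_noise = rng.normal(size=200)
        assert fx.delong_test(s_good, s_noise, y) < 0.01

    def test_agrees_with_bootstrap_on_paired_data(self, rng):
        """Paired DeLong p within 0.05 of a stratified bootstrap p (20 sets)."""
        for trial in range(20):
            y = np.r_[np.zeros(40, int), np.ones(40, int)]
            base = rng.normal(size=80)
            sa = base + 0.8 * y + rng.normal(0, 0.5, 80)
            sb = base + 0.5 * y + rng.normal(0, 0.5, 80)
            p_delong = fx.delong_test(sa, sb, y)
            obs = fx.auc(sa, y) - fx.auc(sb, y)
            # stratified bootstrap of the AUC difference; two-sided normal-quantile p
            diffs = []
            idx0, idx1 = np.flatnonzero(y == 0), np.flatnonzero(y == 1)
            for _ in range(2000):
                b = np.r_[rng.choice(idx0, idx0.size), rng.choice(idx1, idx1.size)]
                yb = y[b]
                diffs.append(fx.auc(sa[b], yb) - fx.auc(sb[b], yb))
            se = np.std(diffs, ddof=1)
            p_boot = 2 * stats.norm.sf(abs(obs) / se) if se > 0 else 1.0
            assert abs(p_delong - p_boot) < 0.05


class TestYouden:
    def brute_force(self, scores, labels):
        best = None
        for cut in _candidate_cuts(np.asarray(scores, float)):
            sens, spec = fx.confusion_at(scores, labels, cut)
            key = (sens + spec - 1, spec, cut)
            if best is None or key > best:
                best, best_cut = key, cut
        return best_cut

    def test_worked_example_tie_break_prefers_specificity(self):
        scores = np.array([0.1, 0.4, 0.35, 0.8])
        labels = np.array([0, 0, 1, 1])
        thr = fx.youden_threshold(scores, labels)
        assert 0.4 < thr < 0.8
        sens, spec = fx.confusion_at(scores, labels, thr)
        assert (sens, spec) == (0.5, 1.0)

    def test_perfect_separation_attains_j_one(self):
        scores = np.array([0.1, 0.2, 0.8, 0.9])
        labels = np.array([0, 0, 1, 1])
        thr = fx.youden_threshold(scores, labels)
        sens, spec = fx.confusion_at(scores, labels, thr)
        assert sens + spec - 1 == 1.0

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                y[0], y[-1] = 0, 1
            s = np.round(rng.normal(size=n), 1)
            assert fx.youden_threshold(s, y) == self.brute_force(s, y)


class TestConfusion:
    def test_infinite_thresholds(self):
        y = np.array([0, 0, 1, 1])
        s = np.array([0.1, 0.4, 0.35, 0.8])
        assert fx.confusion_at(s, y, -np.inf) == (1.0, 0.0)
        assert fx.confusion_at(s, y, np.inf) == (0.0, 1.0)

    def test_worked_instance_at_half(self):
        sens, spec = fx.confusion_at([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1], 0.5)
        assert (sens, spec) == (0.5, 1.0)


class TestStratifiedKFold:
    def test_study_discovery_fold_shapes(self):
        y = np.r_[np.zeros(137, int), np.ones(138, int)]
        folds = fx.stratified_kfold(y, k=10, seed=0)
        sizes = sorted(f.size for f in folds)
        assert set(sizes) <= {27, 28}
        for f in folds:
            counts = np.bincount(y[f], minlength=2)
            assert set(counts.tolist()) <= {13, 14}

    def test_partition_and_determinism(self):
        y = np.r_[np.zeros(25, int), np.ones(30, int)]
        folds = fx.stratified_kfold(y, k=5, seed=3)
        flat = np.sort(np.concatenate(folds))
        np.testing.assert_array_equal(flat, np.arange(55))
        folds2 = fx.stratified_kfold(y, k=5, seed=3)
        for a, b in zip(folds, folds2):
            np.testing.assert_array_equal(a, b)

    def test_class_smaller_than_k_raises(self):
        y = np.r_[np.zeros(3, int), np.ones(30, int)]
        with pytest.raises(ValueError):
            fx.stratified_kfold(y, k=5)


def centroid_scorer(X_train, y_train, X_test, clin_train=None, clin_test=None):
    """Cheap deterministic classifier: project on the class-mean difference."""
    w = X_train[y_train == 1].mean(axis=0) - X_train[y_train == 0].mean(axis=0)
    return X_test @ w


class TestPermutationTest:
    def test_minimum_attainable_p(self, rng):
        """Observed above every permutation at B=999 gives exactly 0.001."""
        y = np.r_[np.zeros(30, int), np.ones(30, int)]
        X = rng.normal(size=(60, 10)) + 3.0 * y[:, None]
        p, obs, perm = fx.permutation_test(centroid_scorer, X, y, B=999, seed=0, k=5)
        assert obs > perm.max()
        assert p == pytest.approx(0.001)

    def test_single_permutation_ceiling(self, rng):
        y = np.r_[np.zeros(10, int), np.ones(10, int)]
        X = rng.normal(size=(20, 3))  # pure noise: permuted can beat observed
        for seed in range(20):
            p, obs, perm = fx.permutation_test(centroid_scorer, X, y, B=1,
                                               seed=seed, k=2)
            if perm[0] >= obs:
                assert p == 1.0
                break
        else:
            pytest.fail("no permutation beat the observed statistic in 20 tries")

    def test_null_p_values_approximately_uniform(self, rng):
        ps = []
        for s in range(100):
            r = np.random.default_rng(s)
            y = np.r_[np.zeros(20, int), np.ones(20, int)]
            X = r.normal(size=(40, 5))
            p, _, _ = fx.permutation_test(centroid_scorer, X, y, B=99, seed=s, k=5)
            ps.append(p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPowerAnalysis:
    def test_reported_minimum_cohort_size(self):
        # alpha = 0.15 and power = 0.9; standardized effect 0.70 gives 62 total
        assert fx.min_sample_size(0.70, 0.15, 0.9) == 62

    def test_doubling_effect_quarters_n(self):
        n1 = fx.min_sample_size(0.5, 0.05, 0.8)
        n2 = fx.min_sample_size(1.0, 0.05, 0.8)
        assert n1 / 4 <= n2 <= n1 / 4 + 4  # up to rounding

    def test_monotone_in_power(self):
        assert fx.min_sample_size(0.5, 0.05, 0.95) > fx.min_sample_size(0.5, 0.05, 0.8)

    def test_invalid_parameters_raise(self):
        for args in [(0, 0.05, 0.8), (0.5, 0, 0.8), (0.5, 0.05, 1.0)]:
            with pytest.raises(ValueError):
                fx.min_sample_size(*args)
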