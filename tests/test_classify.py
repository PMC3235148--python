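"""Discrimination scores, splits, ROC areas, controls and statistics."""

import numpy as np
import pytest

from hmmdecode.classify import (
    HmmPairClassifier,
    RtGaussianClassifier,
    compare_area_distributions,
    cross_validate_pair,
    evaluate_control,
    fixed_prior_accuracy,
    roc_area,
    rt_baseline,
    score_rt_correlation,
    select_q_pair,
    split_90_10,
)
from hmmdecode.hmm import GaussianHMM


def _pair(m1, m2, props=(0.5, 0.5)):
    clf = HmmPairClassifier.__new__(HmmPairClassifier)
    clf.classes_ = np.array(["day1", "day2"])
    clf.models_ = [m1, m2]
    clf.train_proportions_ = np.asarray(props, dtype=float)
    return clf


@pytest.fixture
def separated_models():
    m1 = GaussianHMM.from_params([1.0], [[1.0]], [[-2.0]], [np.eye(1)])
    m2 = GaussianHMM.from_params([1.0], [[1.0]], [[2.0]], [np.eye(1)])
    return m1, m2


class TestDiscriminationScore:
    def test_identical_models_score_zero(self, separated_models, rng):
        m1, _ = separated_models
        clf = _pair(m1, m1)
        X = [rng.normal(size=(6, 1)) for _ in range(4)]
        np.testing.assert_allclose(clf.decision_function(X), 0.0, atol=1e-10)

    def test_swapping_models_negates(self, separated_models, rng):
        m1, m2 = separated_models
        X = [rng.normal(size=(5, 1)) for _ in range(6)]
        s = _pair(m1, m2).decision_function(X)
        np.testing.assert_allclose(_pair(m2, m1).decision_function(X), -s, atol=1e-9)

    def test_own_class_scores_positive_mostly(self, separated_models, rng):
        m1, m2 = separated_models
        clf = _pair(m1, m2)
        X2 = [m2.sample(10, rng)[0] for _ in range(100)]
        assert np.mean(clf.decision_function(X2) > 0) > 0.5


class TestSplits:
    def test_stratified_counts(self):
        y = np.array(["day1"] * 100 + ["day2"] * 100)
        for train, test in split_90_10(y, n_splits=5, seed=0):
            assert len(test) == 20
            assert np.sum(y[test] == "day1") == 10
            assert np.sum(y[test] == "day2") == 10

    def test_disjoint_and_complete(self):
        y = np.array(["day1"] * 30 + ["day2"] * 30)
        for train, test in split_90_10(y, n_splits=4, seed=1):
            assert set(train) | set(test) == set(range(60))
            assert not set(train) & set(test)

    def test_seed_determinism(self):
        y = np.array(["day1"] * 50 + ["day2"] * 50)
        a = split_90_10(y, n_splits=3, seed=7)
        b = split_90_10(y, n_splits=3, seed=7)
        c = split_90_10(y, n_splits=3, seed=8)
        for (ta, sa), (tb, sb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(sa, sb)
        assert any(
            not np.array_equal(sa, sc) for (_, sa), (_, sc) in zip(a, c)
        )

    def test_small_class_rejected(self):
        y = np.array(["day1"] * 30 + ["day2"] * 5)
        with pytest.raises(ValueError, match="fewer than 10"):
            split_90_10(y)


class TestRocArea:
    def test_perfect_separation(self):
        res = roc_area([1, 2, 3, 10, 11, 12], ["a"] * 3 + ["b"] * 3)
        assert res.area == 1.0
        assert res.fpr[0] == 0.0 and res.tpr[-1] == 1.0

    def test_hand_enumerated_u_statistic(self):
        assert roc_area([1, 2, 3, 4], [1, 1, 2, 2]).area == 1.0
        # positives (label 2) score {1, 3}, negatives {2, 4}: of the four
        # pairs only 3>2 wins, so U/(n1*n2) = 1/4
        assert roc_area([1, 2, 3, 4], [2, 1, 2, 1]).area == 0.25
        # with the labels flipped the area complements
        assert roc_area([1, 2, 3, 4], [1, 2, 1, 2]).area == 0.75

    def test_ties_count_half(self):
        assert roc_area([1.0, 1.0], ["a", "b"]).area == 0.5

    def test_permuted_labels_near_half(self, rng):
        scores = rng.normal(size=2000)
        labels = rng.permutation(["a", "b"] * 1000)
        # null SE of AUC ~ sqrt((n1+n2+1)/(12 n1 n2)) ~ 0.013
        assert abs(roc_area(scores, labels).area - 0.5) < 3 * 0.013

    def test_one_class_rejected(self):
        with pytest.raises(ValueError, match="two classes"):
            roc_area([1, 2], ["a", "a"])


class TestFixedPriorAccuracy:
    def test_equal_priors_threshold_at_zero(self, separated_models, rng):
        m1, m2 = separated_models
        clf = _pair(m1, m2)
        X = [m1.sample(20, rng)[0] for _ in range(10)] + [
            m2.sample(20, rng)[0] for _ in range(10)
        ]
        y = np.array(["day1"] * 10 + ["day2"] * 10)
        scores = clf.decision_function(X)
        by_sign = np.where(scores > 0, "day2", "day1")
        assert fixed_prior_accuracy(clf, X, y) == np.mean(by_sign == y)

    def test_skewed_priors_shift_threshold(self, separated_models):
        # proportions (0.9, 0.1): a trial is called day2 only when the
        # score exceeds log(0.9/0.1)
        m1, m2 = separated_models
        clf = _pair(m1, m2, props=(0.9, 0.1))
        shift = np.log(0.9 / 0.1)
        # choose single-frame trials whose scores straddle the shifted
        # threshold: score of a 1-frame trial at x is 4x here
        xs = [shift / 4 - 0.05, shift / 4 + 0.05]
        X = [np.array([[v]]) for v in xs]
        pred = clf.predict(X)
        assert list(pred) == ["day1", "day2"]

    def test_empty_rejected(self, separated_models):
        clf = _pair(*separated_models)
        with pytest.raises(ValueError, match="empty"):
            fixed_prior_accuracy(clf, [], np.array([]))


class TestEndToEndCv:
    def test_cv_and_q_selection_argmax(self, rng):
        # 1-D, Q=1 data; class means differ -> easy discrimination at any Q
        X, y = [], []
        for day, mu in (("day1", -1.5), ("day2", 1.5)):
            for _ in range(15):
                X.append(rng.normal(mu, 1.0, size=(int(rng.integers(8, 15)), 1)))
                y.append(day)
        y = np.array(y)
        reports, best = select_q_pair(
            X, y, q_grid=[1, 2], n_splits=3, seed=0, max_iter=10, gmm_max_iter=20
        )
        assert len(reports) == 4
        areas = {k: r.mean_area for k, r in reports.items() if r.areas}
        assert areas[best] == max(areas.values())
        rep = reports[best]
        assert rep.n_splits == 3
        assert rep.mean_area > 0.8

    def test_single_cell_grid(self, rng):
        X = [rng.normal(d, 1, size=(10, 1)) for d in [-1] * 12 + [1] * 12]
        y = np.array(["day1"] * 12 + ["day2"] * 12)
        reports, best = select_q_pair(
            X, y, q_grid=[1], n_splits=2, seed=0, max_iter=5, gmm_max_iter=10
        )
        assert best == (1, 1) and set(reports) == {(1, 1)}


class TestRtBaseline:
    def test_identical_distributions_near_half(self, rng):
        rts = np.concatenate([rng.normal(500, 50, 60), rng.normal(500, 50, 60)])
        y = np.array(["day1"] * 60 + ["day2"] * 60)
        rep = rt_baseline(rts, y, n_splits=10, seed=0)
        assert abs(rep.mean_area - 0.5) < 0.2

    def test_disjoint_supports_area_one(self):
        rts = np.concatenate([np.linspace(300, 400, 20), np.linspace(600, 700, 20)])
        y = np.array(["day1"] * 20 + ["day2"] * 20)
        rep = rt_baseline(rts, y, n_splits=5, seed=0)
        assert rep.mean_area == 1.0

    def test_shift_invariance(self, rng):
        rts = np.concatenate([rng.normal(500, 40, 30), rng.normal(550, 40, 30)])
        y = np.array(["day1"] * 30 + ["day2"] * 30)
        a = rt_baseline(rts, y, n_splits=5, seed=3).areas
        b = rt_baseline(rts + 100.0, y, n_splits=5, seed=3).areas
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_rts_floored_with_warning(self):
        rts = np.array([500.0] * 15 + [510.0] * 15)
        y = np.array(["day1"] * 15 + ["day2"] * 15)
        with pytest.warns(UserWarning, match="floored"):
            RtGaussianClassifier().fit(rts, y)


class TestEvaluateControl:
    def test_same_generative_model_near_half(self, rng):
        m1 = GaussianHMM.from_params([1.0], [[1.0]], [[-1.0]], [np.eye(1)])
        m2 = GaussianHMM.from_params([1.0], [[1.0]], [[1.0]], [np.eye(1)])
        pairs = [_pair(m1, m2) for _ in range(10)]
        null_model = GaussianHMM.from_params([1.0], [[1.0]], [[0.0]], [np.eye(1)])
        X = [null_model.sample(10, rng)[0] for _ in range(120)]
        y = np.array(["day1", "day2"] * 60)
        rep = evaluate_control(pairs, X, y, seed=0)
        assert abs(rep.mean_area - 0.5) < 0.2

    def test_no_retraining_models_untouched(self, separated_models, rng):
        m1, m2 = separated_models
        clf = _pair(m1, m2)
        before = (m1.fingerprint, m2.fingerprint)
        X = [rng.normal(size=(8, 1)) for _ in range(30)]
        y = np.array(["day1", "day2"] * 15)
        evaluate_control([clf], X, y, seed=0)
        assert (m1.fingerprint, m2.fingerprint) == before

    def test_empty_control_rejected(self, separated_models):
        clf = _pair(*separated_models)
        with pytest.raises(ValueError, match="empty"):
            evaluate_control([clf], [], np.array([]))


class TestStatistics:
    def test_correlation_identity_and_affine_invariance(self, rng):
        x = rng.normal(size=50)
        r, p = score_rt_correlation(x, x)
        assert r == pytest.approx(1.0)
        y = rng.normal(size=50)
        r1, _ = score_rt_correlation(x, y)
        r2, _ = score_rt_correlation(3.0 * x + 10.0, 0.5 * y - 2.0)
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_independent_scores_not_significant(self, rng):
        x, y = rng.normal(size=500), rng.normal(size=500)
        r, p = score_rt_correlation(x, y)
        assert abs(r) < 0.15

    def test_zero_variance_undefined(self, rng):
        with pytest.warns(UserWarning, match="zero variance"):
            r, p = score_rt_correlation(np.ones(10), rng.normal(size=10))
        assert np.isnan(r)

    def test_area_comparison_welch(self):
        a = [0.9 + e for e in (0.001, -0.002, 0.0015, -0.001, 0.0005) * 2]
        b = [0.5 + e for e in (0.001, -0.002, 0.0015, -0.001, 0.0005) * 2]
        t, p = compare_area_distributions(a, b)
        assert p < 1e-10
        t2, p2 = compare_area_distributions(b, a)
        assert p2 == pytest.approx(p)
        assert t2 == pytest.approx(-t)

    def test_identical_constant_lists_p_one(self):
        with pytest.warns(UserWarning, match="identical"):
            _, p = compare_area_distributions([0.8] * 5, [0.8] * 5)
        assert p == 1.0


class TestCrossValidatePair:
    def test_keep_models_and_split_bookkeeping(self, rng):
        X = [rng.normal(d, 1, size=(12, 1)) for d in [-2] * 15 + [2] * 15]
        y = np.array(["day1"] * 15 + ["day2"] * 15)
        rep = cross_validate_pair(
            X, y, 1, 1, n_splits=3, seed=0, keep_models=True,
            max_iter=5, gmm_max_iter=10,
        )
        assert len(rep.models) == 3 and len(rep.splits) == 3
        assert rep.mean_area > 0.9
        assert rep.sd_area >= 0.0
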