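"""Forward likelihood, Baum-Welch and Viterbi against independent oracles."""

import numpy as np
import pytest
from scipy.special import logsumexp

from conftest import brute_force_loglik, brute_force_viterbi, random_hmm_params
from hmmdecode._emissions import component_logpdfs
from hmmdecode.gmm import FrameGMM
from hmmdecode.hmm import GaussianHMM, init_from_gmm, load_model, save_model


class TestInitFromGmm:
    def test_stated_mapping(self, rng):
        g = FrameGMM(n_components=3, random_state=0).fit(rng.normal(size=(200, 2)))
        m = init_from_gmm(g)
        np.testing.assert_array_equal(m.startprob_, g.weights_ / g.weights_.sum())
        np.testing.assert_allclose(m.transmat_, np.full((3, 3), 1 / 3))
        np.testing.assert_array_equal(m.means_, g.means_)
        np.testing.assert_array_equal(m.covars_, g.covariances_)

    def test_q1_degenerate(self, rng):
        g = FrameGMM(n_components=1, random_state=0).fit(rng.normal(size=(50, 1)))
        m = init_from_gmm(g)
        assert m.startprob_.tolist() == [1.0]
        assert m.transmat_.tolist() == [[1.0]]


class TestForward:
    def test_single_state_closed_form(self, rng):
        mean, cov = np.array([[0.5, -1.0]]), np.array([np.diag([1.0, 2.0])])
        m = GaussianHMM.from_params([1.0], [[1.0]], mean, cov)
        X = rng.normal(size=(2, 2))
        expected = component_logpdfs(X, mean, cov).sum()
        assert m.score(X) == pytest.approx(float(expected), rel=1e-12)

    def test_matches_brute_force_enumeration(self, rng):
        for _ in range(20):
            pi, A, means, covs = random_hmm_params(rng)
            m = GaussianHMM.from_params(pi, A, means, covs)
            L = int(rng.integers(1, 7))
            X = rng.normal(size=(L, means.shape[1]))
            brute = brute_force_loglik(pi, A, means, covs, X)
            assert m.score(X) == pytest.approx(brute, rel=1e-8)

    def test_translation_invariance(self, rng):
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        X = rng.normal(size=(8, means.shape[1]))
        m = GaussianHMM.from_params(pi, A, means, covs)
        m2 = GaussianHMM.from_params(pi, A, means + 7.5, covs)
        assert m.score(X) == pytest.approx(m2.score(X + 7.5), rel=1e-10)

    def test_one_frame_equals_prior_weighted_mixture(self, rng):
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        m = GaussianHMM.from_params(pi, A, means, covs)
        x = rng.normal(size=(1, means.shape[1]))
        mix = logsumexp(component_logpdfs(x, means, covs)[0] + np.log(pi))
        assert m.score(x) == pytest.approx(float(mix), rel=1e-10)

    def test_state_permutation_invariance(self, rng):
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        q = pi.size
        perm = rng.permutation(q)
        m = GaussianHMM.from_params(pi, A, means, covs)
        mp = GaussianHMM.from_params(
            pi[perm], A[np.ix_(perm, perm)], means[perm], covs[perm]
        )
        X = rng.normal(size=(6, means.shape[1]))
        assert m.score(X) == pytest.approx(mp.score(X), rel=1e-10)

    def test_long_trial_stays_finite(self, rng):
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        m = GaussianHMM.from_params(pi, A, means, covs)
        X = rng.normal(size=(3000, means.shape[1]))
        assert np.isfinite(m.score(X))

    def test_dimension_mismatch_reported(self, rng):
        m = GaussianHMM.from_params([1.0], [[1.0]], [[0.0, 0.0]], [np.eye(2)])
        with pytest.raises(ValueError, match="contacts"):
            m.score(rng.normal(size=(4, 3)))

    def test_matches_hmmlearn(self, rng):
        hmmlearn = pytest.importorskip("hmmlearn.hmm")
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        ours = GaussianHMM.from_params(pi, A, means, covs)
        ref = hmmlearn.GaussianHMM(n_components=pi.size, covariance_type="full")
        ref.startprob_, ref.transmat_ = pi, A
        ref.means_, ref.covars_ = means, covs
        X = rng.normal(size=(25, means.shape[1]))
        assert ours.score(X) == pytest.approx(ref.score(X), rel=1e-9)
        np.testing.assert_array_equal(ours.decode(X), ref.predict(X))


class TestPosteriors:
    def test_marginals_sum_to_one_each_frame(self, rng):
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        m = GaussianHMM.from_params(pi, A, means, covs)
        gamma = m.posteriors(rng.normal(size=(15, means.shape[1])))
        np.testing.assert_allclose(gamma.sum(axis=1), 1.0, atol=1e-10)


class TestViterbi:
    def test_matches_exhaustive_argmax(self, rng):
        for _ in range(15):
            pi, A, means, covs = random_hmm_params(rng)
            m = GaussianHMM.from_params(pi, A, means, covs)
            L = int(rng.integers(1, 7))
            X = rng.normal(size=(L, means.shape[1]))
            np.testing.assert_array_equal(
                m.decode(X), brute_force_viterbi(pi, A, means, covs, X)
            )

    def test_q1_constant_path(self, rng):
        m = GaussianHMM.from_params([1.0], [[1.0]], [[0.0]], [np.eye(1)])
        np.testing.assert_array_equal(m.decode(rng.normal(size=(9, 1))), np.zeros(9))

    def test_tie_break_deterministic_lowest_state(self):
        # two states with identical emissions and symmetric dynamics: every
        # path probability ties, so the all-zeros path must win
        m = GaussianHMM.from_params(
            [0.5, 0.5], [[0.5, 0.5], [0.5, 0.5]],
            [[0.0], [0.0]], [np.eye(1), np.eye(1)],
        )
        X = np.zeros((5, 1))
        np.testing.assert_array_equal(m.decode(X), np.zeros(5, dtype=int))
        np.testing.assert_array_equal(m.decode(X), m.decode(X))


class TestBaumWelch:
    def test_q1_one_step_pooled_moments(self, rng):
        seqs = [rng.normal(3.0, 2.0, size=(L, 2)) for L in (5, 9, 14)]
        m = GaussianHMM(n_states=1, random_state=0, reg_covar=1e-10).fit(seqs)
        pool = np.concatenate(seqs)
        np.testing.assert_allclose(m.means_[0], pool.mean(axis=0), atol=1e-8)
        np.testing.assert_allclose(
            m.covars_[0], np.cov(pool.T, bias=True), rtol=1e-6
        )

    def test_trace_non_decreasing(self, rng):
        for _ in range(3):
            seqs = [rng.normal(size=(int(rng.integers(5, 20)), 2)) for _ in range(8)]
            m = GaussianHMM(n_states=2, random_state=0).fit(seqs)
            d = np.diff(m.loglik_trace_)
            assert np.all(d >= -1e-8 * np.abs(m.loglik_trace_[:-1]))

    def test_recovers_self_transitions(self, rng):
        true = GaussianHMM.from_params(
            [0.5, 0.5], [[0.9, 0.1], [0.1, 0.9]],
            [[-3.0], [3.0]], [np.eye(1), np.eye(1)],
        )
        seqs = [true.sample(50, rng)[0] for _ in range(200)]
        m = GaussianHMM(n_states=2, random_state=0).fit(seqs)
        order = np.argsort(m.means_.ravel())
        diag = np.diag(m.transmat_)[order]
        np.testing.assert_allclose(diag, [0.9, 0.9], atol=0.05)
        np.testing.assert_allclose(np.sort(m.means_.ravel()), [-3, 3], atol=0.15)

    def test_variable_lengths_pooled(self, rng):
        seqs = [rng.normal(size=(L, 1)) for L in (3, 30, 7)]
        m = GaussianHMM(n_states=2, random_state=1).fit(seqs)
        assert np.allclose(m.transmat_.sum(axis=1), 1.0, atol=1e-9)
        assert np.isclose(m.startprob_.sum(), 1.0, atol=1e-9)


class TestSerialization:
    def test_round_trip_and_convention(self, rng, tmp_path):
        pi, A, means, covs = random_hmm_params(rng, q_max=3, n_max=2)
        m = GaussianHMM.from_params(pi, A, means, covs)
        save_model(m, tmp_path / "m.json")
        back = load_model(tmp_path / "m.json")
        np.testing.assert_allclose(back.transmat_, m.transmat_)
        np.testing.assert_allclose(back.startprob_, m.startprob_)
        # the stored matrix is column-stochastic
        d = m.to_dict()
        colA = np.asarray(d["transition_matrix_colstochastic"])
        np.testing.assert_allclose(colA.sum(axis=0), 1.0, atol=1e-9)

    def test_load_validates_stochasticity(self, tmp_path):
        import json

        bad = {"Q": 2, "priors": [0.7, 0.7],
               "transition_matrix_colstochastic": [[0.5, 0.5], [0.5, 0.5]],
               "means": [[0.0], [1.0]], "covariances": [[[1.0]], [[1.0]]]}
        p = tmp_path / "bad.json"
        p.write_text(json.dumps(bad))
        with pytest.raises(ValueError, match="sum to 1"):
            load_model(p)
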