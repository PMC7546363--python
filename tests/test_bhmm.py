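import itertools

import numpy as np
import pytest
from scipy.special import multigammaln

from gazehmm import (InfeasibleModelError, decode, default_priors, elbo,
                     select_state_count, vbem_fit)
from gazehmm.bhmm import _log_gauss
from gazehmm.types import BhmmModel

from conftest import random_hmm


def enumerate_marginals(model, X):
    """Brute-force smoothed marginals by summing over all state paths."""
    T = len(X)
    K = model.n_states
    logB = _log_gauss(X, model.means, model.covariances)
    post = np.zeros((T, K))
    total = 0.0
    for path in itertools.product(range(K), repeat=T):
        lp = np.log(model.prior[path[0]]) + logB[0, path[0]]
        for t in range(1, T):
            lp += np.log(model.transition[path[t - 1], path[t]]) \
                + logB[t, path[t]]
        p = np.exp(lp)
        total += p
        for t in range(T):
            post[t, path[t]] += p
    return post / total


def simulate_from(model, T, rng):
    z = rng.choice(model.n_states, p=model.prior)
    X, Z = [], []
    for _ in range(T):
        X.append(rng.multivariate_normal(model.means[z],
                                         model.covariances[z]))
        Z.append(z)
        z = rng.choice(model.n_states, p=model.transition[z])
    return np.array(X), np.array(Z)


class TestDecode:
    def test_marginals_match_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        worst = 0.0
        for _ in range(30):
            K = int(rng.integers(2, 4))
            T = int(rng.integers(2, 9))
            model = random_hmm(rng, K)
            X = rng.normal(0, 2.5, (T, 2))
            g = decode(model, X).responsibilities
            ref = enumerate_marginals(model, X)
            worst = max(worst, np.abs(g - ref).max())
        assert worst < 1e-10

    def test_map_at_isolated_state_mean(self):
        means = np.array([[0.0, 0.0], [100.0, 100.0], [-100.0, 100.0]])
        covs = np.array([np.eye(2)] * 3)
        model = BhmmModel(np.full(3, 1 / 3), np.full((3, 3), 1 / 3), means,
                          covs)
        a = decode(model, means[1][None, :])
        assert a.map_states[0] == 1
        assert a.responsibilities[0, 1] > 0.99

    def test_identical_states_give_uniform_responsibilities(self):
        K = 4
        model = BhmmModel(np.full(K, 1 / K), np.full((K, K), 1 / K),
                          np.zeros((K, 2)), np.array([np.eye(2)] * K))
        a = decode(model, np.random.default_rng(0).normal(0, 1, (6, 2)))
        np.testing.assert_allclose(a.responsibilities, 1 / K, atol=1e-12)

    def test_map_ties_break_to_lowest_index(self):
        model = BhmmModel([0.5, 0.5], np.full((2, 2), 0.5),
                          np.zeros((2, 2)), np.array([np.eye(2)] * 2))
        a = decode(model, np.zeros((3, 2)))
        assert (a.map_states == 0).all()

    def test_far_outlier_observation_stays_finite(self):
        model = BhmmModel([1.0], [[1.0]], [[0.0, 0.0]], [np.eye(2)])
        a = decode(model, np.array([[1e4, -1e4]]))
        assert np.isfinite(a.responsibilities).all()
        np.testing.assert_allclose(a.responsibilities.sum(axis=1), 1.0)

    def test_cross_check_against_hmmlearn_posteriors(self):
        hmm = pytest.importorskip("hmmlearn.hmm")
        rng = np.random.default_rng(3)
        model = random_hmm(rng, 3, D=2)
        X, _ = simulate_from(model, 40, rng)
        ours = decode(model, X).responsibilities
        ref = hmm.GaussianHMM(n_components=3, covariance_type="full",
                              init_params="")
        ref.startprob_ = model.prior
        ref.transmat_ = model.transition
        ref.means_ = model.means
        ref.covars_ = model.covariances
        theirs = ref.predict_proba(X)
        np.testing.assert_allclose(ours, theirs, atol=1e-8)


class TestVbemFit:
    def test_single_state_closed_form(self):
        X = np.array([[1.0, 2.0], [3.0, 0.0], [2.0, 1.0], [0.0, 1.0]])
        model, post = vbem_fit([X], 1, restarts=1, seed=0)
        np.testing.assert_allclose(model.prior, [1.0])
        np.testing.assert_allclose(model.transition, [[1.0]])
        pri = post.priors
        expected_mean = (pri.kappa0 * pri.m0 + len(X) * X.mean(axis=0)) \
            / (pri.kappa0 + len(X))
        np.testing.assert_allclose(model.means[0], expected_mean, atol=1e-9)

    def test_two_state_parameter_recovery(self):
        rng = np.random.default_rng(11)
        A = np.array([[0.75, 0.25], [0.35, 0.65]])
        means = np.array([[400.0, 300.0, 0.0], [1000.0, 700.0, 0.0]])
        true = BhmmModel([0.5, 0.5], A, means,
                         np.array([np.diag([2500.0, 2500.0, 1.0])] * 2))
        seqs = [simulate_from(true, 200, rng)[0] for _ in range(40)]
        model, _ = vbem_fit(seqs, 2, restarts=2, seed=5)
        perm = [0, 1] if np.linalg.norm(model.means[0, :2] - means[0, :2]) \
            < np.linalg.norm(model.means[0, :2] - means[1, :2]) else [1, 0]
        assert np.abs(model.means[perm][:, :2] - means[:, :2]).max() < 15.0
        assert np.abs(model.transition[np.ix_(perm, perm)] - A).max() < 0.05

    def test_duplicating_sequences_barely_moves_the_point_model(self):
        rng = np.random.default_rng(2)
        true = BhmmModel([0.5, 0.5], [[0.8, 0.2], [0.2, 0.8]],
                         [[0.0, 0.0], [600.0, 600.0]],
                         np.array([np.eye(2) * 2500.0] * 2))
        seqs = [simulate_from(true, 120, rng)[0] for _ in range(6)]
        m1, _ = vbem_fit(seqs, 2, restarts=1, seed=3)
        m2, _ = vbem_fit(seqs * 2, 2, restarts=1, seed=3)
        d = min(np.abs(m1.means - m2.means).max(),
                np.abs(m1.means - m2.means[::-1]).max())
        assert d < 1.0   # shrinkage shift under one pixel

    def test_point_models_satisfy_stochasticity_invariants(self):
        rng = np.random.default_rng(9)
        for s in range(5):
            model = random_hmm(rng, 3)
            seqs = [simulate_from(model, 60, rng)[0] for _ in range(3)]
            fit, _ = vbem_fit(seqs, 3, restarts=1, seed=s)
            fit.validate(tol=1e-10)
            assert abs(fit.prior.sum() - 1.0) < 1e-10
            np.testing.assert_allclose(fit.transition.sum(axis=1), 1.0,
                                       atol=1e-10)

    def test_infeasible_state_count_raises(self):
        with pytest.raises(InfeasibleModelError):
            vbem_fit([np.zeros((3, 2))], 5, restarts=1, seed=0)

    def test_same_seed_reproduces_fit(self):
        rng = np.random.default_rng(4)
        seqs = [rng.normal(0, 1, (50, 2)) for _ in range(3)]
        m1, _ = vbem_fit(seqs, 2, restarts=2, seed=8)
        m2, _ = vbem_fit(seqs, 2, restarts=2, seed=8)
        np.testing.assert_array_equal(m1.transition, m2.transition)
        np.testing.assert_array_equal(m1.means, m2.means)

    def test_decode_equivariant_under_state_permutation(self):
        rng = np.random.default_rng(6)
        model = random_hmm(rng, 3)
        perm = np.array([2, 0, 1])
        permuted = BhmmModel(model.prior[perm],
                             model.transition[np.ix_(perm, perm)],
                             model.means[perm], model.covariances[perm])
        X = rng.normal(0, 2, (25, 2))
        g1 = decode(model, X).responsibilities
        g2 = decode(permuted, X).responsibilities
        np.testing.assert_allclose(g1[:, perm], g2, atol=1e-12)


class TestElbo:
    def test_trace_non_decreasing(self):
        rng = np.random.default_rng(14)
        for s in range(10):
            seqs = [rng.normal(0, 1, (40, 3)) + rng.integers(0, 2) * 2.0
                    for _ in range(3)]
            _, post = vbem_fit(seqs, 2, restarts=1, seed=s)
            trace = np.array(post.elbo_trace)
            assert np.all(np.diff(trace) >= -1e-6 * np.abs(trace[:-1]))

    def test_elbo_bounded_by_exact_evidence_single_state(self):
        X = np.array([[0.1, 0.2, 0.3], [0.4, -0.2, 0.1], [-0.3, 0.5, 0.2]])
        priors = default_priors(X, 1)
        _, post = vbem_fit([X], 1, priors=priors, restarts=1, seed=0)
        N, D = X.shape
        kN = priors.kappa0 + N
        nuN = priors.nu0 + N
        xbar = X.mean(axis=0)
        S = (X - xbar).T @ (X - xbar)
        TN = priors.W0inv + S + priors.kappa0 * N / kN * np.outer(
            xbar - priors.m0, xbar - priors.m0)
        _, ld0 = np.linalg.slogdet(priors.W0inv)
        _, ldN = np.linalg.slogdet(TN)
        log_evidence = (-N * D / 2 * np.log(np.pi)
                        + D / 2 * np.log(priors.kappa0 / kN)
                        + priors.nu0 / 2 * ld0 - nuN / 2 * ldN
                        + multigammaln(nuN / 2, D)
                        - multigammaln(priors.nu0 / 2, D))
        assert post.elbo_trace[-1] <= log_evidence + 1e-9

    def test_public_elbo_matches_trace(self):
        rng = np.random.default_rng(1)
        seqs = [rng.normal(0, 1, (30, 2)) for _ in range(2)]
        _, post = vbem_fit(seqs, 2, restarts=1, seed=0)
        assert elbo(seqs, post) == pytest.approx(post.elbo_trace[-1],
                                                 rel=1e-6)

    def test_complexity_penalty_prefers_true_state_count(self):
        rng = np.random.default_rng(21)
        true = BhmmModel([0.5, 0.5], [[0.7, 0.3], [0.3, 0.7]],
                         [[0.0, 0.0], [12.0, 12.0]],
                         np.array([np.eye(2)] * 2))
        wins = 0
        for s in range(5):
            seqs = [simulate_from(true, 80, np.random.default_rng(100 + s
                                                                  + i))[0]
                    for i in range(4)]
            _, r2 = vbem_fit(seqs, 2, restarts=2, seed=s)
            _, r5 = vbem_fit(seqs, 5, restarts=2, seed=s)
            wins += r2.elbo_trace[-1] > r5.elbo_trace[-1]
        assert wins >= 3


class TestSelectStateCount:
    def test_recovers_three_well_separated_states(self):
        rng = np.random.default_rng(33)
        means = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
        true = BhmmModel(np.full(3, 1 / 3),
                         np.full((3, 3), 0.2) + np.eye(3) * 0.4, means,
                         np.array([np.eye(2)] * 3))
        hits = 0
        for s in range(5):
            seqs = [simulate_from(true, 80, np.random.default_rng(s * 7
                                                                  + i))[0]
                    for i in range(6)]
            k, _ = select_state_count(seqs, range(1, 7), restarts=2, seed=s)
            hits += (k == 3)
        assert hits >= 4

    def test_point_mass_data_selects_one_state(self):
        X = np.zeros((40, 2)) + np.random.default_rng(0).normal(
            0, 1e-3, (40, 2))
        k, _ = select_state_count([X], [1, 2, 3], restarts=1, seed=0)
        assert k == 1

    def test_singleton_range_has_no_choice(self):
        rng = np.random.default_rng(0)
        k, res = select_state_count([rng.normal(0, 1, (30, 2))], [2],
                                    restarts=1, seed=0)
        assert k == 2 and set(res) == {2}

    def test_empty_range_rejected(self):
        with pytest.raises(ValueError):
            select_state_count([np.zeros((5, 2))], [], seed=0)

    def test_cross_check_against_hmmlearn_variational_fit(self):
        vhmm = pytest.importorskip("hmmlearn.vhmm")
        rng = np.random.default_rng(17)
        true = BhmmModel([0.5, 0.5], [[0.8, 0.2], [0.25, 0.75]],
                         [[0.0, 0.0], [8.0, 8.0]],
                         np.array([np.eye(2)] * 2))
        seqs = [simulate_from(true, 150, rng)[0] for _ in range(8)]
        ours, _ = vbem_fit(seqs, 2, restarts=2, seed=0)
        ref = vhmm.VariationalGaussianHMM(n_components=2,
                                          covariance_type="full",
                                          random_state=1, n_iter=200)
        ref.fit(np.concatenate(seqs), [len(s) for s in seqs])
        om = ours.means[np.argsort(ours.means[:, 0])]
        rm = ref.means_posterior_[np.argsort(ref.means_posterior_[:, 0])]
        np.testing.assert_allclose(om, rm, atol=0.5)
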