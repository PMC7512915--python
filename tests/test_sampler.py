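import numpy as np
import pytest

from catfusion import (CatfusionError, Hyperparams, conditional_probability,
                       init_state, run_gibbs)
from catfusion.sampler import (gibbs_sweep, k_log_weights, phi_log_weights,
                               step_k, step_lambda, step_omega, step_phi,
                               step_pi, step_x, x_weights)

from conftest import random_dataset


def small_hp(**kw):
    defaults = dict(n_iter=10, burn_in=2, thin=1, L=4, seed=0)
    defaults.update(kw)
    return Hyperparams(**defaults)


class TestHyperparams:
    @pytest.mark.parametrize("bad", [dict(b=1.0), dict(b=-0.1), dict(a=-1.5, b=0.5),
                                     dict(alpha=0.0), dict(thin=0),
                                     dict(burn_in=10, n_iter=10)])
    def test_invalid_rejected(self, bad):
        with pytest.raises(CatfusionError):
            small_hp(**bad)

    def test_defaults_follow_cardinalities(self):
        hp = Hyperparams(n_iter=10, burn_in=0)
        C = np.array([2, 4])
        np.testing.assert_allclose(hp.beta_vector(C), [0.5, 0.25])
        assert hp.truncation(C) == 8
        assert hp.truncation(np.array([3] * 10)) == 32


class TestInitState:
    def test_deterministic_and_forced(self, rng):
        ds = random_dataset(np.random.default_rng(5), T=30, q=2, C=[1, 3])
        hp = small_hp()
        s1 = init_state(ds, hp, np.random.default_rng(11))
        s2 = init_state(ds, hp, np.random.default_rng(11))
        np.testing.assert_array_equal(s1.x, s2.x)
        np.testing.assert_array_equal(s1.model.phi, s2.model.phi)
        np.testing.assert_allclose(s1.model.lam, s2.model.lam)
        # cardinality-1 column is forced to a single cluster and label
        assert s1.model.k[0] == 1
        assert np.all(s1.x[:, 0] == 0)
        s1.model.validate()

    def test_counts_match_defining_sums(self, rng):
        ds = random_dataset(rng, T=50, q=3, C=[2, 3, 2])
        state = init_state(ds, small_hp(), rng)
        counts = state.string_response_counts(ds)
        # recount oracle: brute-force loop over the data
        from catfusion.factor import string_strides

        brute = np.zeros_like(counts)
        strides = string_strides(state.model.k)
        for t in range(ds.T):
            code = int(np.dot(state.x[t], strides))
            brute[code, ds.y[t]] += 1
        np.testing.assert_array_equal(counts, brute)
        for j in range(3):
            mode = state.mode_level_counts(ds, j)
            for c in range(ds.C[j]):
                for s in range(state.model.k[j]):
                    assert mode[c, s] == np.sum(
                        (ds.z[:, j] == c) & (state.x[:, j] == s))


class TestStepPhi:
    def test_truncation_one_forces_zero(self, rng):
        ds = random_dataset(rng, T=20, q=2)
        state = init_state(ds, small_hp(L=1), rng)
        step_phi(state, ds, small_hp(L=1), rng)
        assert np.all(state.model.phi == 0)

    def test_empty_string_samples_from_pi(self, rng):
        """Strings with zero data count get log-weights equal to log pi."""
        ds = random_dataset(rng, T=10, q=2)
        state = init_state(ds, small_hp(), rng)
        state.x[:] = 0  # only string (0,0) is occupied
        logw = phi_log_weights(state, ds)
        expect = np.log(state.model.pi)
        for code in range(1, state.model.n_strings):
            np.testing.assert_allclose(logw[code] - logw[code].max(),
                                       expect - expect.max(), atol=1e-12)

    def test_two_cell_posterior_odds(self, rng):
        """Single string, L=2, counts (2,1): odds match the closed form
        pi_l * lam_l(0)^2 * lam_l(1)."""
        ds = random_dataset(rng, T=3, q=1, C=[1])
        ds.y[:] = [0, 0, 1]
        state = init_state(ds, small_hp(L=2), rng)
        logw = phi_log_weights(state, ds)[0]
        pi, lam = state.model.pi, state.model.lam
        hand = np.log(pi) + 2 * np.log(lam[:, 0]) + np.log(lam[:, 1])
        np.testing.assert_allclose(logw - logw[0], hand - hand[0], atol=1e-12)


class TestStepPi:
    def test_stick_identity_and_beta_params(self, rng):
        ds = random_dataset(rng, T=30, q=2)
        hp = small_hp(L=6)
        state = init_state(ds, hp, rng)
        for _ in range(5):
            step_pi(state, hp, rng)
            assert state.model.pi.sum() == pytest.approx(1.0, abs=1e-12)
            assert state.model.V[-1] == 1.0

    def test_posterior_stick_means(self):
        """With a=1, b=0 the sticks are Beta(1+n_l, 1+tail); the average of
        many conditional draws must match the analytic mean."""
        rng = np.random.default_rng(3)
        ds = random_dataset(rng, T=20, q=1, C=[2])
        hp = small_hp(L=3)
        state = init_state(ds, hp, rng)
        state.model.phi = np.array([0, 1])  # n = (1, 1, 0)
        n = np.array([1.0, 1.0, 0.0])
        tails = np.array([1.0, 0.0])  # sum of n beyond each stick
        mean_V = (1 + n[:2]) / (1 + n[:2] + 1 + tails)
        reps = 4000
        acc = np.zeros(3)
        for _ in range(reps):
            step_pi(state, hp, rng)
            acc += state.model.V
        got = acc / reps
        var = mean_V * (1 - mean_V) / (1 + n[:2] + 1 + tails + 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(got[:2] - mean_V) < 3 * se)


class TestStepLambdaOmega:
    def test_unoccupied_cluster_uses_prior(self):
        """Atoms with no assigned data follow Dirichlet(alpha,..): check the
        posterior-mean identity (alpha + n)/(C0 alpha + n_tot) within 3 SE."""
        rng = np.random.default_rng(7)
        ds = random_dataset(rng, T=40, q=1, C=[2])
        hp = small_hp(L=2, alpha=1.0)
        state = init_state(ds, hp, rng)
        state.model.phi[:] = 0  # atom 1 unoccupied
        n = state.string_response_counts(ds)
        nlc = np.zeros((2, 2))
        np.add.at(nlc, state.model.phi, n)
        nl0 = nlc[0]
        reps = 4000
        acc = np.zeros((2, 2))
        for _ in range(reps):
            step_lambda(state, ds, hp, rng)
            acc += state.model.lam
            assert np.allclose(state.model.lam.sum(1), 1.0, atol=1e-12)
        got = acc / reps
        mean0 = (1.0 + nl0) / (2.0 + nl0.sum())
        se0 = np.sqrt(mean0 * (1 - mean0) / (2.0 + nl0.sum() + 1) / reps)
        assert np.all(np.abs(got[0] - mean0) < 3 * se0)
        se1 = np.sqrt(0.25 / 3.0 / reps)
        assert np.all(np.abs(got[1] - 0.5) < 3 * se1)

    def test_omega_moments_and_degenerate(self):
        rng = np.random.default_rng(9)
        ds = random_dataset(rng, T=30, q=2, C=[2, 2])
        hp = small_hp(L=3, beta=1.0)
        state = init_state(ds, hp, rng)
        state.model.k[:] = [2, 1]
        state.k_pending[:] = [2, 1]
        state.model.omega[1] = np.ones((2, 1))
        state.x[:, 1] = 0
        state.model.phi = rng.integers(0, 3, size=2)
        counts = state.mode_level_counts(ds, 0)
        reps = 4000
        acc = np.zeros((2, 2))
        for _ in range(reps):
            step_omega(state, ds, hp, rng)
            acc += state.model.omega[0]
            # k_j = 1 gives the trivial one-column matrix exactly
            np.testing.assert_array_equal(state.model.omega[1], np.ones((2, 1)))
            assert np.allclose(state.model.omega[0].sum(1), 1.0, atol=1e-12)
        got = acc / reps
        mean = (1.0 + counts) / (2.0 + counts.sum(1, keepdims=True))
        se = np.sqrt(mean * (1 - mean) / (2.0 + counts.sum(1, keepdims=True) + 1) / reps)
        assert np.all(np.abs(got - mean) < 3 * se)


class TestStepX:
    def test_degenerate_dimension(self, rng):
        ds = random_dataset(rng, T=15, q=2, C=[1, 2])
        hp = small_hp()
        state = init_state(ds, hp, rng)
        step_x(state, ds, hp, rng)
        assert np.all(state.x[:, 0] == 0)
        assert np.all(state.x[:, 1] < state.model.k[1])

    def test_full_conditional_matches_enumeration(self, rng):
        """w(s) for one (t, j) cell equals the ratio of joint likelihoods
        with that coordinate swapped (everything else fixed)."""
        ds = random_dataset(rng, T=6, q=2, C=[2, 2])
        hp = small_hp(L=3)
        state = init_state(ds, hp, rng)
        j, t = 0, 2
        w = x_weights(state, ds, j)[t]
        # oracle: joint p(y_t, x_t | params) with x[t, j] = s
        from catfusion.factor import string_strides

        strides = string_strides(state.model.k)
        joint = np.empty(state.model.k[j])
        for s in range(state.model.k[j]):
            xs = state.x[t].copy()
            xs[j] = s
            code = int(np.dot(xs, strides))
            p = state.model.lam[state.model.phi[code], ds.y[t]]
            for jj in range(2):
                p *= state.model.omega[jj][ds.z[t, jj], xs[jj]]
            joint[s] = p
        np.testing.assert_allclose(w / w.sum(), joint / joint.sum(), atol=1e-12)


class TestStepK:
    def test_cardinality_one_forced(self, rng):
        ds = random_dataset(rng, T=10, q=1, C=[1])
        hp = small_hp()
        state = init_state(ds, hp, rng)
        step_k(state, ds, hp, rng)
        assert state.k_pending[0] == 1

    def test_single_observation_hand_values(self, rng):
        """C_j=2, beta=1, mu=0, one observation, one occupied label:
        p(k=1) = 2/3 and p(k=2) = 1/3 (Gamma(k)/Gamma(k+1) = 1/k)."""
        ds = random_dataset(rng, T=1, q=1, C=[2])
        ds.z[0, 0] = 0
        hp = small_hp(beta=1.0, mu=0.0)
        state = init_state(ds, hp, rng)
        state.x[0, 0] = 0
        support, logw = k_log_weights(state, ds, hp, 0)
        np.testing.assert_array_equal(support, [1, 2])
        p = np.exp(logw - logw.max())
        p /= p.sum()
        np.testing.assert_allclose(p, [2 / 3, 1 / 3], atol=1e-12)

    def test_support_excludes_occupied_labels(self, rng):
        ds = random_dataset(rng, T=12, q=1, C=[3])
        hp = small_hp()
        state = init_state(ds, hp, rng)
        state.x[:, 0] = np.resize([0, 1], 12)  # max label 1 -> support {2, 3}
        support, _ = k_log_weights(state, ds, hp, 0)
        np.testing.assert_array_equal(support, [2, 3])

    def test_collapsed_conditional_matches_mc_marginalization(self):
        """Monte-Carlo oracle: sample omega explicitly and average
        p(x | omega) to estimate the collapsed marginal on a 3-observation
        toy; the exact Dirichlet-multinomial form must agree within 3 SE."""
        rng = np.random.default_rng(12)
        ds = random_dataset(rng, T=3, q=1, C=[2])
        ds.z[:, 0] = [0, 0, 1]
        hp = small_hp(beta=0.7, mu=0.4)
        state = init_state(ds, hp, rng)
        state.x[:, 0] = [0, 0, 0]
        support, logw = k_log_weights(state, ds, hp, 0)
        ours = np.exp(logw - logw.max())
        ours /= ours.sum()

        draws = 200_000
        est = np.zeros(2)
        sems = np.zeros(2)
        for i, k in enumerate(support):
            om = rng.gamma(hp.beta, size=(draws, 2, k))
            om /= om.sum(axis=2, keepdims=True)
            lik = om[:, 0, 0] * om[:, 0, 0] * om[:, 1, 0]  # z=(0,0,1), x=(0,0,0)
            prior_k = np.exp(-hp.mu * k)
            est[i] = prior_k * lik.mean()
            sems[i] = prior_k * lik.std() / np.sqrt(draws)
        mc = est / est.sum()
        # delta-method SE on the normalized probability
        se = np.hypot(sems[0] * est[1], sems[1] * est[0]) / est.sum() ** 2
        assert abs(ours[0] - mc[0]) < 3 * max(se, 1e-6)


class TestSweepAndRun:
    def test_invariants_hold_every_sweep(self, rng):
        ds = random_dataset(rng, T=60, q=3, C=[2, 3, 2])
        hp = small_hp(L=5, n_iter=25, burn_in=5)
        state = init_state(ds, hp, rng)
        for _ in range(25):
            ll = gibbs_sweep(state, ds, hp, rng)
            assert np.isfinite(ll)
            state.model.validate()
            assert np.all(state.x < state.model.k[None, :])
            assert np.all(state.ktilde() <= state.model.k)

    def test_huge_penalty_dominates_and_collapses(self, rng):
        """An overwhelming penalty always picks the smallest admissible
        dimension (one more than the largest occupied label), so the chain
        coalesces to k_j = 1 as the occupied labels merge."""
        ds = random_dataset(rng, T=6, q=2, C=[2, 3])
        hp = small_hp(mu=1e6, n_iter=400, burn_in=1)
        state = init_state(ds, hp, rng)
        for sweep in range(400):
            gibbs_sweep(state, ds, hp, rng)
            expected = state.x.max(axis=0) + 1
            np.testing.assert_array_equal(state.k_pending, expected)
            if np.all(state.model.k == 1):
                break
        assert np.all(state.model.k == 1)

    def test_run_gibbs_reproducible_and_sized(self, rng):
        ds = random_dataset(np.random.default_rng(2), T=60, q=2)
        hp = small_hp(n_iter=40, burn_in=10, thin=3, seed=123)
        e1 = run_gibbs(ds, hp)
        e2 = run_gibbs(ds, hp)
        assert len(e1) == (40 - 10) // 3
        np.testing.assert_allclose(e1.loglik_trace, e2.loglik_trace)
        np.testing.assert_array_equal(e1.ktilde_matrix, e2.ktilde_matrix)
        for s1, s2 in zip(e1.samples, e2.samples):
            np.testing.assert_allclose(s1.model.lam, s2.model.lam)
        for s in e1.samples:
            s.model.validate()

    def test_forced_single_cluster_matches_conjugate_form(self):
        """With every k_j pinned at 1 the model is an iid categorical with a
        Dirichlet(alpha) prior; the posterior predictive must match
        (alpha + count_c)/(C0 alpha + T) within Monte-Carlo error."""
        rng = np.random.default_rng(21)
        ds = random_dataset(rng, T=120, q=2, C0=3)
        hp = Hyperparams(mu=1e6, L=4, alpha=1.0, n_iter=600, burn_in=100,
                         thin=1, seed=5)
        ens = run_gibbs(ds, hp)
        counts = np.bincount(ds.y, minlength=3)
        closed = (1.0 + counts) / (3.0 + ds.T)
        probe = np.array([0, 0])
        draws = np.stack([
            conditional_probability(s.model, probe) for s in ens.samples
        ])
        got = draws.mean(axis=0)
        se = draws.std(axis=0) / np.sqrt(len(ens))
        # retained draws autocorrelate; inflate the naive SE generously
        assert np.all(np.abs(got - closed) < 3 * se * 3 + 1e-3)

    def test_loglik_is_post_sweep_model_likelihood(self, rng):
        ds = random_dataset(rng, T=40, q=2)
        hp = small_hp(n_iter=5, burn_in=1, seed=9)
        state = init_state(ds, hp, rng)
        ll = gibbs_sweep(state, ds, hp, rng)
        direct = sum(
            np.log(conditional_probability(state.model, ds.z[t])[ds.y[t]])
            for t in range(ds.T)
        )
        assert ll == pytest.approx(direct, abs=1e-8)
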