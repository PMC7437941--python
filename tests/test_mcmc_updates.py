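"""Unit tests of the seven conditional updates against closed forms and
brute-force oracles."""

import numpy as np
import pytest
from scipy import stats

from hbfm import ExpressionCounts, ModelState, SamplerConfig, run_chain
from hbfm.mcmc import (GibbsSweeper, update_alpha, update_beta, update_h1,
                       update_h2, update_lambda, update_phi, update_theta)

from conftest import counts_from_state, make_state


def flat_state(G, N, F=1, **kw):
    """Inactive-loading state with unit factors (product term is 1)."""
    defaults = dict(
        beta=np.ones(G), alpha=np.zeros((G, F), dtype=int),
        lam=np.ones((N, F)), phi=np.full(F, 0.5), theta=np.zeros(F),
    )
    defaults.update(kw)
    return ModelState(**defaults)


class TestBetaUpdate:
    def test_inactive_loadings_match_closed_form_gamma(self, rng):
        # replicated genes with identical counts give iid draws from
        # Gamma(0.001 + sum y, 0.001 + N)
        G, N = 20_000, 2
        y = np.tile([3, 1], (G, 1))
        state = flat_state(G, N)
        draws = update_beta(ExpressionCounts(y), state, rng)
        a, b = 4.001, 2.001
        assert draws.mean() == pytest.approx(a / b, abs=3 * np.sqrt(a / b**2 / G))
        ks = stats.kstest(draws, lambda q: stats.gamma.cdf(q, a, scale=1 / b))
        assert ks.pvalue > 0.001

    def test_active_loadings_rate_uses_mean_product(self, toy_state, toy_counts, rng):
        # conditional mean of beta_g approaches (sum_i y_gi)/(sum_i W_gi)
        draws = np.array([
            update_beta(toy_counts, toy_state, np.random.default_rng(s))
            for s in range(3000)
        ])
        sw = GibbsSweeper(toy_counts, toy_state)
        expect = (0.001 + toy_counts.values.sum(1)) / (0.001 + sw.W.sum(1))
        assert np.allclose(draws.mean(0), expect, rtol=0.05)


class TestThetaUpdate:
    def test_counts_of_active_loadings_set_beta_params(self, rng):
        G, F = 10, 30_000
        alpha = np.zeros((G, F), dtype=int)
        alpha[:4, :] = 1  # 4 active per factor
        state = flat_state(G, 1, F=F, alpha=alpha, lam=np.ones((1, F)),
                           phi=np.full(F, 0.5), theta=np.full(F, 0.5))
        draws = update_theta(state, rng)
        # Beta(1+4, 1+6) mean 5/12
        se = np.sqrt(stats.beta.var(5, 7) / F)
        assert draws.mean() == pytest.approx(5 / 12, abs=3 * se)


class TestAlphaUpdate:
    def test_matches_bruteforce_enumeration(self, toy_state, toy_counts):
        """Conditional three-way probabilities equal direct joint evaluation."""
        sw = GibbsSweeper(toy_counts, toy_state)
        y = toy_counts.values

        def joint_logp(val, g, f):
            st = toy_state.copy()
            st.alpha[g, f] = val
            af = st.alpha.astype(float)
            lm = (np.log(st.beta)[:, None] + af @ np.log(st.lam).T
                  - (0.5 * (np.abs(af) @ st.phi))[:, None])
            ll = np.sum(y * lm - np.exp(lm))
            prior = np.log(1 - st.theta[f]) if val == 0 else np.log(st.theta[f] / 2)
            return ll + prior

        for f in range(toy_state.n_factors):
            lw = sw._alpha_logweights(f)[0]
            for g in range(toy_state.n_genes):
                direct = np.array([joint_logp(v, g, f) for v in (0, 1, -1)])
                expected = np.exp(direct - direct.max())
                expected /= expected.sum()
                got = np.exp(lw[:, g] - lw[:, g].max())
                got /= got.sum()
                assert np.allclose(got, expected, atol=1e-8)

    def test_zero_activation_probability_forces_inactive(self, rng):
        state = make_state(seed=5)
        state.theta[:] = 0.0
        Y = counts_from_state(state)
        assert np.all(update_alpha(Y, state, rng) == 0)

    def test_unit_factors_reduce_to_prior_probabilities(self, rng):
        # lambda = 1 and phi ~ 0 make the likelihood indifferent to alpha
        G = 30_000
        state = flat_state(G, 3, phi=np.array([1e-9]), theta=np.array([0.6]))
        Y = ExpressionCounts(np.zeros((G, 3), dtype=int))
        draws = update_alpha(Y, state, rng).ravel()
        freq = [(draws == v).mean() for v in (0, 1, -1)]
        se = 3 * np.sqrt(0.25 / G)
        assert freq[0] == pytest.approx(0.4, abs=se)
        assert freq[1] == pytest.approx(0.3, abs=se)
        assert freq[2] == pytest.approx(0.3, abs=se)


class TestHyperUpdates:
    def test_h1_posterior_moments(self):
        # F=4, log phi = 1 each, h2=1: mean 4/4.01, var 1/4.01
        state = flat_state(2, 1, F=4, phi=np.full(4, np.e),
                           lam=np.ones((1, 4)), theta=np.zeros(4))
        state.h2 = 1.0
        draws = np.array([
            update_h1(state, np.random.default_rng(s)) for s in range(4000)
        ])
        assert draws.mean() == pytest.approx(4 / 4.01, abs=3 * np.sqrt(1 / 4.01 / 4000))
        assert draws.var() == pytest.approx(1 / 4.01, rel=0.15)

    def test_h2_inverse_gamma_moments(self):
        # F=2 with residual SS 2 about h1: IG(2, 2), mean 2
        state = flat_state(2, 1, F=2, phi=np.exp([1.0, -1.0]) * np.e**0,
                           lam=np.ones((1, 2)), theta=np.zeros(2))
        state.h1 = 0.0
        state.phi = np.exp(np.array([1.0, -1.0]))
        draws = np.array([
            update_h2(state, np.random.default_rng(s)) for s in range(4000)
        ])
        assert np.all(draws > 0)
        se = np.sqrt(stats.invgamma.var(2, scale=2) / 4000)
        assert draws.mean() == pytest.approx(2.0, abs=3 * se)


class TestPhiUpdate:
    def test_inactive_factor_sampled_from_prior(self):
        G, F = 3, 1500
        state = flat_state(G, 2, F=F, lam=np.ones((2, F)),
                           phi=np.full(F, 0.5), theta=np.zeros(F))
        state.h1, state.h2 = 0.3, 0.6
        Y = ExpressionCounts(np.zeros((G, 2), dtype=int))
        draws = update_phi(Y, state, SamplerConfig(), np.random.default_rng(2))
        ks = stats.kstest(np.log(draws), lambda q: stats.norm.cdf(q, 0.3, np.sqrt(0.6)))
        assert ks.pvalue > 0.01

    def test_active_factor_acceptance_strictly_interior(self, toy_state, toy_counts):
        sw = GibbsSweeper(toy_counts, toy_state,
                          SamplerConfig(seed=4, adapt_phi=False))
        for _ in range(1000):
            sw.sweep_phi()
        acc, tot = sw.acc["phi"]
        assert 0 < acc < tot


class TestLambdaUpdate:
    def test_inactive_factor_sampled_from_prior(self):
        G, N = 2, 8000
        state = flat_state(G, N, phi=np.array([0.7]))
        Y = ExpressionCounts(np.zeros((G, N), dtype=int))
        draws = update_lambda(Y, state, SamplerConfig(), np.random.default_rng(3))
        ks = stats.kstest(np.log(draws[:, 0]),
                          lambda q: stats.norm.cdf(q, 0, np.sqrt(0.7)))
        assert ks.pvalue > 0.01

    def test_gamma_limit_branch_runs_when_only_positive_loadings(self, rng):
        state = make_state(alpha=np.array([[1], [1], [0]]), N=50, seed=8)
        Y = counts_from_state(state, seed=12)
        draws = update_lambda(Y, state, SamplerConfig(), rng)
        assert np.all(draws > 0)

    def test_inverse_gamma_limit_branch_when_only_negative(self, rng):
        state = make_state(alpha=np.array([[-1], [-1], [0]]), N=50, seed=8)
        Y = counts_from_state(state, seed=12)
        draws = update_lambda(Y, state, SamplerConfig(), rng)
        assert np.all(draws > 0)


class TestRunChain:
    def test_trace_contract(self, toy_state, toy_counts):
        cfg = SamplerConfig(n_iter=120, n_retain=40, seed=6)
        tr = run_chain(toy_counts, toy_state, cfg)
        assert tr.failed is None
        assert tr.n_retained == 40
        assert np.allclose(tr.deviance, -2.0 * tr.loglik)
        assert tr.rho_samples.shape == (40, 5, 5)

    def test_same_seed_reproduces_bitwise(self, toy_state, toy_counts):
        cfg = SamplerConfig(n_iter=80, n_retain=20, seed=11)
        t1 = run_chain(toy_counts, toy_state, cfg)
        t2 = run_chain(toy_counts, toy_state, cfg)
        assert np.array_equal(t1.rho_samples, t2.rho_samples)
        assert np.array_equal(t1.loglik, t2.loglik)
        assert np.array_equal(t1.final_state.lam, t2.final_state.lam)

    def test_incremental_w_matches_recomputation(self, toy_state, toy_counts):
        sw = GibbsSweeper(toy_counts, toy_state, SamplerConfig(seed=2))
        for _ in range(60):
            sw.full_sweep()
        drifted = sw.W.copy()
        sw.recompute_W()
        assert np.allclose(drifted, sw.W, rtol=1e-8)

    def test_trace_round_trip(self, toy_state, toy_counts, tmp_path):
        from hbfm.mcmc import ChainTrace
        cfg = SamplerConfig(n_iter=60, n_retain=10, seed=3)
        tr = run_chain(toy_counts, toy_state, cfg)
        tr.save(tmp_path / "chain.npz")
        back = ChainTrace.load(tmp_path / "chain.npz")
        assert np.array_equal(back.rho_samples, tr.rho_samples)
        assert np.array_equal(back.alpha_samples, tr.alpha_samples)
        assert np.allclose(back.final_state.beta, tr.final_state.beta)
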