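"""Distributional machinery: log-normal moment algebra, joint assembly,
reparameterised sampling, denoising, and the sample-based derivative
estimators with their noisy-moment reconstruction."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from dpinns.autodiff import Tensor
from dpinns import moments as mo


class TestMomentTransforms:
    def test_degenerate_lognormal(self):
        lm = mo.linear_to_log_moments(mo.MomentPair(1.0, 0.0))
        assert lm.mu_log == pytest.approx(0.0)
        assert lm.var_log == pytest.approx(0.0)

    def test_mean20_var4_frozen_values(self):
        # moment matching: mu = ln(400/sqrt(404)), s2 = ln(1.01)
        lm = mo.linear_to_log_moments(mo.MomentPair(20.0, 4.0))
        assert lm.mu_log == pytest.approx(2.990757108127407, rel=1e-12)
        assert lm.var_log == pytest.approx(0.009950330853168092, rel=1e-12)

    def test_mean20_var4_against_monte_carlo(self, rng):
        lm = mo.linear_to_log_moments(mo.MomentPair(20.0, 4.0))
        draws = np.exp(rng.normal(lm.mu_log, np.sqrt(lm.var_log), 2_000_000))
        assert draws.mean() == pytest.approx(20.0, rel=3e-3)
        assert draws.var(ddof=1) == pytest.approx(4.0, rel=2e-2)

    def test_negative_mean_rejected(self):
        with pytest.raises(ValueError):
            mo.linear_to_log_moments(mo.MomentPair(-1.0, 1.0))

    def test_inverse_identity_at_origin(self):
        m = mo.log_to_linear_moments(mo.LogMomentPair(0.0, 0.0))
        assert m.mean == pytest.approx(1.0)
        assert m.variance == pytest.approx(0.0)

    def test_closed_form_mean_recovery(self):
        m = mo.log_to_linear_moments(mo.LogMomentPair(np.log(20) - 0.005, 0.01))
        assert m.mean == pytest.approx(20.0, rel=1e-12)

    @given(st.floats(0.01, 1e3), st.floats(0.0, 1e4))
    def test_round_trip_exact(self, mean, var):
        lm = mo.linear_to_log_moments(mo.MomentPair(mean, var))
        back = mo.log_to_linear_moments(lm)
        assert back.mean == pytest.approx(mean, rel=1e-12)
        assert back.variance == pytest.approx(var, rel=1e-10, abs=1e-12)


class TestJointAssembly:
    def _joint(self, cross, rho=0.0):
        m = np.array([20.0, 10.0, 5.0])
        v = np.array([4.0, 2.0, 1.0])
        mu = np.array([2.7, -2.1])
        sd = np.array([0.1, 0.39])
        return mo.assemble_joint(mo.MomentPair(m, v), mu, sd, rho, cross)

    def test_zero_cross_gives_block_diagonal(self):
        jp = self._joint(np.zeros(2), rho=0.3)
        cov = mo.joint_covariance(jp)
        assert cov.shape == (3, 3, 3)
        np.testing.assert_allclose(cov[:, 0, 1:], 0.0, atol=1e-15)

    def test_parameter_block_equals_population_covariance(self):
        rho, sd = 0.3, np.array([0.1, 0.39])
        jp = self._joint(np.array([0.2, -0.4]), rho=rho)
        cov = mo.joint_covariance(jp)
        expected = np.array([[sd[0] ** 2, rho * sd[0] * sd[1]],
                             [rho * sd[0] * sd[1], sd[1] ** 2]])
        for j in range(3):
            np.testing.assert_allclose(cov[j, 1:, 1:], expected, rtol=1e-12)

    def test_psd_repair_on_infeasible_correlations(self):
        # rho(c,1)=0.9, rho(c,2)=0.9, rho(1,2)=-0.9 is not a valid
        # correlation matrix; repair must lift the smallest eigenvalue
        jp = self._joint(np.array([0.9, 0.9]), rho=-0.9)
        cov = mo.joint_covariance(jp)
        for j in range(3):
            assert np.linalg.eigvalsh(cov[j]).min() >= 0.0
        R = jp.chol_corr @ jp.chol_corr.T
        assert np.linalg.eigvalsh(R).min() >= 1e-7

    def test_chol3_matches_lapack(self, rng):
        for dim in (2, 3):
            A = rng.normal(size=(dim, dim))
            R = A @ A.T + dim * np.eye(dim)
            d = np.sqrt(np.diag(R))
            R = R / np.outer(d, d)
            L = mo.chol3([[R[i][j] for j in range(dim)] for i in range(dim)])
            np.testing.assert_allclose(L, np.linalg.cholesky(R), rtol=1e-12)


class TestDrawJoint:
    def _jp(self):
        m = np.full(4, 20.0)
        v = np.full(4, 4.0)
        return mo.assemble_joint(mo.MomentPair(m, v), np.array([2.7, -2.1]),
                                 np.array([0.1, 0.39]), 0.0,
                                 np.array([0.0, -0.5]))

    def test_determinism_under_seed(self):
        jp = self._jp()
        c1, p1, _ = mo.draw_joint(jp, 50, np.random.default_rng(7))
        c2, p2, _ = mo.draw_joint(jp, 50, np.random.default_rng(7))
        np.testing.assert_array_equal(c1, c2)
        np.testing.assert_array_equal(p1, p2)

    def test_minimum_two_samples(self):
        with pytest.raises(ValueError):
            mo.draw_joint(self._jp(), 1, np.random.default_rng(0))

    def test_monte_carlo_consistency(self, rng):
        # sample log-moments converge to the assembled joint parameters
        jp = self._jp()
        n = 200_000
        conc, pars, _ = mo.draw_joint(jp, n, rng)
        logs = np.log(np.concatenate(
            [conc[0][:, None], pars[0]], axis=1))
        cov_target = mo.joint_covariance(jp)[0]
        se = 3.0 / np.sqrt(n)
        np.testing.assert_allclose(logs.mean(axis=0), jp.mu[0],
                                   atol=4 * se)
        np.testing.assert_allclose(np.cov(logs.T), cov_target,
                                   atol=6 * se)

    def test_gradient_through_sampling(self):
        # AD gradient of a scalar loss w.r.t. the distributional mean
        # matches finite differences through the reparameterised draw
        z = np.random.default_rng(3).standard_normal((2, 40, 3))

        def loss_np(mu_val):
            jp = mo.assemble_joint(
                mo.MomentPair(np.array([20.0, 10.0]), np.array([4.0, 2.0])),
                np.array([mu_val, -2.1]), np.array([0.1, 0.39]), 0.0,
                np.array([0.1, -0.3]))
            conc, pars, _ = mo.draw_joint(jp, 40, None, z=z)
            return float((pars ** 2).mean() + conc.mean())

        mu = Tensor(np.array([2.7, -2.1]), requires_grad=True)
        jp = mo.assemble_joint(
            mo.MomentPair(np.array([20.0, 10.0]), np.array([4.0, 2.0])),
            mu, np.array([0.1, 0.39]), 0.0, np.array([0.1, -0.3]))
        conc, pars, _ = mo.draw_joint(jp, 40, None, z=z)
        loss = (pars ** 2).mean() + conc.mean()
        loss.backward()
        h = 1e-6
        g_fd = (loss_np(2.7 + h) - loss_np(2.7 - h)) / (2 * h)
        assert mu.grad[0] == pytest.approx(g_fd, rel=1e-5)


class TestDenoising:
    def test_stochastic_inversion_exact_when_eps_forced(self):
        out = mo.denoise_samples(np.array([[2.0]]), mo.ResidualModel(1.0),
                                 None, eps_z=np.array([[np.log(2.0)]]))
        assert out[0, 0] == pytest.approx(1.0)

    def test_zero_sigma_is_identity(self):
        c = np.array([[1.0, 2.0, 3.0]])
        out = mo.denoise_samples(c, mo.ResidualModel(0.0), None,
                                 eps_z=np.ones_like(c))
        np.testing.assert_array_equal(out, c)
        lm = mo.linear_to_log_moments(mo.MomentPair(np.array([2.0]),
                                                    np.array([1.0])))
        out2 = mo.denoise_shrinkage(c, lm.mu_log, lm.var_log, 0.0)
        np.testing.assert_allclose(out2, c, rtol=1e-6)

    def test_shrinkage_reproduces_true_moment_relations(self, rng):
        # forward model: C = C_true e^eps; denoising must recover
        # E[C_true] = E[C] e^{-sigma^2/2} and the matching variance
        sigma, n = 0.25, 1_000_000
        c_true = np.exp(rng.normal(3.0, 0.4, n))
        c_obs = c_true * np.exp(rng.normal(0.0, sigma, n))
        m, v = c_obs.mean(), c_obs.var(ddof=1)
        lm = mo.linear_to_log_moments(mo.MomentPair(np.array([m]),
                                                    np.array([v])))
        den = mo.denoise_shrinkage(c_obs[None, :], lm.mu_log, lm.var_log,
                                   sigma)
        assert den.mean() == pytest.approx(m * np.exp(-sigma ** 2 / 2),
                                           rel=5e-3)
        assert den.var(ddof=1) == pytest.approx(c_true.var(ddof=1), rel=2e-2)


class TestDerivativeEstimators:
    def test_mean_derivative_simple_average(self):
        assert mo.estimate_mean_derivative(np.array([[1.0, 2.0, 3.0]]))[0] \
            == pytest.approx(2.0)

    def test_var_derivative_hand_case(self):
        # C = {1, 3}, dC = {0, 2}: (2/1)[(1-2)(0-1) + (3-2)(2-1)] = 4
        d = mo.estimate_var_derivative(np.array([[1.0, 3.0]]),
                                       np.array([[0.0, 2.0]]))
        assert d[0] == pytest.approx(4.0)

    def test_var_derivative_zero_for_identical_samples(self):
        d = mo.estimate_var_derivative(np.full((1, 5), 2.0),
                                       np.full((1, 5), -1.3))
        assert d[0] == pytest.approx(0.0)

    def test_var_derivative_sign_flips_with_negated_derivatives(self, rng):
        c = rng.uniform(1, 5, (1, 50))
        dc = rng.normal(size=(1, 50))
        dm = dc.mean()
        flipped = 2 * dm - dc  # negate around the mean derivative
        d1 = mo.estimate_var_derivative(c, dc)
        d2 = mo.estimate_var_derivative(c, flipped)
        assert d1[0] == pytest.approx(-d2[0])

    def test_requires_two_samples(self):
        with pytest.raises(ValueError):
            mo.estimate_var_derivative(np.ones((1, 1)), np.ones((1, 1)))

    def test_estimators_match_finite_difference_of_sample_moments(self, rng):
        # For a frozen set of individual (Vd, ke) draws, the sample mean
        # and unbiased variance of the exactly integrated profiles are
        # differentiable in t; the estimators must match their central
        # finite differences.
        n = 400
        vd = np.exp(rng.normal(np.log(15.0), 0.1, n))
        ke = np.exp(rng.normal(np.log(0.115), 0.38, n))
        t, h = 5.0, 1e-4

        def profiles(tt):
            return (300.0 / vd) * np.exp(-ke * tt)

        c = profiles(t)[None, :]
        dc = (-ke * profiles(t))[None, :]
        dm_fd = (profiles(t + h).mean() - profiles(t - h).mean()) / (2 * h)
        dv_fd = (profiles(t + h).var(ddof=1)
                 - profiles(t - h).var(ddof=1)) / (2 * h)
        assert mo.estimate_mean_derivative(dc)[0] == pytest.approx(
            dm_fd, abs=1e-6, rel=1e-6)
        assert mo.estimate_var_derivative(c, dc)[0] == pytest.approx(
            dv_fd, abs=1e-6, rel=1e-5)


class TestNoisyReconstruction:
    def test_sigma_zero_identities(self):
        rm = mo.ResidualModel(0.0)
        assert mo.noisy_mean_derivative(1.7, rm) == pytest.approx(1.7)
        assert mo.noisy_var_derivative(5.0, 1.7, -0.4, rm) \
            == pytest.approx(-0.4)

    def test_mean_inflation_closed_form(self):
        rm = mo.ResidualModel(0.1)
        assert mo.noisy_mean_derivative(1.0, rm) \
            == pytest.approx(np.exp(0.005), rel=1e-12)

    def test_var_reduction_when_mean_derivative_zero(self):
        rm = mo.ResidualModel(0.3)
        s2 = 0.09
        assert mo.noisy_var_derivative(5.0, 0.0, 2.0, rm) \
            == pytest.approx(np.exp(2 * s2) * 2.0, rel=1e-12)

    def test_reconstruction_matches_symbolic_differentiation(self):
        # Observed moments of C = C_true e^eps:
        #   E[C] = e^{s2/2} M,  Var[C] = (V + M^2) e^{2 s2} - M^2 e^{s2}.
        # The reconstruction must equal d/dt of those exact expressions
        # for arbitrary smooth M(t), V(t).
        import sympy as sp
        t, s = sp.symbols("t sigma", positive=True)
        M = 20 * sp.exp(-sp.Rational(1, 8) * t)
        V = 4 * sp.exp(-sp.Rational(1, 5) * t) + sp.Rational(1, 2)
        s2 = s ** 2
        obs_mean = sp.exp(s2 / 2) * M
        obs_var = (V + M ** 2) * sp.exp(2 * s2) - M ** 2 * sp.exp(s2)
        for tv, sv in [(0.7, 0.1), (3.0, 0.25), (12.0, 0.05)]:
            subs = {t: tv, s: sv}
            rm = mo.ResidualModel(sv)
            mt = float(M.subs(subs))
            dmt = float(sp.diff(M, t).subs(subs))
            dvt = float(sp.diff(V, t).subs(subs))
            rec_m = mo.noisy_mean_derivative(dmt, rm)
            rec_v = mo.noisy_var_derivative(mt, dmt, dvt, rm)
            assert rec_m == pytest.approx(
                float(sp.diff(obs_mean, t).subs(subs)), rel=1e-10)
            assert rec_v == pytest.approx(
                float(sp.diff(obs_var, t).subs(subs)), rel=1e-10)


class TestVarToSD:
    @pytest.mark.parametrize("dv,sd,expected", [
        (4.0, 1.0, 2.0), (0.0, 0.37, 0.0)])
    def test_chain_rule_values(self, dv, sd, expected):
        assert mo.var_to_sd_derivative(dv, sd) == pytest.approx(expected)

    def test_symbolic_chain_rule_consistency(self):
        # Var(t) = t^2 has SD(t) = t; at t=1, dVar/dt = 2 and SD = 1
        assert mo.var_to_sd_derivative(2.0, 1.0) == pytest.approx(1.0)

    def test_floor_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            out = mo.var_to_sd_derivative(1.0, 1e-12, floor=1e-8)
        assert out == pytest.approx(1.0 / (2e-8))
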