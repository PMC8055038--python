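"""Gibbs full conditionals against closed forms and independent oracles."""

import numpy as np
import pytest
from scipy import special, stats

from depindex import irt
from depindex._util import truncnorm_onesided


RNG = np.random.default_rng


class TestLatentUtilities:
    def test_zero_side_truncation(self):
        X = np.zeros((200, 1))
        xs = irt.step_latent_utilities(
            X, np.zeros((1, 1)), np.ones((1, 1)), np.zeros(200), np.zeros(200, int),
            RNG(0),
        )
        assert (xs <= 0).all()

    def test_half_normal_mean_at_zero_linear_predictor(self):
        n = 10**5
        X = np.ones((n, 1))
        xs = irt.step_latent_utilities(
            X, np.zeros((1, 1)), np.ones((1, 1)), np.zeros(n), np.zeros(n, int), RNG(1)
        )
        target = np.sqrt(2 / np.pi)  # half-normal mean
        se = np.sqrt(1 - 2 / np.pi) / np.sqrt(n)
        assert abs(xs.mean() - target) < 3 * se

    def test_far_tail_truncated_mean_matches_closed_form(self):
        n = 10**5
        mean = 5.0
        X = np.ones((n, 1))
        xs = irt.step_latent_utilities(
            X, np.full((1, 1), mean), np.full((1, 1), 1e-12), np.zeros(n),
            np.zeros(n, int), RNG(2),
        )
        # N(5,1) truncated to (0, inf): mean = 5 + phi(-5)/(1 - Phi(-5))
        closed = mean + stats.norm.pdf(-mean) / (1 - stats.norm.cdf(-mean))
        assert abs(xs.mean() - closed) < 3 / np.sqrt(n)

    def test_extreme_linear_predictor_stays_finite(self):
        X = np.array([[1.0], [0.0]])
        xs = irt.step_latent_utilities(
            X, np.array([[12.0]]), np.array([[1e-12]]), np.zeros(2),
            np.zeros(2, int), RNG(3),
        )
        assert np.isfinite(xs).all()
        assert xs[0, 0] > 0 and xs[1, 0] <= 0


class TestThetaConditional:
    def test_single_item_hand_case(self):
        m, V = irt.theta_full_conditional(
            np.array([[1.5]]), np.array([[0.0]]), np.array([[1.0]]), np.zeros(1, int)
        )
        assert m[0] == pytest.approx(0.75, abs=1e-10)
        assert V[0] == pytest.approx(0.5, abs=1e-10)

    def test_zero_discrimination_reverts_to_prior(self):
        m, V = irt.theta_full_conditional(
            np.array([[2.0, -1.0]]),
            np.zeros((2, 1)),
            np.zeros((2, 1)),
            np.zeros(1, int),
        )
        assert m[0] == pytest.approx(0.0, abs=1e-12)
        assert V[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_item_hand_case(self):
        m, V = irt.theta_full_conditional(
            np.array([[1.0, 1.0]]),
            np.zeros((2, 1)),
            np.array([[1.0], [2.0]]),
            np.zeros(1, int),
        )
        assert m[0] == pytest.approx(3.0 / 6.0, abs=1e-10)
        assert V[0] == pytest.approx(1.0 / 6.0, abs=1e-10)


class TestItemRegressionPosterior:
    def test_flat_prior_exact_line(self):
        mean, _ = irt.item_regression_posterior(
            np.array([-1.0, 0.0, 1.0]),
            np.array([-1.0, 0.0, 1.0]),
            np.zeros(2),
            np.array([np.inf, np.inf]),
        )
        np.testing.assert_allclose(mean, [0.0, 1.0], atol=1e-10)

    def test_prior_domination(self):
        mean, cov = irt.item_regression_posterior(
            np.array([5.0, -3.0]),
            np.array([0.3, -0.2]),
            np.array([0.7, 1.3]),
            np.array([1e-12, 1e-12]),
        )
        np.testing.assert_allclose(mean, [0.7, 1.3], atol=1e-6)
        assert cov[0, 0] < 1e-10 and cov[1, 1] < 1e-10

    def test_matches_two_d_grid_oracle(self):
        rng = RNG(8)
        theta = rng.standard_normal(12)
        xs = 0.4 + 0.9 * theta + rng.standard_normal(12)
        prior_mean = np.array([0.2, 0.8])
        prior_var = np.array([1.5, 2.0])
        mean, cov = irt.item_regression_posterior(xs, theta, prior_mean, prior_var)

        grid = np.linspace(-4, 4, 401)
        A, B = np.meshgrid(grid, grid, indexing="ij")
        logpost = -0.5 * ((xs[None, None, :] - A[..., None] - B[..., None] * theta) ** 2).sum(-1)
        logpost -= 0.5 * (A - prior_mean[0]) ** 2 / prior_var[0]
        logpost -= 0.5 * (B - prior_mean[1]) ** 2 / prior_var[1]
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        mean_grid = np.array([(w * A).sum(), (w * B).sum()])
        np.testing.assert_allclose(mean, mean_grid, atol=2e-3)
        var_grid = np.array(
            [(w * (A - mean_grid[0]) ** 2).sum(), (w * (B - mean_grid[1]) ** 2).sum()]
        )
        np.testing.assert_allclose(np.diag(cov), var_grid, atol=2e-3)

    def test_degenerate_design_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            irt.item_regression_posterior(
                np.array([1.0, 2.0]),
                np.array([0.5, 0.5]),
                np.zeros(2),
                np.array([np.inf, np.inf]),
            )


class TestConstrainedCellSampler:
    def test_chain_matches_truncated_grid_oracle(self):
        """The sub-Gibbs scan's invariant law is the beta>0-truncated posterior."""
        rng = RNG(9)
        theta = rng.standard_normal(8)
        xs2 = -0.5 + 0.3 * theta + rng.standard_normal(8)
        pm = np.array([0.0, 0.0])
        pv = np.array([4.0, 4.0])
        mean, cov = irt.item_regression_posterior(xs2, theta, pm, pv)

        n_draws = 40000
        a_draws = np.empty(n_draws)
        b_draws = np.empty(n_draws)
        beta = 1.0
        x_star = xs2[:, None]
        for s in range(n_draws):
            a, b = irt.step_item_params(
                x_star, theta, np.zeros(8, int),
                pm[:1], pv[:1], pm[1:], pv[1:], np.array([[beta]]), rng,
            )
            a_draws[s], b_draws[s] = a[0, 0], b[0, 0]
            beta = b_draws[s]

        grid_a = np.linspace(mean[0] - 5, mean[0] + 5, 301)
        grid_b = np.linspace(1e-4, mean[1] + 5 * np.sqrt(cov[1, 1]) + 3, 301)
        A, B = np.meshgrid(grid_a, grid_b, indexing="ij")
        dev = np.stack([A - mean[0], B - mean[1]], axis=-1)
        prec = np.linalg.inv(cov)
        logpost = -0.5 * np.einsum("...i,ij,...j->...", dev, prec, dev)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        ea, eb = (w * A).sum(), (w * B).sum()
        # compare to 4 effective MC SEs (draws are autocorrelated)
        se_a = 4 * a_draws.std() / np.sqrt(n_draws / 10)
        se_b = 4 * b_draws.std() / np.sqrt(n_draws / 10)
        assert abs(a_draws.mean() - ea) < se_a
        assert abs(b_draws.mean() - eb) < se_b
        assert (b_draws > 0).all()


class TestHyperConditionals:
    def test_equal_values_center_posterior_mean(self):
        spec = irt.IrtModelSpec(prior_loc_sd=1e6)
        values = np.full((1, 4), 2.5)
        mu_mean, _ = irt.mu_full_conditional(values, np.array([1.0]), spec)
        assert mu_mean[0] == pytest.approx(2.5, abs=1e-4)

    def test_inverse_gamma_bookkeeping(self):
        spec = irt.IrtModelSpec(hyper_tau_shape=2.0, hyper_tau_scale=1.0)
        values = np.full((1, 4), 1.7)
        shape, scale = irt.tau2_full_conditional(values, np.array([1.7]), spec)
        assert shape == pytest.approx(2.0 + 2.0, abs=1e-12)  # 2 + K/2, K=4
        assert scale[0] == pytest.approx(1.0, abs=1e-12)  # zero residual SS

    def test_mu_update_matches_grid_oracle(self):
        spec = irt.IrtModelSpec(prior_loc_sd=2.0)
        values = np.array([[0.4, 1.2, -0.3, 0.9]])
        tau2 = np.array([0.6])
        mu_mean, mu_var = irt.mu_full_conditional(values, tau2, spec)
        grid = np.linspace(-6, 6, 120001)
        loglik = -0.5 * ((values[0][:, None] - grid[None, :]) ** 2 / tau2[0]).sum(0)
        logprior = -0.5 * grid**2 / 4.0
        w = np.exp(loglik + logprior - (loglik + logprior).max())
        w /= w.sum()
        assert mu_mean[0] == pytest.approx((w * grid).sum(), abs=1e-6)
        assert mu_var[0] == pytest.approx((w * (grid - mu_mean[0]) ** 2).sum(), abs=1e-6)

    def test_sampled_hyper_moments(self):
        spec = irt.IrtModelSpec()
        values = np.array([[0.5, 1.5, 1.0, 2.0]])
        rng = RNG(10)
        mus = np.array(
            [irt.step_hyper(values, np.array([1.0]), spec, rng)[0][0] for _ in range(20000)]
        )
        m, v = irt.mu_full_conditional(values, np.array([1.0]), spec)
        assert mus.mean() == pytest.approx(m[0], abs=4 * np.sqrt(v[0] / 20000))


class TestGewekeJointConsistency:
    def test_successive_conditional_simulation_preserves_joint(self):
        """Geweke-style check: prior-predictive vs Gibbs-forward moments agree.

        Draw (alpha, beta, theta, X) from the generative joint repeatedly
        (marginal-conditional); separately run the full Gibbs cycle
        (utilities, theta, item regression + collapsed refresh) with X
        redrawn each sweep (successive-conditional). Both sample the same
        joint, so moments of test functions must agree within MC error.
        """
        N, J = 6, 2
        spec_sd = 1.0
        prov = np.zeros(N, int)
        pm = np.zeros(J)
        pv = np.full(J, spec_sd**2)
        rng = RNG(12)
        n_mc, n_sc = 6000, 30000

        def draw_prior(rng):
            alpha = rng.standard_normal((J, 1)) * spec_sd
            beta = truncnorm_onesided(np.zeros((J, 1)), np.ones((J, 1), bool), rng) * spec_sd
            theta = rng.standard_normal(N)
            return alpha, beta, theta

        def draw_data(alpha, beta, theta, rng):
            eta = alpha.T[prov] + beta.T[prov] * theta[:, None]
            return (eta + rng.standard_normal((N, J)) > 0).astype(float)

        g_mc = np.empty((n_mc, 4))
        for s in range(n_mc):
            alpha, beta, theta = draw_prior(rng)
            X = draw_data(alpha, beta, theta, rng)
            g_mc[s] = [alpha[0, 0], beta[1, 0], X.mean(), alpha[0, 0] * beta[0, 0]]

        g_sc = np.empty((n_sc, 4))
        alpha, beta, theta = draw_prior(rng)
        for s in range(n_sc):
            X = draw_data(alpha, beta, theta, rng)
            xs = irt.step_latent_utilities(X, alpha, beta, theta, prov, rng)
            theta = irt.step_theta(xs, alpha, beta, prov, rng)
            alpha, beta = irt.step_item_params(xs, theta, prov, pm, pv, pm, pv, beta, rng)
            alpha, beta = irt.refresh_item_params_collapsed(
                X, theta, prov, alpha, beta, pm, pv, pm, pv, rng
            )
            g_sc[s] = [alpha[0, 0], beta[1, 0], X.mean(), alpha[0, 0] * beta[0, 0]]

        for col in range(4):
            se = np.sqrt(
                g_mc[:, col].var() / n_mc + 10 * g_sc[:, col].var() / n_sc
            )
            assert abs(g_mc[:, col].mean() - g_sc[:, col].mean()) < 4 * se, col
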