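"""Likelihood closed forms, elliptical-slice-sampler correctness and
posterior summaries."""

import numpy as np
import pytest

import polrate as pr
from polrate.inference import ForwardModelConfig, forward_density


@pytest.fixture(scope="module")
def tiny_obs():
    """A small observation set generated by the forward model itself."""
    n = 20
    x = np.arange(float(n))
    p_tilde = np.full(n, 1.5)
    y_star = np.full(n, 0.4)
    cfg = ForwardModelConfig(p_max=3.0)
    obs0 = pr.ObservationSet(x=x, times=[5.0, 15.0], y=np.zeros((2, n)), y_star=y_star)
    rho = forward_density(obs0, p_tilde, 1.0, cfg)
    return pr.ObservationSet(x=x, times=[5.0, 15.0], y=rho, y_star=y_star), p_tilde, cfg


class TestLogLikelihood:
    def test_zero_residuals_leave_only_normalisation(self, tiny_obs):
        obs, p_tilde, cfg = tiny_obs
        f = pr.gp.latent_from_rates(p_tilde, cfg.p_max) if hasattr(pr, "gp") else None
        from polrate.gp import latent_from_rates

        f = latent_from_rates(p_tilde, cfg.p_max)
        sigma = 0.3
        theta = np.array([0.0, sigma, 1.0, 0.5, 5.0])
        ll = pr.log_likelihood(obs, f, theta, cfg)
        nt = obs.n_obs
        assert ll == pytest.approx(-0.5 * nt * np.log(2 * np.pi * sigma**2), rel=1e-9)

    def test_single_residual_closed_form(self, tiny_obs):
        obs, p_tilde, cfg = tiny_obs
        from polrate.gp import latent_from_rates

        f = latent_from_rates(p_tilde, cfg.p_max)
        sigma = 0.2
        theta = np.array([0.0, sigma, 1.0, 0.5, 5.0])
        ll0 = pr.log_likelihood(obs, f, theta, cfg)
        # perturb one observation by r: log-lik drops by r^2 / (2 sigma^2)
        r = 0.07
        y = obs.y.copy()
        y[0, 3] += r
        obs_p = pr.ObservationSet(x=obs.x, times=obs.times, y=y, y_star=obs.y_star)
        ll1 = pr.log_likelihood(obs_p, f, theta, cfg)
        assert ll0 - ll1 == pytest.approx(r**2 / (2 * sigma**2), rel=1e-6)

    def test_doubling_sigma_scales_terms_predictably(self, tiny_obs):
        obs, p_tilde, cfg = tiny_obs
        from polrate.gp import latent_from_rates

        f = latent_from_rates(p_tilde, cfg.p_max) + 0.3  # nonzero residuals
        nt = obs.n_obs
        th1 = np.array([0.0, 0.1, 1.0, 0.5, 5.0])
        th2 = np.array([0.0, 0.2, 1.0, 0.5, 5.0])
        ll1 = pr.log_likelihood(obs, f, th1, cfg)
        ll2 = pr.log_likelihood(obs, f, th2, cfg)
        norm1 = -0.5 * nt * np.log(2 * np.pi * 0.1**2)
        norm2 = -0.5 * nt * np.log(2 * np.pi * 0.2**2)
        quad1 = ll1 - norm1
        quad2 = ll2 - norm2
        assert quad2 == pytest.approx(quad1 / 4.0, rel=1e-9)


class TestEllipticalSliceStep:
    def test_flat_likelihood_samples_the_prior(self, rng):
        x = np.zeros(3)
        draws = np.empty((10_000, 3))
        ll = 0.0
        for i in range(draws.shape[0]):
            x, ll, _ = pr.elliptical_slice_step(x, lambda _: 0.0, rng, cur_loglik=ll)
            draws[i] = x
        # Monte-Carlo error on mean ~ 1/sqrt(ESS); the chain correlates draws
        assert np.all(np.abs(draws.mean(axis=0)) < 0.08)
        assert np.all(np.abs(draws.var(axis=0) - 1.0) < 0.12)

    def test_conjugate_normal_posterior_recovered(self, rng):
        # prior N(0,1), likelihood N(y | x, s^2) with y = 0.8, s = 0.5
        y_obs, s = 0.8, 0.5
        post_var = 1.0 / (1.0 + 1.0 / s**2)
        post_mean = post_var * y_obs / s**2
        loglik = lambda x: -0.5 * (y_obs - x[0]) ** 2 / s**2
        x = np.zeros(1)
        ll = loglik(x)
        draws = np.empty(20_000)
        for i in range(draws.size):
            x, ll, _ = pr.elliptical_slice_step(x, loglik, rng, cur_loglik=ll)
            draws[i] = x[0]
        assert draws.mean() == pytest.approx(post_mean, abs=0.03)
        assert draws.var() == pytest.approx(post_var, abs=0.04)

    def test_bit_reproducible_per_seed(self):
        loglik = lambda x: -0.5 * np.sum(x**2)
        out = []
        for _ in range(2):
            rng = np.random.default_rng(123)
            x = np.ones(4)
            ll = loglik(x)
            for _ in range(50):
                x, ll, _ = pr.elliptical_slice_step(x, loglik, rng, cur_loglik=ll)
            out.append(x.copy())
        assert np.array_equal(out[0], out[1])

    def test_broken_likelihood_raises(self, rng):
        with pytest.raises(pr.ConvergenceError):
            pr.elliptical_slice_step(np.zeros(2), lambda _: -np.inf, rng, cur_loglik=0.0)


class TestRunMcmc:
    def test_near_noiseless_constant_rate_recovery(self):
        """With tiny noise and a constant true rate, the posterior median
        rate profile lands within 5% of truth across the lattice."""
        n = 40
        x = np.arange(float(n))
        p_true = np.full(n, 1.8)
        cfg = ForwardModelConfig(p_max=3.0)
        times = np.array([5.0, 15.0, 40.0])
        base = pr.ObservationSet(x=x, times=times, y=np.zeros((3, n)),
                                 y_star=np.full(n, 0.45))
        rho = forward_density(base, p_true, 1.0, cfg)
        obs = pr.ObservationSet(x=x, times=times, y=rho, y_star=base.y_star)
        spec = pr.default_hyperprior()
        s = pr.run_mcmc(obs, spec, 3.0, n_total=400, n_burn=150, seed=9)
        med = np.median(s.p_tilde_draws, axis=0)
        assert np.all(np.abs(med - p_true) / p_true < 0.05)

    def test_invalid_sizes_rejected(self, tiny_obs):
        obs, _, _ = tiny_obs
        with pytest.raises(pr.ParameterError):
            pr.run_mcmc(obs, pr.default_hyperprior(), 3.0, n_total=10, n_burn=10)

    def test_draw_bounds_and_shapes(self, tiny_obs):
        obs, _, _ = tiny_obs
        spec = pr.default_hyperprior()
        s = pr.run_mcmc(obs, spec, 3.0, n_total=40, n_burn=10, seed=2)
        assert s.f_draws.shape == (30, obs.x.size)
        assert s.theta_draws.shape == (30, 5)
        assert np.all(s.theta_draws > spec.theta_min)
        assert np.all(s.theta_draws < spec.theta_max)

    def test_save_load_roundtrip(self, tiny_obs, tmp_path):
        obs, _, _ = tiny_obs
        s = pr.run_mcmc(obs, pr.default_hyperprior(), 3.0, n_total=25, n_burn=5, seed=3)
        path = tmp_path / "post.npz"
        s.save(path)
        s2 = pr.PosteriorSamples.load(path)
        assert np.array_equal(s.f_draws, s2.f_draws)
        assert np.array_equal(s.theta_draws, s2.theta_draws)
        assert s2.theta_names == s.theta_names


class TestSummaries:
    def test_identical_draws_give_zero_width_intervals(self):
        f = np.tile(np.linspace(-1, 1, 8), (20, 1))
        th = np.tile([1.0, 0.1, 1.0, 0.5, 5.0], (20, 1))
        s = pr.PosteriorSamples(f, th, np.zeros(20), 0, 20, 0, p_max=3.0)
        rates_df, hyper_df = pr.summarize(s)
        assert np.allclose(rates_df["rate_lower"], rates_df["rate_upper"])
        assert np.allclose(hyper_df["lower"], hyper_df["upper"])

    def test_quantile_convention_on_1_to_100(self):
        draws = np.arange(1.0, 101.0)
        th = np.column_stack([draws] * 5)
        # keep theta inside the default box: scale down
        th = th / 1000.0 + np.array([0.0, 0.0, 0.85, 0.0, 0.0])
        f = np.zeros((100, 4))
        s = pr.PosteriorSamples(f, th, np.zeros(100), 0, 100, 0, p_max=3.0)
        _, hyper_df = pr.summarize(s)
        m = hyper_df.loc[hyper_df.parameter == "m", "median"].item()
        lo = hyper_df.loc[hyper_df.parameter == "m", "lower"].item()
        hi = hyper_df.loc[hyper_df.parameter == "m", "upper"].item()
        assert m == pytest.approx(50.5 / 1000)
        assert lo == pytest.approx(3.475 / 1000)
        assert hi == pytest.approx(97.525 / 1000)


class TestPosteriorPredictive:
    def test_zero_noise_single_draw_equals_forward_solution(self, tiny_obs):
        obs, p_tilde, cfg = tiny_obs
        from polrate.gp import latent_from_rates

        f = latent_from_rates(p_tilde, cfg.p_max)
        theta = np.array([0.5, 1e-12, 1.0, 0.5, 5.0])
        s = pr.PosteriorSamples(f[None, :], theta[None, :], np.zeros(1), 0, 1, 0,
                                p_max=cfg.p_max)
        pred = pr.posterior_predictive(s, obs, cfg, n_draws=1, seed=0)
        rho = forward_density(obs, p_tilde, 1.0, cfg)
        assert np.allclose(pred.density_median, rho, atol=1e-9)
        assert np.allclose(pred.density_lower, pred.density_upper, atol=1e-9)


def test_whitened_log_target_matches_direct_density(tiny_obs):
    """The whitened-coordinate target (data log-lik plus standard-normal
    log-priors) differs from the direct joint density of (f, theta) only by
    the constant Jacobian of the fixed linear maps."""
    from scipy.stats import norm

    from polrate.gp import GPHyper, kernel_cholesky, se_kernel_matrix, theta_from_xi

    from scipy.linalg import solve_triangular

    obs, p_tilde, cfg = tiny_obs
    spec = pr.default_hyperprior()
    rng = np.random.default_rng(0)
    for _ in range(5):
        eta = rng.standard_normal(obs.x.size)
        z = 0.3 * rng.standard_normal(5)
        xi = spec.mu_xi + spec.sigma_xi * z
        theta = theta_from_xi(xi, spec)
        K = se_kernel_matrix(obs.x, GPHyper(theta[0], theta[3], theta[4]))
        L = kernel_cholesky(K, theta[3])
        f = theta[0] + L @ eta
        ll = pr.log_likelihood(obs, f, theta, cfg)
        whitened = ll + norm.logpdf(eta).sum() + norm.logpdf(z).sum()
        r = solve_triangular(L, f - theta[0], lower=True)
        gp_term = (
            -0.5 * r @ r
            - np.sum(np.log(np.diag(L)))
            - 0.5 * f.size * np.log(2 * np.pi)
        )
        direct = ll + gp_term + norm.logpdf(xi, spec.mu_xi, spec.sigma_xi).sum()
        jacobian = np.sum(np.log(np.diag(L))) + 5 * np.log(spec.sigma_xi)
        assert whitened - direct == pytest.approx(jacobian, abs=1e-8)
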