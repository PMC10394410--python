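"""Posterior inference of the rate profile from time-course density data.

The observation model is ``kappa * y_ij = rho(x_i, t_j; f) + eps`` with
``eps ~ N(0, sigma_eps)``: read counts ``y`` are proportional to occupancy up
to an unknown inverse amplification factor ``kappa``, plus additive Gaussian
noise on the density scale.  ``rho`` is obtained by running the forward solver
of :mod:`polrate.hydro` with zero-influx boundaries from the initial condition
``rho(x, 0) = kappa * y_star(x)``, where ``y_star`` is the unperturbed
(pre-treatment) profile.

Sampling uses block Gibbs with elliptical slice sampling (ESS).  Both the
latent field and the five hierarchical parameters are updated in whitened
coordinates (``f = m + chol(K) eta`` with ``eta ~ N(0, I)``; ``xi = mu_xi +
sigma_xi z`` with ``z ~ N(0, I)``), which keeps the ESS normal-prior
requirement exact while the kernel hyperparameters move.  Optionally each
sweep interweaves a centred update of the hyperparameters (holding ``f``
fixed and treating the GP density of ``f`` as part of the slice target),
which restores hyperparameter mixing when the data pin the latent field; the
two updates target the same joint posterior.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.linalg import solve_triangular

from . import gp
from .exceptions import ConvergenceError, IntegrationError, ParameterError
from .hydro import BoundarySpec, SpatialGrid, integrate_density

__all__ = [
    "ObservationSet",
    "ForwardModelConfig",
    "PosteriorSamples",
    "log_likelihood",
    "elliptical_slice_step",
    "run_mcmc",
    "posterior_predictive",
    "summarize",
]

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass
class ObservationSet:
    """Read-scale profiles at a set of run-on times.

    Attributes
    ----------
    x : array of shape (n,)
        Observation positions, uniformly spaced (lattice units; one unit =
        one coverage bin).
    times : array of shape (t,)
        Run-on times (minutes), strictly increasing.
    y : array of shape (t, n)
        Post-treatment profiles; ``y[j, i]`` is the value at position ``x[i]``
        and time ``times[j]``.
    y_star : array of shape (n,)
        Unperturbed (pre-treatment) profile, used as the initial condition.
    bin_width : float
        Nucleotides per bin (metadata; the solver works in lattice units).
    gene_id : str
    """

    x: np.ndarray
    times: np.ndarray
    y: np.ndarray
    y_star: np.ndarray
    bin_width: float = 1.0
    gene_id: str = ""

    def __post_init__(self):
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.y = np.atleast_2d(np.asarray(self.y, dtype=float))
        self.y_star = np.atleast_1d(np.asarray(self.y_star, dtype=float))
        if self.y.shape != (self.times.size, self.x.size):
            raise ParameterError(
                f"y shape {self.y.shape} != (n_times, n_x) = "
                f"({self.times.size}, {self.x.size})"
            )
        if self.y_star.size != self.x.size:
            raise ParameterError("y_star length must match x")
        if np.any(self.y < 0) or np.any(self.y_star < 0):
            raise ParameterError("observations must be non-negative")
        if self.times.size > 1 and np.any(np.diff(self.times) <= 0):
            raise ParameterError("times must be strictly increasing")
        self._grid = SpatialGrid.from_positions(self.x)

    @property
    def grid(self) -> SpatialGrid:
        return self._grid

    @property
    def n_obs(self) -> int:
        return self.y.size


@dataclass
class ForwardModelConfig:
    """Forward-solver settings used inside the likelihood.

    The default time integrator is the second-order Heun scheme at the CFL
    step: likelihood evaluations dominate the MCMC cost, and second-order
    accuracy is far below the observation-noise scale.  Data generation in
    :mod:`polrate.simulate` uses a finer fourth-order configuration.
    """

    p_max: float = 3.0
    a: float = 1.0
    b: float = 0.0
    dt: float | None = None
    cfl: float = 0.5
    order: int = 2


def forward_density(
    obs: ObservationSet, p_tilde: np.ndarray, kappa: float, config: ForwardModelConfig
) -> np.ndarray:
    """Density ``rho(x_i, t_j)`` from the initial condition ``kappa y_star``.

    ``kappa y_star`` is clipped into [0, 1] (noise can push the rescaled
    pre-treatment profile marginally outside the physical range).
    """
    rho0 = np.clip(kappa * obs.y_star, 0.0, 1.0)
    fld = integrate_density(
        rho0,
        p_tilde,
        config.a,
        config.b,
        BoundarySpec.no_influx(),
        obs.times,
        dt=config.dt,
        cfl=config.cfl,
        order=config.order,
        grid=obs.grid,
    )
    return fld.rho


def log_likelihood(
    obs: ObservationSet, f: np.ndarray, theta: np.ndarray, config: ForwardModelConfig
) -> float:
    """Gaussian log-likelihood of the residuals ``kappa y - rho`` with std
    ``sigma_eps``, normalised over all ``n * t`` observations.

    Returns ``-inf`` (with a debug log) if the forward solve fails, so the
    state is simply rejected inside slice-sampling brackets.
    """
    theta = np.asarray(theta, dtype=float)
    sigma_eps, kappa = theta[1], theta[2]
    if sigma_eps <= 0 or kappa <= 0:
        return -np.inf
    p_tilde = gp.link_rates(f, config.p_max)
    try:
        rho = forward_density(obs, p_tilde, kappa, config)
    except IntegrationError as err:
        logger.debug("forward solve failed, rejecting state: %s", err)
        return -np.inf
    resid = kappa * obs.y - rho
    nt = resid.size
    return float(
        -0.5 * np.sum(resid**2) / sigma_eps**2
        - 0.5 * nt * (_LOG2PI + 2.0 * np.log(sigma_eps))
    )


def elliptical_slice_step(current, loglik_fn, rng, cur_loglik=None, max_shrink=100):
    """One elliptical-slice-sampling update for a standard-normal prior.

    Parameters
    ----------
    current : array
        Current state, whose prior (in these coordinates) is N(0, I).
    loglik_fn : callable
        Log-likelihood (every density factor except the N(0, I) prior).
    rng : numpy.random.Generator
    cur_loglik : float, optional
        Cached ``loglik_fn(current)``; computed if omitted.
    max_shrink : int
        Bracket-shrink budget; exhausting it indicates a broken likelihood.

    Returns
    -------
    (new_state, new_loglik, n_evals)
    """
    current = np.asarray(current, dtype=float)
    if cur_loglik is None:
        cur_loglik = loglik_fn(current)
    if not np.isfinite(cur_loglik):
        raise ConvergenceError("ESS requires a finite log-likelihood at the current state")
    nu = rng.standard_normal(current.shape)
    log_y = cur_loglik + np.log(rng.uniform())
    theta = rng.uniform(0.0, 2.0 * np.pi)
    lo, hi = theta - 2.0 * np.pi, theta
    n_evals = 0
    for _ in range(max_shrink):
        prop = current * np.cos(theta) + nu * np.sin(theta)
        ll = loglik_fn(prop)
        n_evals += 1
        if ll > log_y:
            return prop, ll, n_evals
        if theta < 0.0:
            lo = theta
        else:
            hi = theta
        theta = rng.uniform(lo, hi)
    raise ConvergenceError(
        f"ESS bracket shrank {max_shrink} times without acceptance; "
        "the likelihood is likely returning inconsistent values"
    )


@dataclass
class PosteriorSamples:
    """Kept MCMC draws of the latent field and hierarchical parameters."""

    f_draws: np.ndarray  # (n_kept, n)
    theta_draws: np.ndarray  # (n_kept, 5)
    log_posterior: np.ndarray  # (n_total,), whitened-coordinate log target
    seed: int
    n_total: int
    n_burn: int
    p_max: float
    theta_names: tuple = gp.HyperPriorSpec.names

    @property
    def n_kept(self) -> int:
        return self.f_draws.shape[0]

    @property
    def p_tilde_draws(self) -> np.ndarray:
        return gp.link_rates(self.f_draws, self.p_max)

    def save(self, path) -> None:
        np.savez_compressed(
            path,
            f_draws=self.f_draws,
            theta_draws=self.theta_draws,
            log_posterior=self.log_posterior,
            seed=self.seed,
            n_total=self.n_total,
            n_burn=self.n_burn,
            p_max=self.p_max,
            theta_names=np.asarray(self.theta_names),
        )

    @classmethod
    def load(cls, path) -> "PosteriorSamples":
        with np.load(path, allow_pickle=False) as z:
            return cls(
                f_draws=z["f_draws"],
                theta_draws=z["theta_draws"],
                log_posterior=z["log_posterior"],
                seed=int(z["seed"]),
                n_total=int(z["n_total"]),
                n_burn=int(z["n_burn"]),
                p_max=float(z["p_max"]),
                theta_names=tuple(str(s) for s in z["theta_names"]),
            )


def _gp_logpdf(f, m, L):
    """log N(f; m, K) given the Cholesky factor L of K."""
    r = solve_triangular(L, f - m, lower=True)
    return float(
        -0.5 * r @ r - np.sum(np.log(np.diag(L))) - 0.5 * f.size * _LOG2PI
    )


def run_mcmc(
    obs: ObservationSet,
    spec: gp.HyperPriorSpec,
    p_max: float,
    n_total: int = 10_000,
    n_burn: int = 2_000,
    seed: int = 0,
    *,
    config: ForwardModelConfig | None = None,
    interweave: bool = True,
    n_latent_updates: int = 2,
    n_gp_hyper_updates: int = 3,
    fail_window: int = 500,
    progress: bool = False,
) -> PosteriorSamples:
    """Block-Gibbs ESS sampler for the joint posterior of (f, theta).

    Each sweep performs, in order: (i) ``n_latent_updates`` ESS updates of
    the whitened latent ``eta``; (ii) an ESS update of the whitened hyper
    vector ``z``; and, if ``interweave`` is set (default), (iii) centred ESS
    updates with the latent field held fixed: ``n_gp_hyper_updates`` of
    ``(m, sigma_f, l)`` against the GP density of ``f`` (these need no
    forward solves) followed by one of ``(sigma_eps, kappa)`` against the
    data.  The repeats cheaply decorrelate the weakly identified kernel
    hyperparameters.  Draw ``i >= n_burn`` of ``(f, theta)`` is stored after
    the sweep.

    Aborts if more than half of the forward solves fail within any
    ``fail_window`` consecutive sweeps.
    """
    if not (n_total > n_burn >= 0):
        raise ParameterError("need n_total > n_burn >= 0")
    config = config or ForwardModelConfig(p_max=p_max)
    if config.p_max != p_max:
        config = ForwardModelConfig(
            p_max=p_max, a=config.a, b=config.b, dt=config.dt, cfl=config.cfl,
            order=config.order,
        )
    rng = np.random.default_rng(seed)
    n = obs.x.size

    x_lat = obs.grid.x

    def chol_for(theta):
        hyper = gp.GPHyper(m=theta[0], sigma_f=theta[3], l=theta[4])
        K = gp.se_kernel_matrix(x_lat, hyper)
        return gp.kernel_cholesky(K, hyper.sigma_f)

    # deterministic start: box midpoints, flat latent field
    z = np.zeros(5)
    eta = np.zeros(n)
    xi = spec.mu_xi + spec.sigma_xi * z
    theta = gp.theta_from_xi(xi, spec)
    L = chol_for(theta)
    f = theta[0] + L @ eta

    n_evals = 0
    n_fail = 0

    def data_ll(f_, theta_):
        nonlocal n_evals, n_fail
        ll = log_likelihood(obs, f_, theta_, config)
        n_evals += 1
        if not np.isfinite(ll):
            n_fail += 1
        return ll

    ll_cur = data_ll(f, theta)
    if not np.isfinite(ll_cur):
        raise ConvergenceError("forward model fails at the initial state")

    n_kept = n_total - n_burn
    f_draws = np.empty((n_kept, n))
    theta_draws = np.empty((n_kept, 5))
    log_post = np.empty(n_total)

    window_evals = window_fails = 0

    for sweep in range(n_total):
        # --- block (i): whitened latent field ---
        def ll_eta(eta_):
            return data_ll(theta[0] + L @ eta_, theta)

        for _ in range(n_latent_updates):
            eta, ll_cur, _ = elliptical_slice_step(eta, ll_eta, rng, cur_loglik=ll_cur)
        f = theta[0] + L @ eta

        # --- block (ii): whitened hyperparameters ---
        cache = {}

        def ll_z(z_):
            theta_ = gp.theta_from_xi(spec.mu_xi + spec.sigma_xi * z_, spec)
            L_ = chol_for(theta_)
            f_ = theta_[0] + L_ @ eta
            ll = data_ll(f_, theta_)
            cache["state"] = (theta_, L_, f_, ll)
            return ll

        z, ll_cur, _ = elliptical_slice_step(z, ll_z, rng, cur_loglik=ll_cur)
        theta, L, f, ll_cur = cache["state"]

        # --- block (iii): centred hyperparameter updates, f held fixed ---
        # With f fixed the likelihood is flat in (m, sigma_f, l), so they are
        # updated against the GP density of f alone (no forward solves);
        # (sigma_eps, kappa) get their own ESS update against the data.
        if interweave:
            gp_idx = [0, 3, 4]  # m, sigma_f, l
            noise_idx = [1, 2]  # sigma_eps, kappa
            cache.clear()

            def ll_gp_sub(z_sub):
                z_ = z.copy()
                z_[gp_idx] = z_sub
                theta_ = gp.theta_from_xi(spec.mu_xi + spec.sigma_xi * z_, spec)
                L_ = chol_for(theta_)
                cache["state"] = (z_, theta_, L_)
                return _gp_logpdf(f, theta_[0], L_)

            for _ in range(n_gp_hyper_updates):
                cur = _gp_logpdf(f, theta[0], L)
                _, _, _ = elliptical_slice_step(
                    z[gp_idx], ll_gp_sub, rng, cur_loglik=cur
                )
                z, theta, L = cache["state"]

            cache.clear()

            def ll_noise_sub(z_sub):
                z_ = z.copy()
                z_[noise_idx] = z_sub
                theta_ = gp.theta_from_xi(spec.mu_xi + spec.sigma_xi * z_, spec)
                ll = data_ll(f, theta_)
                cache["state"] = (z_, theta_, ll)
                return ll

            _, _, _ = elliptical_slice_step(
                z[noise_idx], ll_noise_sub, rng, cur_loglik=ll_cur
            )
            z, theta, ll_cur = cache["state"]
            # re-whiten the (unchanged) latent field under the new kernel
            eta = solve_triangular(L, f - theta[0], lower=True)

        log_post[sweep] = ll_cur - 0.5 * (eta @ eta + z @ z)
        if sweep >= n_burn:
            f_draws[sweep - n_burn] = f
            theta_draws[sweep - n_burn] = theta

        if (sweep + 1) % fail_window == 0:
            frac = (n_fail - window_fails) / max(n_evals - window_evals, 1)
            if frac > 0.5:
                raise ConvergenceError(
                    f"{frac:.0%} of forward solves failed in the last "
                    f"{fail_window} sweeps; check rates/data scaling"
                )
            window_fails, window_evals = n_fail, n_evals
            logger.info(
                "sweep %d/%d log-lik %.2f theta %s",
                sweep + 1, n_total, ll_cur, np.array2string(theta, precision=3),
            )
        if progress and (sweep + 1) % max(n_total // 20, 1) == 0:
            print(f"  sweep {sweep + 1}/{n_total}  loglik {ll_cur:.2f}")

    return PosteriorSamples(
        f_draws=f_draws,
        theta_draws=theta_draws,
        log_posterior=log_post,
        seed=seed,
        n_total=n_total,
        n_burn=n_burn,
        p_max=p_max,
    )


@dataclass
class PredictiveSummary:
    """Pointwise posterior-predictive bands on the density scale plus rate
    bands; medians are equal-tailed quantile summaries over draws."""

    times: np.ndarray
    x: np.ndarray
    density_draws: np.ndarray  # (n_draws, t, n), includes observation noise
    density_median: np.ndarray  # (t, n)
    density_lower: np.ndarray
    density_upper: np.ndarray
    rate_median: np.ndarray  # (n,)
    rate_lower: np.ndarray
    rate_upper: np.ndarray


def posterior_predictive(
    samples: PosteriorSamples,
    obs: ObservationSet,
    config: ForwardModelConfig | None = None,
    *,
    n_draws: int = 200,
    seed: int = 0,
    density_level: float = 0.95,
    rate_level: float = 0.99,
) -> PredictiveSummary:
    """Forward-simulate kept draws and add observation noise.

    Draws are thinned deterministically (evenly spaced) from the kept chain;
    each is propagated through the forward model and perturbed with
    ``N(0, sigma_eps)`` noise on the density scale.  Bands are equal-tailed
    at ``density_level`` (density) and ``rate_level`` (rate profile).
    """
    if samples.n_kept == 0:
        raise ParameterError("no kept draws")
    config = config or ForwardModelConfig(p_max=samples.p_max)
    rng = np.random.default_rng(seed)
    idx = np.unique(
        np.linspace(0, samples.n_kept - 1, min(n_draws, samples.n_kept)).astype(int)
    )
    dens = np.empty((idx.size, obs.times.size, obs.x.size))
    for k, i in enumerate(idx):
        theta = samples.theta_draws[i]
        p_tilde = gp.link_rates(samples.f_draws[i], samples.p_max)
        rho = forward_density(obs, p_tilde, theta[2], config)
        noise = theta[1] * rng.standard_normal(rho.shape) if theta[1] > 0 else 0.0
        dens[k] = rho + noise
    alpha = 0.5 * (1.0 - density_level)
    rates = gp.link_rates(samples.f_draws, samples.p_max)
    beta = 0.5 * (1.0 - rate_level)
    return PredictiveSummary(
        times=obs.times.copy(),
        x=obs.x.copy(),
        density_draws=dens,
        density_median=np.median(dens, axis=0),
        density_lower=np.quantile(dens, alpha, axis=0),
        density_upper=np.quantile(dens, 1.0 - alpha, axis=0),
        rate_median=np.median(rates, axis=0),
        rate_lower=np.quantile(rates, beta, axis=0),
        rate_upper=np.quantile(rates, 1.0 - beta, axis=0),
    )


def summarize(samples: PosteriorSamples, *, rate_level: float = 0.99, hyper_level: float = 0.95):
    """Posterior summaries: per-position rate median with 99% CI and
    per-hyperparameter median with 95% CI (equal-tailed, linear-interpolation
    quantiles).

    Returns ``(rates_df, hyper_df)`` as pandas DataFrames.
    """
    import pandas as pd

    if samples.n_kept == 0:
        raise ParameterError("no kept draws")
    rates = samples.p_tilde_draws
    a = 0.5 * (1.0 - rate_level)
    rates_df = pd.DataFrame(
        {
            "position": np.arange(rates.shape[1]),
            "rate_median": np.median(rates, axis=0),
            "rate_lower": np.quantile(rates, a, axis=0),
            "rate_upper": np.quantile(rates, 1.0 - a, axis=0),
        }
    )
    b = 0.5 * (1.0 - hyper_level)
    th = samples.theta_draws
    hyper_df = pd.DataFrame(
        {
            "parameter": list(samples.theta_names),
            "median": np.median(th, axis=0),
            "lower": np.quantile(th, b, axis=0),
            "upper": np.quantile(th, 1.0 - b, axis=0),
        }
    )
    return rates_df, hyper_df
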