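"""Gaussian-process latent prior on the hop-rate profile.

The rate profile is modelled as ``p_tilde(x) = p_max * sigmoid(f(x))`` with a
latent field ``f ~ GP(m, k)`` under the squared-exponential kernel
``k(x, x') = sigma_f^2 exp(-(x-x')^2 / (2 l^2))``.  The sigmoid link keeps
rates smooth, positive and bounded above by ``p_max``.

The five hierarchical parameters ``theta = (m, sigma_eps, kappa, sigma_f, l)``
carry a scaled-sigmoid Gaussian prior: ``theta = theta_min +
(theta_max - theta_min) * sigmoid(xi)`` with ``xi ~ N(mu_xi, sigma_xi^2)``,
which confines the search to a box the practitioner deems plausible.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.special import expit, logit

from .exceptions import ConvergenceError, ParameterError
from .hydro import SpatialGrid

__all__ = [
    "GPHyper",
    "RateProfile",
    "HyperPriorSpec",
    "se_kernel_matrix",
    "kernel_cholesky",
    "link_rates",
    "latent_from_rates",
    "sample_rate_profile",
    "theta_from_xi",
    "xi_from_theta",
]

#: adaptive diagonal jitter ladder, as a fraction of sigma_f^2
_JITTER_START = 1e-10
_JITTER_MAX = 1e-6


@dataclass(frozen=True)
class GPHyper:
    """GP mean (latent scale), kernel amplitude and length-scale."""

    m: float
    sigma_f: float
    l: float

    def __post_init__(self):
        if not (self.sigma_f > 0):
            raise ParameterError("sigma_f must be positive")
        if not (self.l > 0):
            raise ParameterError("length-scale l must be positive")


def se_kernel_matrix(x, hyper: GPHyper) -> np.ndarray:
    """Squared-exponential covariance matrix on positions ``x`` (no jitter)."""
    x = np.asarray(x, dtype=float)
    d = x[:, None] - x[None, :]
    return hyper.sigma_f**2 * np.exp(-0.5 * (d / hyper.l) ** 2)


def kernel_cholesky(K: np.ndarray, sigma_f: float) -> np.ndarray:
    """Lower Cholesky factor with an adaptive diagonal jitter.

    Jitter starts at ``1e-10 sigma_f^2`` and doubles up to ``1e-6 sigma_f^2``
    before giving up; the first attempt is jitter-free.
    """
    n = K.shape[0]
    try:
        return np.linalg.cholesky(K)
    except np.linalg.LinAlgError:
        pass
    jitter = _JITTER_START * sigma_f**2
    while jitter <= _JITTER_MAX * sigma_f**2:
        try:
            return np.linalg.cholesky(K + jitter * np.eye(n))
        except np.linalg.LinAlgError:
            jitter *= 2.0
    raise ConvergenceError(
        f"Cholesky failed even with jitter {jitter / 2:g} "
        f"(sigma_f={sigma_f:g}, n={n})"
    )


def link_rates(f, p_max: float) -> np.ndarray:
    """Sigmoid link ``p_tilde = p_max / (1 + exp(-f))``; range (0, p_max)."""
    if not (p_max > 0):
        raise ParameterError("p_max must be positive")
    return p_max * expit(np.asarray(f, dtype=float))


def latent_from_rates(p_tilde, p_max: float) -> np.ndarray:
    """Inverse link; requires rates strictly inside (0, p_max)."""
    p_tilde = np.asarray(p_tilde, dtype=float)
    if np.any(p_tilde <= 0) or np.any(p_tilde >= p_max):
        raise ParameterError("rates must lie strictly inside (0, p_max)")
    return logit(p_tilde / p_max)


@dataclass
class RateProfile:
    """Latent GP values on a grid together with the linked hop rates."""

    grid: SpatialGrid
    f: np.ndarray
    p_max: float

    def __post_init__(self):
        self.f = np.atleast_1d(np.asarray(self.f, dtype=float))
        if self.f.size != self.grid.n:
            raise ParameterError("latent vector length must match the grid")
        if not (self.p_max > 0):
            raise ParameterError("p_max must be positive")

    @property
    def p_tilde(self) -> np.ndarray:
        return link_rates(self.f, self.p_max)


def sample_rate_profile(
    grid: SpatialGrid, hyper: GPHyper, p_max: float, seed
) -> RateProfile:
    """Draw ``f ~ N(m, K)`` on the grid and return the linked rate profile.

    ``seed`` may be an int or a :class:`numpy.random.Generator`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    K = se_kernel_matrix(grid.x, hyper)
    L = kernel_cholesky(K, hyper.sigma_f)
    f = hyper.m + L @ rng.standard_normal(grid.n)
    return RateProfile(grid=grid, f=f, p_max=p_max)


_THETA_NAMES = ("m", "sigma_eps", "kappa", "sigma_f", "l")


@dataclass
class HyperPriorSpec:
    """Box bounds and Gaussian hyper-prior for theta = (m, sigma_eps, kappa,
    sigma_f, l).

    ``sigma_xi`` is treated as the standard deviation of the latent Gaussian
    ``xi``; at the default ``(mu_xi, sigma_xi) = (0, 1)`` the std-vs-precision
    reading of the scale parameter is immaterial.
    """

    theta_min: np.ndarray
    theta_max: np.ndarray
    mu_xi: float = 0.0
    sigma_xi: float = 1.0

    names = _THETA_NAMES

    def __post_init__(self):
        self.theta_min = np.atleast_1d(np.asarray(self.theta_min, dtype=float))
        self.theta_max = np.atleast_1d(np.asarray(self.theta_max, dtype=float))
        if self.theta_min.size != 5 or self.theta_max.size != 5:
            raise ParameterError("theta bounds must be 5-vectors (m, sigma_eps, kappa, sigma_f, l)")
        if np.any(self.theta_min >= self.theta_max):
            raise ParameterError("theta_min must be < theta_max elementwise")
        if not (self.sigma_xi > 0):
            raise ParameterError("sigma_xi must be positive")

    def index(self, name: str) -> int:
        return _THETA_NAMES.index(name)

    @classmethod
    def from_file(cls, path) -> "HyperPriorSpec":
        """Read bounds from a plain-text ``key = value`` config.

        Recognised keys: ``theta_min``, ``theta_max`` (comma-separated
        5-vectors), ``mu_xi``, ``sigma_xi``; also per-parameter forms such as
        ``kappa_min = 0.8``.
        """
        from .simulate import default_hyperprior

        spec = default_hyperprior()
        tmin = spec.theta_min.copy()
        tmax = spec.theta_max.copy()
        mu_xi, sigma_xi = spec.mu_xi, spec.sigma_xi
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ParameterError(f"malformed config line: {raw!r}")
            key, val = (s.strip() for s in line.split("=", 1))
            if key == "theta_min":
                tmin = np.array([float(v) for v in val.split(",")])
            elif key == "theta_max":
                tmax = np.array([float(v) for v in val.split(",")])
            elif key == "mu_xi":
                mu_xi = float(val)
            elif key == "sigma_xi":
                sigma_xi = float(val)
            elif key.endswith("_min") and key[:-4] in _THETA_NAMES:
                tmin[_THETA_NAMES.index(key[:-4])] = float(val)
            elif key.endswith("_max") and key[:-4] in _THETA_NAMES:
                tmax[_THETA_NAMES.index(key[:-4])] = float(val)
            else:
                raise ParameterError(f"unknown config key {key!r}")
        return cls(theta_min=tmin, theta_max=tmax, mu_xi=mu_xi, sigma_xi=sigma_xi)


def theta_from_xi(xi, spec: HyperPriorSpec) -> np.ndarray:
    """Scaled-sigmoid map from the latent Gaussian xi to the bounded theta."""
    xi = np.asarray(xi, dtype=float)
    return spec.theta_min + (spec.theta_max - spec.theta_min) * expit(xi)


def xi_from_theta(theta, spec: HyperPriorSpec) -> np.ndarray:
    """Inverse of :func:`theta_from_xi`; theta must be strictly inside the box."""
    theta = np.asarray(theta, dtype=float)
    u = (theta - spec.theta_min) / (spec.theta_max - spec.theta_min)
    if np.any(u <= 0.0) or np.any(u >= 1.0):
        raise ParameterError("theta must lie strictly inside (theta_min, theta_max)")
    return logit(u)
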