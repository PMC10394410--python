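"""Hydrodynamic-limit forward model for driven lattice transport.

In the continuum limit the expected occupancy ``rho(x, t)`` of the exclusion
process obeys the conservation law

    d(rho)/dt = -d/dx [ lambda(x) rho (1 - rho) - nu(x) d(rho)/dx ],

where ``lambda = p_tilde (1 - b)`` is the net drive and
``nu = (a/2) p_tilde (1 + b)`` the diffusion induced by the finite lattice
spacing ``a``; ``p_tilde`` is the (spatially varying) forward hop-rate profile
and ``b`` in [0, 1) the backward-to-forward rate ratio.

The solver is a conservative method-of-lines scheme: interface fluxes use the
discrete two-point product form ``p~ rho_left (1 - rho_right) - q~ rho_right
(1 - rho_left)``, whose Taylor expansion is exactly the advection-diffusion
flux above, and which at ``a = 1`` makes the scheme identical (up to time
discretisation) to the mean-field lattice ODEs of :mod:`polrate.lattice`.
Time stepping is explicit Runge--Kutta (Heun or classical RK4) under a CFL
guard.

Boundary conditions are ghost-cell reservoirs: ``fixed-density`` couples the
end cell to a reservoir at a prescribed density (used to build the
non-equilibrium stationary state, NESS), ``zero-influx`` removes the incoming
interface flux while keeping the free outgoing one (the continuum analogue of
blocked initiation after triptolide treatment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
import pandas as pd

from .exceptions import ConvergenceError, IntegrationError, InvalidStateError, ParameterError

__all__ = [
    "SpatialGrid",
    "DensityField",
    "TransportCoefficients",
    "BoundarySpec",
    "transport_coefficients",
    "flux",
    "integrate_density",
    "find_ness",
    "run_depletion",
]

_BC_FIXED = 0
_BC_ZERO_INFLUX = 1
_BOUND_TOL = 1e-9


@dataclass(frozen=True)
class SpatialGrid:
    """Uniform 1-D discretisation of a gene body / lattice.

    ``x[i] = x0 + i*a`` are cell positions, ``L = n*a`` the domain length.
    Lengths are in lattice units (one unit = one site; for genomic data one
    site = one coverage bin).
    """

    n: int
    a: float = 1.0
    x0: float = 0.0

    def __post_init__(self):
        if self.n < 3:
            raise ParameterError(f"grid needs n >= 3 points, got {self.n}")
        if not (self.a > 0):
            raise ParameterError("grid spacing a must be positive")

    @property
    def x(self) -> np.ndarray:
        return self.x0 + self.a * np.arange(self.n)

    @property
    def L(self) -> float:
        return self.n * self.a

    @classmethod
    def from_positions(cls, x, rel_tol: float = 1e-12) -> "SpatialGrid":
        """Build a grid from explicit positions, checking uniform spacing."""
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ParameterError("need at least 3 positions")
        dx = np.diff(x)
        a = float(dx.mean())
        if a <= 0 or np.max(np.abs(dx - a)) > rel_tol * max(abs(a), 1.0) * x.size:
            raise ParameterError("positions are not uniformly increasing")
        return cls(n=x.size, a=a, x0=float(x[0]))


@dataclass
class DensityField:
    """Occupancy density ``rho(x_i, t_j)`` on a grid at a set of times."""

    grid: SpatialGrid
    times: np.ndarray
    rho: np.ndarray  # shape (n_times, n)

    def __post_init__(self):
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.rho = np.atleast_2d(np.asarray(self.rho, dtype=float))
        if self.rho.shape != (self.times.size, self.grid.n):
            raise InvalidStateError(
                f"rho shape {self.rho.shape} != (n_times, n) = "
                f"({self.times.size}, {self.grid.n})"
            )
        if self.rho.min() < -_BOUND_TOL or self.rho.max() > 1.0 + _BOUND_TOL:
            raise InvalidStateError("density outside [0,1] beyond tolerance")
        self.rho = np.clip(self.rho, 0.0, 1.0)

    def total_mass(self) -> np.ndarray:
        """Total particle number ``sum_i rho_i * a`` at each time."""
        return self.rho.sum(axis=1) * self.grid.a

    def to_frame(self) -> pd.DataFrame:
        """Tidy (x, t, rho) table."""
        x = self.grid.x
        recs = {
            "x": np.tile(x, self.times.size),
            "t": np.repeat(self.times, self.grid.n),
            "rho": self.rho.ravel(),
        }
        return pd.DataFrame(recs)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def save(self, path, key: str = "") -> None:
        """Binary (npz) container, optionally keyed by a gene/config id."""
        np.savez_compressed(
            path, key=np.asarray(key), times=self.times, rho=self.rho,
            n=self.grid.n, a=self.grid.a, x0=self.grid.x0,
        )

    @classmethod
    def load(cls, path) -> "DensityField":
        with np.load(path, allow_pickle=False) as z:
            grid = SpatialGrid(n=int(z["n"]), a=float(z["a"]), x0=float(z["x0"]))
            return cls(grid=grid, times=z["times"], rho=z["rho"])


@dataclass
class TransportCoefficients:
    """Drive ``lambda(x)`` and diffusion ``nu(x)`` fields.

    Their ratio ``nu/lambda = (a/2)(1+b)/(1-b)`` is constant in x.
    """

    lam: np.ndarray
    nu: np.ndarray
    b: float

    def __post_init__(self):
        self.lam = np.atleast_1d(np.asarray(self.lam, dtype=float))
        self.nu = np.atleast_1d(np.asarray(self.nu, dtype=float))
        if np.any(self.lam < 0) or np.any(self.nu < 0):
            raise ParameterError("transport coefficients must be non-negative")


@dataclass(frozen=True)
class BoundarySpec:
    """Boundary condition at the two domain ends.

    ``kind_*`` is ``"fixed-density"`` (reservoir at ``value_*``) or
    ``"zero-influx"`` (no incoming flux, free outgoing flux).
    """

    kind_left: str = "fixed-density"
    kind_right: str = "fixed-density"
    value_left: float = 0.5
    value_right: float = 0.5

    _KINDS = ("fixed-density", "zero-influx")

    def __post_init__(self):
        for kind in (self.kind_left, self.kind_right):
            if kind not in self._KINDS:
                raise ParameterError(f"unknown boundary kind {kind!r}")
        for v in (self.value_left, self.value_right):
            if not (0.0 <= v <= 1.0):
                raise ParameterError("boundary densities must lie in [0,1]")

    @classmethod
    def ness(cls, rho_left: float = 0.5, rho_right: float = 0.5) -> "BoundarySpec":
        return cls("fixed-density", "fixed-density", rho_left, rho_right)

    @classmethod
    def no_influx(cls) -> "BoundarySpec":
        return cls("zero-influx", "zero-influx", 0.0, 0.0)

    def _codes(self):
        code = {"fixed-density": _BC_FIXED, "zero-influx": _BC_ZERO_INFLUX}
        return (
            code[self.kind_left],
            code[self.kind_right],
            float(self.value_left),
            float(self.value_right),
        )


def transport_coefficients(p_tilde, a: float, b: float) -> TransportCoefficients:
    """Transport coefficients from the rate profile.

    ``lambda = p_tilde (1-b)``; ``nu = (a/2) p_tilde (1+b)``.
    """
    p_tilde = np.atleast_1d(np.asarray(p_tilde, dtype=float))
    if not (0.0 <= b < 1.0):
        raise ParameterError(f"asymmetry b must lie in [0,1), got {b}")
    if np.any(p_tilde < 0):
        raise ParameterError("rates must be non-negative")
    return TransportCoefficients(
        lam=p_tilde * (1.0 - b), nu=0.5 * a * p_tilde * (1.0 + b), b=float(b)
    )


def flux(rho_slice, coeffs: TransportCoefficients, grid: SpatialGrid) -> np.ndarray:
    """Advection-diffusion flux ``J = lam rho (1-rho) - nu d(rho)/dx`` at the
    ``n-1`` interior cell interfaces (midpoint densities and coefficients,
    central gradient)."""
    rho = np.asarray(rho_slice, dtype=float)
    if rho.min() < -_BOUND_TOL or rho.max() > 1.0 + _BOUND_TOL:
        raise InvalidStateError("density outside [0,1]")
    rho_m = 0.5 * (rho[:-1] + rho[1:])
    lam_m = 0.5 * (coeffs.lam[:-1] + coeffs.lam[1:])
    nu_m = 0.5 * (coeffs.nu[:-1] + coeffs.nu[1:])
    grad = np.diff(rho) / grid.a
    return lam_m * rho_m * (1.0 - rho_m) - nu_m * grad


@nb.njit(cache=True, fastmath=True)
def _scheme_flux(rho, p, b, lk, lv, rk, rv, J):  # pragma: no cover - jitted
    """Interface fluxes in the discrete product form (rate units p_tilde)."""
    n = rho.shape[0]
    for k in range(1, n):
        J[k] = p[k - 1] * rho[k - 1] * (1.0 - rho[k]) - b * p[k] * rho[k] * (
            1.0 - rho[k - 1]
        )
    if lk == _BC_FIXED:
        J[0] = p[0] * (lv * (1.0 - rho[0]) - b * rho[0] * (1.0 - lv))
    else:  # zero influx, free backward exit
        J[0] = -b * p[0] * rho[0]
    if rk == _BC_FIXED:
        J[n] = p[n - 1] * (rho[n - 1] * (1.0 - rv) - b * rv * (1.0 - rho[n - 1]))
    else:  # zero influx, free forward exit
        J[n] = p[n - 1] * rho[n - 1]


@nb.njit(cache=True, fastmath=True)
def _scheme_rhs(rho, p, a, b, lk, lv, rk, rv, J, out):  # pragma: no cover
    _scheme_flux(rho, p, b, lk, lv, rk, rv, J)
    n = rho.shape[0]
    for i in range(n):
        out[i] = (J[i] - J[i + 1]) / a


@nb.njit(cache=True, fastmath=True)
def _integrate_core(
    rho0, p, a, b, lk, lv, rk, rv, times, dt, order, out
):  # pragma: no cover - jitted
    n = rho0.shape[0]
    rho = rho0.copy()
    J = np.empty(n + 1)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    tmp = np.empty(n)
    t = 0.0
    j0 = 0
    if times[0] == 0.0:
        for i in range(n):
            out[0, i] = rho[i]
        j0 = 1
    for j in range(j0, times.size):
        tend = times[j]
        while t < tend - 1e-12:
            h = dt
            if t + h > tend:
                h = tend - t
            _scheme_rhs(rho, p, a, b, lk, lv, rk, rv, J, k1)
            if order == 2:
                for i in range(n):
                    tmp[i] = rho[i] + h * k1[i]
                _scheme_rhs(tmp, p, a, b, lk, lv, rk, rv, J, k2)
                for i in range(n):
                    rho[i] += 0.5 * h * (k1[i] + k2[i])
            else:
                for i in range(n):
                    tmp[i] = rho[i] + 0.5 * h * k1[i]
                _scheme_rhs(tmp, p, a, b, lk, lv, rk, rv, J, k2)
                for i in range(n):
                    tmp[i] = rho[i] + 0.5 * h * k2[i]
                _scheme_rhs(tmp, p, a, b, lk, lv, rk, rv, J, k3)
                for i in range(n):
                    tmp[i] = rho[i] + h * k3[i]
                _scheme_rhs(tmp, p, a, b, lk, lv, rk, rv, J, k4)
                for i in range(n):
                    rho[i] += h / 6.0 * (k1[i] + 2.0 * k2[i] + 2.0 * k3[i] + k4[i])
            t += h
        for i in range(n):
            out[j, i] = rho[i]


def _cfl_dt(p_tilde: np.ndarray, a: float, b: float, cfl: float) -> float:
    pmax = float(np.max(p_tilde))
    if pmax <= 0:
        return 1.0
    # outflow rate from a cell is bounded by 2 * pmax * (1+b) / a
    return cfl * a / (2.0 * pmax * (1.0 + b))


def _validated_rho0(rho0) -> np.ndarray:
    rho0 = np.atleast_1d(np.asarray(rho0, dtype=float))
    if not np.all(np.isfinite(rho0)):
        raise InvalidStateError("initial density contains non-finite values")
    if rho0.min() < -_BOUND_TOL or rho0.max() > 1.0 + _BOUND_TOL:
        raise InvalidStateError("initial density outside [0,1]")
    return np.clip(rho0, 0.0, 1.0)


def integrate_density(
    rho0,
    p_tilde,
    a: float,
    b: float,
    boundary: BoundarySpec,
    times,
    *,
    dt: float | None = None,
    cfl: float = 0.5,
    order: int = 4,
    grid: SpatialGrid | None = None,
) -> DensityField:
    """Integrate the nonlinear density conservation law.

    Parameters
    ----------
    rho0 : array of shape (n,)
        Initial density on the grid, in [0, 1].
    p_tilde : array of shape (n,)
        Forward rate profile on the grid (rate units; hop rates are
        ``p_tilde / a``).
    a, b : float
        Lattice spacing and backward/forward asymmetry.
    boundary : BoundarySpec
    times : increasing array starting at >= 0
        Output times (integration always starts at t = 0).
    dt : float, optional
        Fixed time step; defaults to the CFL-guarded value
        ``cfl * a / (2 p_max (1+b))``.  Smaller values trade speed for
        temporal accuracy.
    order : {2, 4}
        Runge--Kutta order (Heun or classical RK4).
    """
    rho0 = _validated_rho0(rho0)
    p_tilde = np.atleast_1d(np.asarray(p_tilde, dtype=float))
    if p_tilde.size != rho0.size:
        raise ParameterError("p_tilde and rho0 must have equal length")
    if np.any(p_tilde < 0) or not np.all(np.isfinite(p_tilde)):
        raise ParameterError("rates must be finite and non-negative")
    if not (0.0 <= b < 1.0):
        raise ParameterError(f"asymmetry b must lie in [0,1), got {b}")
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if np.any(times < 0) or (times.size > 1 and np.any(np.diff(times) <= 0)):
        raise ParameterError("times must be non-negative and strictly increasing")
    if order not in (2, 4):
        raise ParameterError("order must be 2 or 4")
    if grid is None:
        grid = SpatialGrid(n=rho0.size, a=a)
    if dt is None:
        dt = _cfl_dt(p_tilde, a, b, cfl)
    elif dt <= 0:
        raise ParameterError("dt must be positive")
    lk, rk_, lv, rv = boundary._codes()
    out = np.empty((times.size, rho0.size))
    _integrate_core(rho0, p_tilde, float(a), float(b), lk, lv, rk_, rv, times, float(dt), order, out)
    if not np.all(np.isfinite(out)):
        raise IntegrationError("non-finite density produced; reduce dt")
    if out.min() < -_BOUND_TOL or out.max() > 1.0 + _BOUND_TOL:
        raise IntegrationError(
            f"density left [0,1] (min={out.min():g}, max={out.max():g}); "
            "the CFL guard was overridden too aggressively"
        )
    return DensityField(grid=grid, times=times, rho=np.clip(out, 0.0, 1.0))


def scheme_interface_flux(rho, p_tilde, b: float, boundary: BoundarySpec) -> np.ndarray:
    """The solver's own interface fluxes (n+1 values including boundaries)."""
    rho = np.asarray(rho, dtype=float)
    p_tilde = np.asarray(p_tilde, dtype=float)
    J = np.empty(rho.size + 1)
    lk, rk_, lv, rv = boundary._codes()
    _scheme_flux(rho, p_tilde, float(b), lk, lv, rk_, rv, J)
    return J


@dataclass
class NessResult:
    """Stationary profile with convergence diagnostics."""

    rho_star: np.ndarray
    flux_star: np.ndarray  # interface fluxes, length n+1
    residual: float  # max |d(rho)/dt| at rho_star
    t_elapsed: float

    @property
    def mean_flux(self) -> float:
        return float(self.flux_star.mean())


def find_ness(
    p_tilde,
    a: float,
    b: float,
    boundary: BoundarySpec,
    rho_init,
    *,
    tol: float = 1e-8,
    t_block: float = 50.0,
    max_t: float = 2e5,
    n_consecutive: int = 3,
    dt: float | None = None,
    order: int = 4,
) -> NessResult:
    """Relax to the non-equilibrium stationary state by long-time integration.

    Integrates with fixed-density boundaries in blocks of ``t_block`` until
    ``max |d(rho)/dt|`` stays below ``tol`` for ``n_consecutive`` consecutive
    checkpoints (robust to slow transients through bottlenecks).  Raises
    :class:`ConvergenceError` carrying the residual trajectory on failure.
    """
    if boundary.kind_left != "fixed-density" or boundary.kind_right != "fixed-density":
        raise ParameterError("NESS computation requires fixed-density boundaries")
    rho = _validated_rho0(rho_init)
    p_tilde = np.atleast_1d(np.asarray(p_tilde, dtype=float))
    residual_traj = []
    t = 0.0
    hits = 0
    while t < max_t:
        fld = integrate_density(
            rho, p_tilde, a, b, boundary, np.array([0.0, t_block]), dt=dt, order=order
        )
        rho = fld.rho[-1]
        t += t_block
        res = float(np.max(np.abs(_rhs_once(rho, p_tilde, a, b, boundary))))
        residual_traj.append(res)
        hits = hits + 1 if res < tol else 0
        if hits >= n_consecutive:
            J = scheme_interface_flux(rho, p_tilde, b, boundary)
            return NessResult(rho_star=rho, flux_star=J, residual=res, t_elapsed=t)
    raise ConvergenceError(
        f"NESS not reached within t={max_t:g} (last residual {residual_traj[-1]:.3g})",
        diagnostics=np.asarray(residual_traj),
    )


def _rhs_once(rho, p_tilde, a, b, boundary: BoundarySpec) -> np.ndarray:
    lk, rk_, lv, rv = boundary._codes()
    J = np.empty(rho.size + 1)
    out = np.empty(rho.size)
    _scheme_rhs(
        np.asarray(rho, float), np.asarray(p_tilde, float), float(a), float(b),
        lk, lv, rk_, rv, J, out,
    )
    return out


def run_depletion(
    rho_star,
    p_tilde,
    a: float,
    b: float,
    obs_times,
    *,
    dt: float | None = None,
    order: int = 4,
) -> DensityField:
    """Deplete a stationary profile with blocked influx.

    Starting from ``rho_star``, integrates with zero-influx boundaries at
    both ends (initiation blocked, exits free), mimicking the evolution of
    the polymerase profile after triptolide treatment.  Density near the
    left boundary decreases as the lattice drains.
    """
    boundary = BoundarySpec.no_influx()
    return integrate_density(
        rho_star, p_tilde, a, b, boundary, obs_times, dt=dt, order=order
    )
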