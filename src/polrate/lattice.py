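"""Discrete mean-field dynamics of the asymmetric simple exclusion process.

A 1-D lattice of ``N`` sites with open boundaries hosts at most one particle
per site.  A particle at site ``i`` hops right with rate ``p_i`` (blocked if
``i+1`` is occupied) and left with rate ``q_i`` (blocked if ``i-1`` is
occupied).  Particles enter at the left boundary with rate ``p0`` and at the
right boundary with rate ``qN1``; they leave through the left end with rate
``q_1`` and through the right end with rate ``p_N`` (i.e. the first entry of
``q`` and the last entry of ``p`` double as exit rates).

Under the mean-field factorisation ``E(n_i n_j) ~ E(n_i) E(n_j)`` the expected
occupancies ``phi_i = E(n_i)`` obey a closed system of ODEs, implemented here.
The module also hosts an exact stochastic (Gillespie) simulator of the same
process, which serves as a validation oracle for the factorisation, and the
ODE system itself serves as the brute-force oracle for the continuum solver in
:mod:`polrate.hydro`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba as nb
import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import IntegrationError, InvalidStateError

__all__ = ["LatticeState", "meanfield_rhs", "integrate_meanfield", "gillespie_asep"]

#: occupancies within this distance of [0, 1] are clamped; larger excursions
#: are treated as errors rather than round-off.
CLIP_TOL = 1e-9


def _clamp_occupancy(phi: np.ndarray, tol: float = CLIP_TOL) -> np.ndarray:
    phi = np.asarray(phi, dtype=float)
    if not np.all(np.isfinite(phi)):
        raise InvalidStateError("occupancies contain non-finite values")
    if phi.min() < -tol or phi.max() > 1.0 + tol:
        raise InvalidStateError(
            f"occupancies outside [0,1] beyond tolerance {tol:g}: "
            f"min={phi.min():g}, max={phi.max():g}"
        )
    return np.clip(phi, 0.0, 1.0)


@dataclass
class LatticeState:
    """Expected occupancies plus the full set of hop/boundary rates.

    Parameters
    ----------
    phi : array of shape (N,)
        Expected occupancies ``phi_i`` in [0, 1].
    p : array of shape (N,)
        Forward hop rates; ``p[-1]`` is also the right exit rate.
    q : array of shape (N,)
        Backward hop rates; ``q[0]`` is also the left exit rate.
    p0 : float
        Left injection rate (into site 1 when empty).
    qN1 : float
        Right injection rate ``q_{N+1}`` (into site N when empty).
    """

    phi: np.ndarray
    p: np.ndarray
    q: np.ndarray
    p0: float = 0.0
    qN1: float = 0.0

    def __post_init__(self):
        self.phi = _clamp_occupancy(np.atleast_1d(np.asarray(self.phi, dtype=float)))
        self.p = np.atleast_1d(np.asarray(self.p, dtype=float))
        self.q = np.atleast_1d(np.asarray(self.q, dtype=float))
        n = self.phi.size
        if n < 3:
            raise InvalidStateError(f"need at least 3 sites, got {n}")
        if self.p.size != n or self.q.size != n:
            raise InvalidStateError("p, q and phi must have equal length")
        rates = np.concatenate([self.p, self.q, [self.p0, self.qN1]])
        if not np.all(np.isfinite(rates)) or np.any(rates < 0):
            raise InvalidStateError("all rates must be finite and non-negative")

    @property
    def n_sites(self) -> int:
        return self.phi.size


def meanfield_rhs(state: LatticeState, phi: np.ndarray | None = None) -> np.ndarray:
    """Time derivative ``d(phi)/dt`` of the mean-field occupancies.

    Bulk sites gain from hops in from both neighbours and lose through hops
    out to both neighbours, each hop blocked by the target's occupancy;
    boundary sites exchange particles with the reservoirs at the injection
    and exit rates.

    Parameters
    ----------
    state : LatticeState
    phi : array, optional
        Occupancies to evaluate at instead of ``state.phi`` (used by the ODE
        integrator; not re-validated).
    """
    if phi is None:
        phi = state.phi
    p, q = state.p, state.q
    if not np.all(np.isfinite(phi)):
        raise InvalidStateError("non-finite occupancy passed to meanfield_rhs")
    d = np.empty_like(phi)
    # bulk: gain from left/right neighbours, loss to left/right neighbours
    d[1:-1] = (
        p[:-2] * phi[:-2] * (1.0 - phi[1:-1])
        - p[1:-1] * phi[1:-1] * (1.0 - phi[2:])
        + q[2:] * phi[2:] * (1.0 - phi[1:-1])
        - q[1:-1] * phi[1:-1] * (1.0 - phi[:-2])
    )
    # left boundary: injection p0, exit q_1
    d[0] = (
        state.p0 * (1.0 - phi[0])
        - p[0] * phi[0] * (1.0 - phi[1])
        - q[0] * phi[0]
        + q[1] * phi[1] * (1.0 - phi[0])
    )
    # right boundary: exit p_N, injection q_{N+1}
    d[-1] = (
        p[-2] * phi[-2] * (1.0 - phi[-1])
        - p[-1] * phi[-1]
        + state.qN1 * (1.0 - phi[-1])
        - q[-1] * phi[-1] * (1.0 - phi[-2])
    )
    return d


def boundary_fluxes(state: LatticeState, phi: np.ndarray | None = None) -> tuple[float, float]:
    """Net particle flux entering at the left end and leaving at the right end.

    Returns ``(J_in_left, J_out_right)`` such that
    ``d/dt sum(phi) = J_in_left - J_out_right``.
    """
    if phi is None:
        phi = state.phi
    j_left = state.p0 * (1.0 - phi[0]) - state.q[0] * phi[0]
    j_right = state.p[-1] * phi[-1] - state.qN1 * (1.0 - phi[-1])
    return j_left, j_right


def integrate_meanfield(
    state0: LatticeState,
    t_grid,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    method: str = "RK45",
) -> np.ndarray:
    """Integrate the mean-field ODE system over ``t_grid``.

    Parameters
    ----------
    state0 : LatticeState
        Initial condition (rates are held fixed).
    t_grid : increasing array starting at 0
        Output times.
    rtol, atol : float
        Solver tolerances (adaptive explicit Runge--Kutta; the system is
        non-stiff for the rate magnitudes in scope).

    Returns
    -------
    ndarray of shape (len(t_grid), N)
        Occupancy snapshots; the first row equals ``state0.phi``.
    """
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    if t_grid[0] != 0.0:
        raise ValueError("t_grid must start at 0")
    if t_grid.size > 1 and np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    if t_grid.size == 1:
        return state0.phi[None, :].copy()

    sol = solve_ivp(
        lambda _t, y: meanfield_rhs(state0, y),
        (0.0, float(t_grid[-1])),
        state0.phi,
        t_eval=t_grid,
        method=method,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise IntegrationError(f"mean-field ODE solver failed: {sol.message}")
    out = sol.y.T
    return np.vstack([_clamp_occupancy(row) for row in out])


@nb.njit(cache=True)
def _nb_seed(seed):  # pragma: no cover - jitted
    # numba maintains its own RNG state; np.random.seed from the interpreter
    # does not touch it
    np.random.seed(seed)


@nb.njit(cache=True)
def _gillespie_core(p, q, p0, qN1, n0, t_grid, out):  # pragma: no cover - jitted
    n_sites = n0.size
    occ = n0.copy()
    t = 0.0
    ti = 0
    rates = np.empty(2 * n_sites + 2)
    while ti < t_grid.size:
        # event rates in the current configuration
        total = 0.0
        # 0: left injection, 1: right injection
        rates[0] = p0 if occ[0] == 0 else 0.0
        rates[1] = qN1 if occ[n_sites - 1] == 0 else 0.0
        total += rates[0] + rates[1]
        # 2..n_sites+1: forward hop/exit out of site i
        for i in range(n_sites):
            r = 0.0
            if occ[i] == 1:
                if i == n_sites - 1 or occ[i + 1] == 0:
                    r = p[i]
            rates[2 + i] = r
            total += r
        # n_sites+2 .. 2n_sites+1: backward hop/exit out of site i
        for i in range(n_sites):
            r = 0.0
            if occ[i] == 1:
                if i == 0 or occ[i - 1] == 0:
                    r = q[i]
            rates[2 + n_sites + i] = r
            total += r
        if total <= 0.0:
            # absorbing configuration: fill remaining snapshots
            while ti < t_grid.size:
                for i in range(n_sites):
                    out[ti, i] = occ[i]
                ti += 1
            break
        t_next = t + np.random.exponential(1.0 / total)
        while ti < t_grid.size and t_grid[ti] < t_next:
            for i in range(n_sites):
                out[ti, i] = occ[i]
            ti += 1
        t = t_next
        # select event
        u = np.random.random() * total
        acc = rates[0]
        ev = 0
        while acc < u and ev < 2 * n_sites + 1:
            ev += 1
            acc += rates[ev]
        if ev == 0:
            occ[0] = 1
        elif ev == 1:
            occ[n_sites - 1] = 1
        elif ev < 2 + n_sites:
            i = ev - 2
            occ[i] = 0
            if i < n_sites - 1:
                occ[i + 1] = 1
        else:
            i = ev - 2 - n_sites
            occ[i] = 0
            if i > 0:
                occ[i - 1] = 1


def gillespie_asep(
    state: LatticeState,
    n_replicas: int,
    t_grid,
    seed: int,
    *,
    init: str = "bernoulli",
) -> np.ndarray:
    """Stochastic exclusion-process simulation, averaged over replicas.

    Each replica starts from occupation numbers drawn independently as
    ``Bernoulli(phi_i)`` (``init="bernoulli"``) or from the empty lattice
    (``init="empty"``), then evolves by the exact event-driven algorithm.
    Snapshots are taken at ``t_grid`` and averaged element-wise over replicas.

    This is the validation oracle for the mean-field factorisation: it makes
    no independence assumption, so systematic differences from
    :func:`integrate_meanfield` quantify the factorisation error.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be >= 1")
    t_grid = np.atleast_1d(np.asarray(t_grid, dtype=float))
    rng = np.random.default_rng(seed)
    n = state.n_sites
    acc = np.zeros((t_grid.size, n))
    out = np.empty((t_grid.size, n))
    _nb_seed(int(rng.integers(0, 2**31 - 1)))
    for _ in range(n_replicas):
        if init == "bernoulli":
            n0 = (rng.random(n) < state.phi).astype(np.int64)
        elif init == "empty":
            n0 = np.zeros(n, dtype=np.int64)
        else:
            raise ValueError(f"unknown init {init!r}")
        _gillespie_core(state.p, state.q, state.p0, state.qN1, n0, t_grid, out)
        acc += out
    return acc / n_replicas
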