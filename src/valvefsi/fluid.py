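"""Weakly-compressible SPH fluid solver.

The blood phase is discretized as Lagrangian particles.  Density evolves
through the continuity equation written as a kernel sum over neighbour
pairs, momentum through the symmetric pressure-gradient term plus a
physical viscous term, and pressure closes the system through an
artificial (weakly-compressible) equation of state:

    drho_a/dt = sum_b m_b  v_ab . grad_a W_ab
    dv_a/dt   = - sum_b m_b (P_a + P_b)/(rho_a rho_b) grad_a W_ab
                + sum_b m_b (mu_a + mu_b) v_ab /(rho_a rho_b r_ab^2)
                  (r_ab . grad_a W_ab)

with ``v_ab = v_a - v_b`` and ``r_ab = r_a - r_b``.  Both pair terms are
antisymmetric, so internal forces conserve linear momentum exactly.

Rigid walls in the pure-fluid validation scenes are realized as frozen
("dummy") particles: they carry density and pressure and participate in
every kernel sum, but their kinematics are prescribed.  This transmits
hydrostatic load and an approximate no-slip condition to the fluid
without a mesh.  Deformable tissue surfaces couple through the penalty
contact module instead.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numba
import numpy as np
from scipy.spatial import cKDTree

from .kernels import KernelSpec, _dwdq_scalar, _w_scalar

logger = logging.getLogger(__name__)

__all__ = [
    "FluidState",
    "EquationOfState",
    "neighbor_search",
    "kernel_interpolate",
    "density_rate",
    "momentum_rate",
    "compute_rates",
    "density_rate_cached",
    "eos_pressure",
    "summation_density",
    "noslip_wall_velocity",
    "dummy_wall_pressure",
    "step_fluid",
]


# ---------------------------------------------------------------------------
# state containers


@dataclass
class FluidState:
    """The SPH particle system.

    All arrays are congruent along the first axis.  ``frozen`` marks
    boundary (dummy) particles whose motion is prescribed externally;
    they participate in all kernel sums but receive no acceleration.
    """

    pos: np.ndarray            # (n, dim) positions, m
    vel: np.ndarray            # (n, dim) velocities, m/s
    rho: np.ndarray            # (n,) densities, kg/m^3
    mass: np.ndarray           # (n,) masses, kg
    pressure: np.ndarray | None = None  # (n,) Pa
    mu: float = 0.0035         # dynamic viscosity, Pa s (blood default)
    frozen: np.ndarray | None = None    # (n,) bool

    def __post_init__(self) -> None:
        self.pos = np.ascontiguousarray(self.pos, dtype=float)
        self.vel = np.ascontiguousarray(self.vel, dtype=float)
        self.rho = np.ascontiguousarray(self.rho, dtype=float)
        self.mass = np.ascontiguousarray(self.mass, dtype=float)
        n = self.pos.shape[0]
        if self.pressure is None:
            self.pressure = np.zeros(n)
        self.pressure = np.ascontiguousarray(self.pressure, dtype=float)
        if self.frozen is None:
            self.frozen = np.zeros(n, dtype=bool)
        self.frozen = np.ascontiguousarray(self.frozen, dtype=bool)
        self.validate()

    @property
    def n(self) -> int:
        return self.pos.shape[0]

    @property
    def dim(self) -> int:
        return self.pos.shape[1]

    def validate(self) -> None:
        n = self.pos.shape[0]
        for name in ("vel", "rho", "mass", "pressure", "frozen"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"array '{name}' length {arr.shape[0]} != {n} particles")
        if self.vel.shape != self.pos.shape:
            raise ValueError("velocity array incongruent with positions")
        if np.any(self.mass <= 0.0):
            raise ValueError("all particle masses must be positive")
        if np.any(self.rho <= 0.0):
            raise ValueError("all particle densities must be positive")

    def copy(self) -> "FluidState":
        return FluidState(
            pos=self.pos.copy(), vel=self.vel.copy(), rho=self.rho.copy(),
            mass=self.mass.copy(), pressure=self.pressure.copy(), mu=self.mu,
            frozen=self.frozen.copy(),
        )

    def total_momentum(self) -> np.ndarray:
        return (self.mass[:, None] * self.vel).sum(axis=0)

    def total_mass(self) -> float:
        return float(self.mass.sum())


@dataclass(frozen=True)
class EquationOfState:
    """Artificial weakly-compressible pressure closure.

    ``kind='linear'`` gives ``P = c0^2 (rho - rho0)``; ``kind='tait'``
    gives the Tait form ``P = rho0 c0^2 / gamma ((rho/rho0)^gamma - 1)``.
    Both vanish at the reference density and have stiffness ``c0^2``
    there.  ``c0`` is an artificial sound speed, chosen ~10x the largest
    expected flow speed so density fluctuations stay around 1%.
    """

    rho0: float
    c0: float
    kind: str = "linear"
    gamma: float = 7.0

    def __post_init__(self) -> None:
        if self.c0 <= 0.0:
            raise ValueError("artificial sound speed c0 must be positive")
        if self.rho0 <= 0.0:
            raise ValueError("reference density must be positive")
        if self.kind not in ("linear", "tait"):
            raise ValueError(f"unknown EOS kind '{self.kind}'")

    def pressure(self, rho: np.ndarray | float) -> np.ndarray | float:
        rho = np.asarray(rho, dtype=float)
        if np.any(rho <= 0.0):
            raise ValueError("non-positive density: corrupted fluid state")
        if self.kind == "linear":
            return self.c0**2 * (rho - self.rho0)
        b = self.rho0 * self.c0**2 / self.gamma
        return b * ((rho / self.rho0) ** self.gamma - 1.0)


def eos_pressure(rho: np.ndarray | float, eos: EquationOfState) -> np.ndarray | float:
    """Pressure from density through the weakly-compressible EOS (Pa)."""
    return eos.pressure(rho)


# ---------------------------------------------------------------------------
# neighbour search


def neighbor_search(
    pos: np.ndarray, cutoff: float, periodic: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """All unordered particle pairs closer than ``cutoff`` (strict).

    Parameters
    ----------
    pos : (n, dim) array
    cutoff : float
        Interaction radius, normally ``2 h``.
    periodic : optional (dim,) array
        Per-axis period length; 0 (or None) marks a non-periodic axis.
        Minimum-image distances are used along periodic axes.

    Returns
    -------
    (i, j) : int arrays with i < j, sorted lexicographically.
    """
    pos = np.asarray(pos, dtype=float)
    if not np.all(np.isfinite(pos)):
        raise ValueError("non-finite particle coordinates")
    if pos.shape[0] < 2:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    if periodic is not None and np.any(np.asarray(periodic) > 0):
        periodic = np.asarray(periodic, dtype=float)
        shifted = pos.copy()
        boxsize = np.empty(pos.shape[1])
        for d in range(pos.shape[1]):
            if periodic[d] > 0:
                shifted[:, d] = np.mod(shifted[:, d], periodic[d])
                boxsize[d] = periodic[d]
            else:
                lo = shifted[:, d].min()
                shifted[:, d] -= lo
                boxsize[d] = shifted[:, d].max() + 10.0 * cutoff
        tree = cKDTree(shifted, boxsize=boxsize)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size:
            dr = _minimum_image(pos[pairs[:, 0]] - pos[pairs[:, 1]], periodic)
            keep = np.einsum("ij,ij->i", dr, dr) < cutoff**2
            pairs = pairs[keep]
    else:
        tree = cKDTree(pos)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if pairs.size:
            dr = pos[pairs[:, 0]] - pos[pairs[:, 1]]
            keep = np.einsum("ij,ij->i", dr, dr) < cutoff**2
            pairs = pairs[keep]
    if pairs.size == 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    order = np.lexsort((pairs[:, 1], pairs[:, 0]))
    pairs = pairs[order]
    return pairs[:, 0].astype(np.int64), pairs[:, 1].astype(np.int64)


def _minimum_image(dr: np.ndarray, periodic: np.ndarray | None) -> np.ndarray:
    if periodic is None:
        return dr
    dr = dr.copy()
    for d in range(dr.shape[-1]):
        if periodic[d] > 0:
            dr[..., d] -= periodic[d] * np.round(dr[..., d] / periodic[d])
    return dr


# ---------------------------------------------------------------------------
# numba pair kernels


@numba.njit(cache=True, fastmath=True)
def _accumulate_rates(
    pos, vel, velv, rho, mass, pres, mu2, pi, pj, h, sigma, box,
    c0, alpha_av, drho, acc, pair_grad,
):
    """Pair-loop for continuity and momentum rates.  Fills ``pair_grad``
    with grad_a W per pair (zero outside support) for reuse by the
    post-kick continuity pass.  Returns the number of coincident
    (guarded) pairs."""
    dim = pos.shape[1]
    inv_h = 1.0 / h
    eps_av = 0.01 * h * h
    n_coincident = 0
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        for d in range(dim):
            pair_grad[k, d] = 0.0
        r2 = 0.0
        dr = np.empty(dim)
        dv = np.empty(dim)
        dvv = np.empty(dim)
        for d in range(dim):
            x = pos[a, d] - pos[b, d]
            if box[d] > 0.0:
                x -= box[d] * np.round(x / box[d])
            dr[d] = x
            dv[d] = vel[a, d] - vel[b, d]
            dvv[d] = velv[a, d] - velv[b, d]
            r2 += x * x
        dist = np.sqrt(r2)
        if dist < 1e-14 * h:
            n_coincident += 1
            continue
        q = dist * inv_h
        if q >= 2.0:
            continue
        dwdq = _dwdq_scalar(q, sigma)
        gscale = dwdq * inv_h / dist  # grad_a W = gscale * dr
        vdotg = 0.0
        rdotg = 0.0
        for d in range(dim):
            g = gscale * dr[d]
            pair_grad[k, d] = g
            vdotg += dv[d] * g
            rdotg += dr[d] * g
        # continuity: drho_a/dt += m_b v_ab . grad_a W_ab (symmetric under swap)
        drho[a] += mass[b] * vdotg
        drho[b] += mass[a] * vdotg
        inv_rr = 1.0 / (rho[a] * rho[b])
        # symmetric pressure term
        pterm = (pres[a] + pres[b]) * inv_rr
        # physical viscous term: m_b (mu_a+mu_b) v_ab/(rho_a rho_b r^2) (r . gradW)
        vterm = mu2 * inv_rr / r2 * rdotg
        # optional Monaghan artificial viscosity (off when alpha_av = 0)
        piab = 0.0
        if alpha_av > 0.0:
            vdotr = 0.0
            for d in range(dim):
                vdotr += dv[d] * dr[d]
            if vdotr < 0.0:
                mu_ab = h * vdotr / (r2 + eps_av)
                piab = -alpha_av * c0 * mu_ab / (0.5 * (rho[a] + rho[b]))
        for d in range(dim):
            g = gscale * dr[d]
            f = -(pterm + piab) * g + vterm * dvv[d]
            acc[a, d] += mass[b] * f
            acc[b, d] -= mass[a] * f
    return n_coincident


@numba.njit(cache=True, fastmath=True)
def _wall_pressure_sums(pos, rho, pres, frozen, pi, pj, h, sigma, box, g,
                        num, den):
    """Kernel-weighted fluid pressure at each wall particle, with the
    hydrostatic correction rho_f g . (r_w - r_f) (generalized dummy-wall
    boundary condition)."""
    dim = pos.shape[1]
    inv_h = 1.0 / h
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        if frozen[a] == frozen[b]:
            continue
        if frozen[a]:
            w_id, f_id = a, b
        else:
            w_id, f_id = b, a
        r2 = 0.0
        gdot = 0.0
        for d in range(dim):
            x = pos[w_id, d] - pos[f_id, d]
            if box[d] > 0.0:
                x -= box[d] * np.round(x / box[d])
            r2 += x * x
            gdot += g[d] * x
        q = np.sqrt(r2) * inv_h
        if q >= 2.0:
            continue
        w = _w_scalar(q, sigma)
        num[w_id] += (pres[f_id] + rho[f_id] * gdot) * w
        den[w_id] += w


def dummy_wall_pressure(
    state: FluidState,
    pairs: tuple[np.ndarray, np.ndarray],
    kernel: KernelSpec,
    eos: EquationOfState,
    body_force: np.ndarray | None = None,
    periodic: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pressure and density for frozen (dummy-wall) particles.

    Wall particles take the kernel-weighted pressure of the neighbouring
    fluid plus the hydrostatic term ``rho_f g . (r_w - r_f)``, and their
    density follows from inverting the EOS; integrating their density by
    continuity instead would spuriously compress converging walls.
    Wall particles with no fluid neighbours revert to (0, rho0).

    Returns (rho_wall, P_wall) for the frozen subset, in frozen-index
    order.
    """
    g = (np.zeros(state.dim) if body_force is None
         else np.asarray(body_force, dtype=float))
    num = np.zeros(state.n)
    den = np.zeros(state.n)
    _wall_pressure_sums(
        state.pos, state.rho, state.pressure, state.frozen,
        pairs[0], pairs[1], kernel.h, kernel.sigma,
        _box_array(state.dim, periodic), g, num, den,
    )
    wall = state.frozen
    p_w = np.where(den[wall] > 1e-12, num[wall] / np.maximum(den[wall], 1e-300), 0.0)
    if eos.kind == "linear":
        rho_w = eos.rho0 + p_w / eos.c0**2
    else:
        b = eos.rho0 * eos.c0**2 / eos.gamma
        rho_w = eos.rho0 * np.maximum(1.0 + p_w / b, 1e-3) ** (1.0 / eos.gamma)
    rho_w = np.maximum(rho_w, 0.3 * eos.rho0)
    return rho_w, p_w


@numba.njit(cache=True, fastmath=True)
def _wall_velocity_average(pos, vel, mass, rho, frozen, pi, pj, h, sigma, box,
                           num, den):
    """Kernel-weighted average of free-particle velocities around each
    frozen particle (Morris-style no-slip extrapolation support)."""
    dim = pos.shape[1]
    inv_h = 1.0 / h
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        if frozen[a] == frozen[b]:
            continue
        if frozen[a]:
            w_id, f_id = a, b
        else:
            w_id, f_id = b, a
        r2 = 0.0
        for d in range(dim):
            x = pos[a, d] - pos[b, d]
            if box[d] > 0.0:
                x -= box[d] * np.round(x / box[d])
            r2 += x * x
        q = np.sqrt(r2) * inv_h
        if q >= 2.0:
            continue
        w = _w_scalar(q, sigma) * mass[f_id] / rho[f_id]
        den[w_id] += w
        for d in range(dim):
            num[w_id, d] += w * vel[f_id, d]


@numba.njit(cache=True, fastmath=True)
def _density_rate_from_grad(vel, mass, pi, pj, pair_grad, drho):
    """Continuity rate reusing cached pair kernel gradients."""
    dim = vel.shape[1]
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        vdotg = 0.0
        for d in range(dim):
            vdotg += (vel[a, d] - vel[b, d]) * pair_grad[k, d]
        drho[a] += mass[b] * vdotg
        drho[b] += mass[a] * vdotg


@numba.njit(cache=True)
def _accumulate_summation_density(pos, mass, pi, pj, h, sigma, box, out):
    dim = pos.shape[1]
    n = pos.shape[0]
    w0 = _w_scalar(0.0, sigma)
    for a in range(n):
        out[a] = mass[a] * w0  # self contribution
    for k in range(pi.shape[0]):
        a = pi[k]
        b = pj[k]
        r2 = 0.0
        for d in range(dim):
            x = pos[a, d] - pos[b, d]
            if box[d] > 0.0:
                x -= box[d] * np.round(x / box[d])
            r2 += x * x
        w = _w_scalar(np.sqrt(r2) / h, sigma)
        out[a] += mass[b] * w
        out[b] += mass[a] * w


# ---------------------------------------------------------------------------
# public rate evaluations


def _box_array(state_dim: int, periodic: np.ndarray | None) -> np.ndarray:
    if periodic is None:
        return np.zeros(state_dim)
    return np.asarray(periodic, dtype=float)


def density_rate(
    state: FluidState,
    pairs: tuple[np.ndarray, np.ndarray],
    kernel: KernelSpec,
    periodic: np.ndarray | None = None,
) -> np.ndarray:
    """Continuity-equation density rate per particle (kg/m^3/s)."""
    drho = np.zeros(state.n)
    acc = np.zeros_like(state.pos)
    grad = np.empty((pairs[0].shape[0], state.dim))
    _accumulate_rates(
        state.pos, state.vel, state.vel, state.rho, state.mass, np.zeros(state.n), 0.0,
        pairs[0], pairs[1], kernel.h, kernel.sigma,
        _box_array(state.dim, periodic), 1.0, 0.0, drho, acc, grad,
    )
    return drho


def momentum_rate(
    state: FluidState,
    pairs: tuple[np.ndarray, np.ndarray],
    kernel: KernelSpec,
    periodic: np.ndarray | None = None,
    artificial_visc_alpha: float = 0.0,
    c0: float = 1.0,
) -> np.ndarray:
    """Acceleration per particle from the pressure and viscous pair terms
    (m/s^2).  Pressures in ``state.pressure`` must be current for the
    given densities."""
    drho = np.zeros(state.n)
    acc = np.zeros_like(state.pos)
    grad = np.empty((pairs[0].shape[0], state.dim))
    n_bad = _accumulate_rates(
        state.pos, state.vel, state.vel, state.rho, state.mass, state.pressure,
        2.0 * state.mu, pairs[0], pairs[1], kernel.h, kernel.sigma,
        _box_array(state.dim, periodic), c0, artificial_visc_alpha, drho, acc, grad,
    )
    if n_bad:
        warnings.warn(
            f"{n_bad} coincident particle pair(s): contribution zeroed", RuntimeWarning
        )
    return acc


def compute_rates(
    state: FluidState,
    pairs: tuple[np.ndarray, np.ndarray],
    kernel: KernelSpec,
    eos: EquationOfState,
    periodic: np.ndarray | None = None,
    artificial_visc_alpha: float = 0.0,
    body_force: np.ndarray | None = None,
    vel_visc: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One-pass evaluation of (drho/dt, dv/dt) with current EOS pressure.

    Also returns the cached per-pair kernel gradients so the caller can
    re-evaluate the continuity rate after the velocity kick without a
    second geometry pass (see :func:`density_rate_cached`)."""
    state.pressure[:] = eos.pressure(state.rho)
    drho = np.zeros(state.n)
    acc = np.zeros_like(state.pos)
    grad = np.empty((pairs[0].shape[0], state.dim))
    velv = state.vel if vel_visc is None else vel_visc
    n_bad = _accumulate_rates(
        state.pos, state.vel, velv, state.rho, state.mass, state.pressure,
        2.0 * state.mu, pairs[0], pairs[1], kernel.h, kernel.sigma,
        _box_array(state.dim, periodic), eos.c0, artificial_visc_alpha, drho, acc, grad,
    )
    if n_bad:
        warnings.warn(
            f"{n_bad} coincident particle pair(s): contribution zeroed", RuntimeWarning
        )
    if body_force is not None:
        acc += np.asarray(body_force, dtype=float)[None, :]
    return drho, acc, grad


def density_rate_cached(state, pairs, pair_grad) -> np.ndarray:
    """Continuity rate from cached pair gradients (post-kick pass)."""
    drho = np.zeros(state.n)
    _density_rate_from_grad(state.vel, state.mass, pairs[0], pairs[1], pair_grad, drho)
    return drho


def noslip_wall_velocity(
    state: FluidState,
    pairs: tuple[np.ndarray, np.ndarray],
    kernel: KernelSpec,
    periodic: np.ndarray | None = None,
) -> np.ndarray:
    """Fictitious wall-particle velocities enforcing no-slip.

    Each frozen particle is assigned ``2 v_wall - <v_fluid>`` (the
    kernel-weighted average of neighbouring free-particle velocities),
    the antisymmetric extension of the flow about the wall surface.
    The result is meant for the viscous term only (``vel_visc`` of
    :func:`compute_rates`); continuity keeps the true wall velocity.
    """
    num = np.zeros_like(state.pos)
    den = np.zeros(state.n)
    _wall_velocity_average(
        state.pos, state.vel, state.mass, state.rho, state.frozen,
        pairs[0], pairs[1], kernel.h, kernel.sigma,
        _box_array(state.dim, periodic), num, den,
    )
    velv = state.vel.copy()
    wall = state.frozen & (den > 1e-12)
    velv[wall] = 2.0 * state.vel[wall] - num[wall] / den[wall, None]
    return velv


def summation_density(
    state: FluidState,
    pairs: tuple[np.ndarray, np.ndarray],
    kernel: KernelSpec,
    periodic: np.ndarray | None = None,
) -> np.ndarray:
    """Shepard-style direct density sum ``rho_a = sum_b m_b W_ab``,
    including the self term ``m_a W(0)``.  Used as an optional periodic
    re-initialization filter on rough scenes."""
    out = np.zeros(state.n)
    _accumulate_summation_density(
        state.pos, state.mass, pairs[0], pairs[1], kernel.h, kernel.sigma,
        _box_array(state.dim, periodic), out,
    )
    return out


def kernel_interpolate(
    values: np.ndarray,
    state: FluidState,
    at: np.ndarray,
    kernel: KernelSpec,
    shepard: bool = False,
) -> np.ndarray | float:
    """SPH interpolation of a particle-carried field at arbitrary points.

    Evaluates ``sum_b m_b A_b / rho_b W(at - r_b, h)``; with
    ``shepard=True`` the sum is instead normalized by
    ``sum_b m_b/rho_b W``, which restores zeroth-order consistency near
    free surfaces and boundaries (used by the pressure probes).
    Points with an empty neighbour set return 0 by convention.
    """
    values = np.asarray(values, dtype=float)
    single_point = np.asarray(at).ndim == 1
    at = np.atleast_2d(np.asarray(at, dtype=float))
    tree = cKDTree(state.pos)
    scalar_field = values.ndim == 1
    out_shape = (at.shape[0],) if scalar_field else (at.shape[0], values.shape[1])
    out = np.zeros(out_shape)
    for k, pt in enumerate(at):
        idx = tree.query_ball_point(pt, kernel.support_radius)
        if not idx:
            continue
        idx = np.asarray(idx, dtype=np.int64)
        d = np.linalg.norm(state.pos[idx] - pt[None, :], axis=1)
        w = np.array([_w_scalar(q, kernel.sigma) for q in d / kernel.h])
        vol = state.mass[idx] / state.rho[idx]
        denom = float((vol * w).sum())
        if scalar_field:
            num = float((vol * w * values[idx]).sum())
        else:
            num = (vol * w)[:, None].T @ values[idx]
            num = num.ravel()
        if shepard and denom > 0.0:
            out[k] = num / denom
        else:
            out[k] = num
    if single_point:
        return float(out[0]) if scalar_field else out[0]
    return out


# ---------------------------------------------------------------------------
# time integration


def cfl_dt(kernel: KernelSpec, eos: EquationOfState, vmax: float, cfl: float = 0.25) -> float:
    """Stable explicit time step ``cfl * h / (c0 + vmax)``."""
    return cfl * kernel.h / (eos.c0 + vmax)


def step_fluid(
    state: FluidState,
    kernel: KernelSpec,
    eos: EquationOfState,
    dt: float,
    periodic: np.ndarray | None = None,
    body_force: np.ndarray | None = None,
    ext_accel: np.ndarray | None = None,
    pairs: tuple[np.ndarray, np.ndarray] | None = None,
    artificial_visc_alpha: float = 0.0,
    cfl_limit: float = 1.0,
    frozen_vel: np.ndarray | None = None,
) -> FluidState:
    """Advance the fluid one explicit (semi-implicit / symplectic Euler)
    step in place: kick velocities with current-state forces, then drift
    positions with the new velocities; density integrates the continuity
    rate, pressure follows from the EOS.

    ``ext_accel`` carries externally computed per-particle accelerations
    (contact coupling, piston forces).  ``frozen_vel`` optionally
    prescribes the velocity of frozen particles for this step.
    Frozen particles receive no acceleration but advect with their
    prescribed velocity and keep their density evolving, so walls carry
    hydrostatic pressure.
    """
    vmax = float(np.linalg.norm(state.vel, axis=1).max(initial=0.0))
    limit = cfl_limit * kernel.h / (eos.c0 + vmax)
    if dt > limit:
        raise ValueError(
            f"dt={dt:.3e} exceeds the CFL bound {limit:.3e} (h={kernel.h}, c0={eos.c0})"
        )
    if pairs is None:
        pairs = neighbor_search(state.pos, kernel.support_radius, periodic)
    _, acc, grad = compute_rates(
        state, pairs, kernel, eos, periodic, artificial_visc_alpha, body_force
    )
    if ext_accel is not None:
        acc = acc + ext_accel
    free = ~state.frozen
    state.vel[free] += dt * acc[free]
    if frozen_vel is not None:
        state.vel[state.frozen] = frozen_vel
    # symplectic acoustic coupling: continuity evaluated with the kicked
    # velocities before the drift
    drho = density_rate_cached(state, pairs, grad)
    state.pos += dt * state.vel
    state.rho += dt * drho
    if np.any(state.rho <= 0.0):
        raise FloatingPointError("non-positive density after step: unstable configuration")
    state.pressure[:] = eos.pressure(state.rho)
    if periodic is not None:
        for d in range(state.dim):
            if periodic[d] > 0:
                state.pos[:, d] = np.mod(state.pos[:, d], periodic[d])
    return state
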