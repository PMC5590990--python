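"""SPH fluid core: neighbour search, rate equations, EOS, stepping,
conservation."""

import numpy as np
import pytest

from valvefsi.fluid import (EquationOfState, FluidState, compute_rates,
                            density_rate, eos_pressure, kernel_interpolate,
                            momentum_rate, neighbor_search, step_fluid,
                            summation_density)
from valvefsi.kernels import KernelSpec, cubic_spline_w


def _cloud(rng, n=60, dim=3, spacing=0.01):
    pos = rng.uniform(0.0, 10 * spacing, (n, dim))
    vel = rng.normal(0.0, 0.1, (n, dim))
    rho = np.full(n, 1056.0) * rng.uniform(0.98, 1.02, n)
    mass = np.full(n, 1056.0 * spacing**dim)
    return FluidState(pos=pos, vel=vel, rho=rho, mass=mass)


# ---------------------------------------------------------------------------
# neighbour search


def test_neighbor_search_matches_bruteforce(rng):
    for n in (50, 100, 200):
        pos = rng.uniform(0, 1, (n, 3))
        cutoff = 0.22
        i, j = neighbor_search(pos, cutoff)
        got = set(zip(i.tolist(), j.tolist()))
        expected = set()
        for a in range(n):
            for b in range(a + 1, n):
                if np.linalg.norm(pos[a] - pos[b]) < cutoff:
                    expected.add((a, b))
        assert got == expected


def test_neighbor_search_periodic_minimum_image():
    pos = np.array([[0.05, 0.5], [0.95, 0.5]])
    i, j = neighbor_search(pos, 0.2, periodic=np.array([1.0, 0.0]))
    assert list(zip(i, j)) == [(0, 1)]  # wraps across x
    i, j = neighbor_search(pos, 0.2, periodic=None)
    assert len(i) == 0


def test_neighbor_search_edge_cases():
    assert neighbor_search(np.zeros((1, 3)), 1.0)[0].size == 0
    pos = np.array([[0.0, 0.0, 0.0], [2.1, 0.0, 0.0]])
    assert neighbor_search(pos, 2.0)[0].size == 0  # beyond cutoff
    with pytest.raises(ValueError):
        neighbor_search(np.array([[np.nan, 0, 0]]), 1.0)


# ---------------------------------------------------------------------------
# rate equations


def test_density_rate_zero_for_rigid_motion(rng):
    state = _cloud(rng)
    state.vel[:] = np.array([0.3, -0.1, 0.2])  # common translation
    kernel = KernelSpec(h=0.02, dim=3)
    pairs = neighbor_search(state.pos, kernel.support_radius)
    drho = density_rate(state, pairs, kernel)
    np.testing.assert_allclose(drho, 0.0, atol=1e-12)


def test_density_rate_isolated_particle():
    state = FluidState(pos=np.zeros((1, 3)), vel=np.ones((1, 3)),
                       rho=np.array([1056.0]), mass=np.array([1e-6]))
    kernel = KernelSpec(h=0.01)
    drho = density_rate(state, (np.zeros(0, np.int64), np.zeros(0, np.int64)), kernel)
    assert drho[0] == 0.0


def test_density_rate_two_particle_headon():
    """Approaching pair: drho_a/dt = m_b * 2u * |dW/dr| at separation d,
    checked against a direct numerical derivative of W."""
    h, d, u, m = 0.01, 0.012, 0.5, 2e-6
    state = FluidState(
        pos=np.array([[0.0, 0, 0], [d, 0, 0]]),
        vel=np.array([[u, 0, 0], [-u, 0, 0]]),
        rho=np.full(2, 1056.0), mass=np.full(2, m),
    )
    kernel = KernelSpec(h=h)
    pairs = (np.array([0], np.int64), np.array([1], np.int64))
    drho = density_rate(state, pairs, kernel)
    eps = 1e-8
    dwdr = (float(cubic_spline_w(d + eps, h, 3)[0])
            - float(cubic_spline_w(d - eps, h, 3)[0])) / (2 * eps)
    expected = m * 2.0 * u * abs(dwdr)
    assert drho[0] == pytest.approx(expected, rel=1e-6)
    assert drho[1] == pytest.approx(expected, rel=1e-6)


def test_momentum_rate_single_particle():
    state = FluidState(pos=np.zeros((1, 3)), vel=np.zeros((1, 3)),
                       rho=np.array([1056.0]), mass=np.array([1e-6]),
                       pressure=np.array([500.0]))
    acc = momentum_rate(state, (np.zeros(0, np.int64), np.zeros(0, np.int64)),
                        KernelSpec(h=0.01))
    np.testing.assert_array_equal(acc, 0.0)


def test_momentum_rate_pair_balance(rng):
    """m_a dv_a/dt + m_b dv_b/dt = 0 to machine precision for any pair
    state (pressure and viscous terms are exactly antisymmetric)."""
    for _ in range(10):
        pos = rng.uniform(0, 0.02, (2, 3))
        if np.linalg.norm(pos[0] - pos[1]) > 0.018:
            continue
        state = FluidState(pos=pos, vel=rng.normal(0, 1, (2, 3)),
                           rho=1056 * rng.uniform(0.95, 1.05, 2),
                           mass=rng.uniform(1e-6, 3e-6, 2),
                           pressure=rng.uniform(-100, 500, 2))
        acc = momentum_rate(state, (np.array([0], np.int64), np.array([1], np.int64)),
                            KernelSpec(h=0.01))
        ptot = state.mass[0] * acc[0] + state.mass[1] * acc[1]
        np.testing.assert_allclose(ptot, 0.0, atol=1e-18)


def test_momentum_rate_viscous_term_opposes_relative_motion():
    """Zero pressure, pure relative velocity: the viscous force on each
    particle points against its velocity relative to the other."""
    state = FluidState(
        pos=np.array([[0.0, 0, 0], [0.012, 0, 0]]),
        vel=np.array([[0.0, 0.4, 0], [0.0, -0.4, 0]]),
        rho=np.full(2, 1056.0), mass=np.full(2, 2e-6),
        pressure=np.zeros(2), mu=0.0035,
    )
    acc = momentum_rate(state, (np.array([0], np.int64), np.array([1], np.int64)),
                        KernelSpec(h=0.01))
    assert acc[0, 1] < 0.0   # particle 0 moves +y relative to 1 -> decelerated
    assert acc[1, 1] > 0.0


def test_momentum_rate_coincident_pair_guard():
    state = FluidState(pos=np.zeros((2, 3)), vel=np.zeros((2, 3)),
                       rho=np.full(2, 1056.0), mass=np.full(2, 1e-6),
                       pressure=np.full(2, 100.0))
    with pytest.warns(RuntimeWarning, match="coincident"):
        acc = momentum_rate(state, (np.array([0], np.int64), np.array([1], np.int64)),
                            KernelSpec(h=0.01))
    np.testing.assert_array_equal(acc, 0.0)


# ---------------------------------------------------------------------------
# equation of state


def test_eos_reference_and_linear_value():
    eos = EquationOfState(rho0=1056.0, c0=10.0)
    assert eos_pressure(1056.0, eos) == 0.0
    assert eos_pressure(1.01 * 1056.0, eos) == pytest.approx(0.01 * 1056.0 * 100.0)


def test_eos_monotone_both_kinds():
    rhos = np.linspace(900.0, 1200.0, 50)
    for kind in ("linear", "tait"):
        eos = EquationOfState(rho0=1056.0, c0=8.0, kind=kind)
        p = eos.pressure(rhos)
        assert np.all(np.diff(p) > 0)
        assert eos.pressure(1056.0) == pytest.approx(0.0, abs=1e-9)


def test_eos_invalid_inputs():
    eos = EquationOfState(rho0=1056.0, c0=10.0)
    with pytest.raises(ValueError):
        eos.pressure(-1.0)
    with pytest.raises(ValueError):
        EquationOfState(rho0=1056.0, c0=0.0)
    with pytest.raises(ValueError):
        EquationOfState(rho0=1056.0, c0=1.0, kind="cubic")


# ---------------------------------------------------------------------------
# interpolation


def test_kernel_interpolate_uniform_field_on_lattice():
    """Interior interpolation of a constant field recovers it within 2%."""
    dx = 0.01
    ax = (np.arange(12) + 0.5) * dx
    g = np.meshgrid(ax, ax, ax, indexing="ij")
    pos = np.stack([a.ravel() for a in g], axis=1)
    n = pos.shape[0]
    state = FluidState(pos=pos, vel=np.zeros((n, 3)), rho=np.full(n, 1056.0),
                       mass=np.full(n, 1056.0 * dx**3))
    kernel = KernelSpec(h=1.3 * dx)
    c = 7.3
    val = kernel_interpolate(np.full(n, c), state, np.array([0.06, 0.06, 0.06]), kernel)
    assert val == pytest.approx(c, rel=0.02)


def test_kernel_interpolate_empty_neighbourhood():
    state = FluidState(pos=np.zeros((1, 3)), vel=np.zeros((1, 3)),
                       rho=np.array([1056.0]), mass=np.array([1e-6]))
    kernel = KernelSpec(h=0.01)
    assert kernel_interpolate(np.array([5.0]), state,
                              np.array([0.05, 0.0, 0.0]), kernel) == 0.0


def test_kernel_interpolate_density_gives_summation_density(rng):
    """Interpolating A_b = rho_b at a particle's own position equals the
    summation density sum_b m_b W (plus the self term)."""
    state = _cloud(rng, n=40)
    kernel = KernelSpec(h=0.02)
    pairs = neighbor_search(state.pos, kernel.support_radius)
    rho_sum = summation_density(state, pairs, kernel)
    val = kernel_interpolate(state.rho, state, state.pos[7], kernel)
    assert val == pytest.approx(rho_sum[7], rel=1e-10)


# ---------------------------------------------------------------------------
# stepping and conservation


def test_step_fluid_pure_advection():
    """No forces, no neighbours: one step is r += v dt at constant rho."""
    state = FluidState(pos=np.zeros((1, 3)), vel=np.array([[0.1, 0.2, -0.3]]),
                       rho=np.array([1056.0]), mass=np.array([1e-6]))
    eos = EquationOfState(rho0=1056.0, c0=10.0)
    dt = 1e-4
    step_fluid(state, KernelSpec(h=0.01), eos, dt)
    np.testing.assert_allclose(state.pos[0], np.array([0.1, 0.2, -0.3]) * dt)
    assert state.rho[0] == 1056.0


def test_step_fluid_cfl_guard():
    state = FluidState(pos=np.zeros((1, 3)), vel=np.zeros((1, 3)),
                       rho=np.array([1056.0]), mass=np.array([1e-6]))
    eos = EquationOfState(rho0=1056.0, c0=10.0)
    with pytest.raises(ValueError, match="CFL"):
        step_fluid(state, KernelSpec(h=0.01), eos, dt=0.5)


def test_isolated_cloud_conserves_momentum_and_mass(rng):
    """Free cloud (no walls, no body force): per-step linear momentum
    drift < 1e-10 relative; masses never change."""
    state = _cloud(rng, n=150, spacing=0.008)
    kernel = KernelSpec(h=0.012)
    eos = EquationOfState(rho0=1056.0, c0=5.0)
    mass0 = state.mass.copy()
    p_scale = float(np.abs(state.mass[:, None] * state.vel).sum())
    dt = 0.1 * kernel.h / (eos.c0 + 1.0)
    prev = state.total_momentum()
    for _ in range(20):
        step_fluid(state, kernel, eos, dt)
        cur = state.total_momentum()
        drift = np.linalg.norm(cur - prev) / p_scale
        assert drift < 1e-10
        prev = cur
    np.testing.assert_array_equal(state.mass, mass0)
    assert state.total_mass() == mass0.sum()


def test_fluid_state_validation():
    with pytest.raises(ValueError, match="mass"):
        FluidState(pos=np.zeros((2, 3)), vel=np.zeros((2, 3)),
                   rho=np.full(2, 1056.0), mass=np.array([1e-6, -1e-6]))
    with pytest.raises(ValueError, match="densit"):
        FluidState(pos=np.zeros((2, 3)), vel=np.zeros((2, 3)),
                   rho=np.array([1056.0, 0.0]), mass=np.full(2, 1e-6))
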