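"""Hemodynamic and valve-kinematic metrics: formulas, traces, probes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from valvefsi.metrics import (FluxProbe, HemodynamicsReport, KinematicsReport,
                              detect_rvot_rvct_et, e_over_a, eoa_av, eoa_mv,
                              hydrodynamic_axial_force, opening_angle,
                              regurgitant_fraction, regurgitant_volume,
                              stroke_volume_ef)


# ---------------------------------------------------------------------------
# stroke volume / ejection fraction


def test_stroke_volume_ef_reference_volumes():
    """EDV 112 ml, ESV 47 ml -> SV 65 ml, EF 58%."""
    sv, ef = stroke_volume_ef(112.0, 47.0)
    assert sv == pytest.approx(65.0)
    assert round(ef) == 58


def test_stroke_volume_ef_limits():
    sv, ef = stroke_volume_ef(100.0, 0.0)
    assert (sv, ef) == (100.0, 100.0)
    _, ef_small = stroke_volume_ef(100.0, 100.0 - 1e-9)
    assert ef_small < 1e-8
    with pytest.raises(ValueError):
        stroke_volume_ef(47.0, 112.0)


# ---------------------------------------------------------------------------
# effective orifice area


def test_eoa_normalization_points():
    assert eoa_av(51.6, 1.0) == pytest.approx(1.0)
    assert eoa_av(2 * 51.6, 1.0) == pytest.approx(2.0)   # linear in MSF
    assert eoa_mv(31.0, 1.0) == pytest.approx(1.0)
    assert eoa_mv(62.0, 4.0) == pytest.approx(1.0)       # sqrt(dP) scaling


def test_eoa_round_trip_clinical_anchors():
    """Inverting the AV formula at a 11.1 mmHg mean systolic gradient
    and 1.6 cm^2 EOA gives MSF = 1.6*51.6*sqrt(11.1) ~ 275 ml/s, and
    the forward formula round-trips; same for the MV at 2.0 mmHg and
    3.8 cm^2."""
    msf = 1.6 * 51.6 * np.sqrt(11.1)
    assert msf == pytest.approx(275.0, abs=0.5)
    assert eoa_av(msf, 11.1) == pytest.approx(1.6)
    mdf = 3.8 * 31.0 * np.sqrt(2.0)
    assert mdf == pytest.approx(166.6, abs=0.5)
    assert eoa_mv(mdf, 2.0) == pytest.approx(3.8)


def test_eoa_requires_positive_gradient():
    with pytest.raises(ValueError):
        eoa_av(100.0, 0.0)
    with pytest.raises(ValueError):
        eoa_mv(100.0, -1.0)


# ---------------------------------------------------------------------------
# regurgitation


def test_regurgitant_volume_cases():
    t = np.linspace(0, 1, 1001)
    assert regurgitant_volume(t, np.abs(np.sin(8 * t)) + 0.1) == 0.0
    # -10 ml/s for 0.1 s -> 1 ml
    q = np.where((t >= 0.2) & (t < 0.3), -10.0, 0.0)
    assert regurgitant_volume(t, q) == pytest.approx(1.0, rel=0.02)


def test_regurgitant_volume_sinusoid_lobe():
    """One negative half-sine lobe: RV equals the closed-form lobe area
    2 A T / pi within 0.5% at 1 ms sampling."""
    T, A = 0.1, 30.0
    t = np.arange(0.0, 0.4, 1e-3)
    q = np.where(t < T, -A * np.sin(np.pi * t / T), 5.0)
    rv = regurgitant_volume(t, q)
    assert rv == pytest.approx(2 * A * T / np.pi, rel=0.005)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(shift=st.floats(0.0, 50.0))
def test_regurgitant_volume_invariant_to_added_forward_flow(shift):
    """RV depends only on the negative part of the trace: boosting the
    forward (positive) flow leaves it unchanged."""
    t = np.linspace(0, 0.8, 400)
    q = np.sin(2 * np.pi * t / 0.8) * 20.0
    base = regurgitant_volume(t, q)
    boosted = q + shift * (q > 0)
    assert regurgitant_volume(t, boosted) == pytest.approx(base, rel=1e-12)
    assert regurgitant_volume(t, np.minimum(q, 0.0)) == pytest.approx(base, rel=1e-12)


def test_regurgitant_fraction_clinical_values():
    """RV 4.8 ml over SV 65 ml -> RF 7.4%; RV 9.8 ml -> RF 15%."""
    assert regurgitant_fraction(4.8, 65.0) == pytest.approx(7.4, abs=0.05)
    assert round(regurgitant_fraction(9.8, 65.0)) == 15
    assert regurgitant_fraction(0.0, 65.0) == 0.0
    with pytest.raises(ValueError):
        regurgitant_fraction(1.0, 0.0)


def test_regurgitant_volume_empty_trace():
    with pytest.raises(ValueError):
        regurgitant_volume(np.array([]), np.array([]))


# ---------------------------------------------------------------------------
# flux probe


def test_flux_probe_uniform_flow_through_disk():
    """Uniform flow u through a disk of area A gives Q = u A within 5%
    (kinematic oracle: a moving particle lattice)."""
    from valvefsi.fluid import FluidState
    dx = 1e-3
    u = 0.2
    ax = np.arange(-0.01, 0.01, dx) + dx / 2
    zax = np.arange(-0.005, 0.005, dx) + dx / 2
    g = np.meshgrid(ax, ax, zax, indexing="ij")
    pos = np.stack([a.ravel() for a in g], axis=1)
    r = np.hypot(pos[:, 0], pos[:, 1])
    pos = pos[r < 0.009]
    n = len(pos)
    state = FluidState(pos=pos, vel=np.tile([0, 0, u], (n, 1)),
                       rho=np.full(n, 1056.0), mass=np.full(n, 1056.0 * dx**3))
    radius = 0.006
    probe = FluxProbe(center=np.zeros(3), normal=np.array([0, 0, 1.0]),
                      radius=radius)
    dt = 5e-4
    probe.update(state, 0.0, dt)
    # 40 steps x u dt = 4 mm of travel: exactly four lattice layers cross
    qs = []
    for k in range(1, 41):
        state.pos[:, 2] += u * dt
        qs.append(probe.update(state, k * dt, dt))
    q_mean = np.mean(qs) * 1e6
    assert q_mean == pytest.approx(u * np.pi * radius**2 * 1e6, rel=0.05)


def test_flux_probe_no_crossings():
    from valvefsi.fluid import FluidState
    state = FluidState(pos=np.array([[0.0, 0, 1.0]]), vel=np.zeros((1, 3)),
                       rho=np.array([1056.0]), mass=np.array([1e-6]))
    probe = FluxProbe(np.zeros(3), np.array([0, 0, 1.0]), 0.5)
    probe.update(state, 0.0, 1e-3)
    assert probe.update(state, 1e-3, 1e-3) == 0.0


# ---------------------------------------------------------------------------
# pressure-drop probes


def test_transvalvular_drop_hydrostatic_column(hydrostatic_result):
    """Two probes dz apart in the settled tank read rho g dz (the
    static-column sanity check for the transvalvular-drop machinery);
    swapping the probes negates the trace."""
    from valvefsi.metrics import transvalvular_pressure_drop
    from valvefsi.units import pa_to_mmhg
    sc = hydrostatic_result["scene"]
    H = sc.metadata["height"]
    g = sc.metadata["g"]
    lo = np.array([sc.metadata["width"] / 2, sc.metadata["width"] / 2, 0.25 * H])
    hi = np.array([sc.metadata["width"] / 2, sc.metadata["width"] / 2, 0.75 * H])
    drop = transvalvular_pressure_drop(lo, hi, [sc.fluid], sc.kernel)
    expected = pa_to_mmhg(sc.eos.rho0 * g * 0.5 * H)
    assert drop[0] == pytest.approx(expected, rel=0.05)
    swapped = transvalvular_pressure_drop(hi, lo, [sc.fluid], sc.kernel)
    assert swapped[0] == pytest.approx(-drop[0], rel=1e-12)


# ---------------------------------------------------------------------------
# hydrodynamic force


def test_hydrodynamic_axial_force_projection():
    trace = np.array([[0.0, 0.0, 2.0], [1.0, 0.0, -1.0]])
    axis = np.array([0.0, 0.0, 2.0])     # normalized internally
    out = hydrodynamic_axial_force(trace, axis)
    np.testing.assert_allclose(out, [2.0, -1.0])
    np.testing.assert_allclose(hydrodynamic_axial_force(trace, -axis), -out)
    assert hydrodynamic_axial_force(np.zeros((5, 3)), axis).sum() == 0.0


def test_closed_disk_axial_force_equals_pressure_times_area(rng):
    """Static pressure difference dP across a rigid closed disk: the
    summed contact reaction equals dP x area within 5% (pressure-area
    oracle built from a uniform penetrating particle sheet)."""
    from valvefsi.coupling import ContactConfig, detect_contacts, penalty_forces
    from valvefsi.scenes import _rect_grid_mesh
    dx = 1e-3
    nodes, tris = _rect_grid_mesh(np.linspace(0, 0.02, 11),
                                  np.linspace(0, 0.02, 11), plane="xy", offset=0.0)
    cfg = ContactConfig(stiffness=50.0, thickness=0.8 * dx)
    # particle sheet hovering at uniform penetration delta: mimics fluid
    # pushed against the disk by pressure dP = k delta / dx^2
    delta = 2e-4
    ax = np.arange(0.0005, 0.02, dx)
    gx, gy = np.meshgrid(ax, ax, indexing="ij")
    pts = np.stack([gx.ravel(), gy.ravel(),
                    np.full(gx.size, cfg.thickness - delta)], axis=1)
    cs = detect_contacts(pts, nodes, tris, cfg)
    _, fn = penalty_forces(cs, cfg, tris, len(pts), len(nodes))
    total = fn.sum(axis=0)
    dp = cfg.stiffness * delta / dx**2
    area = 0.02 * 0.02
    assert abs(total[2]) == pytest.approx(dp * area, rel=0.05)


# ---------------------------------------------------------------------------
# E/A ratio


def _gauss(t, t0, w):
    return np.exp(-0.5 * ((t - t0) / w) ** 2)


def test_e_over_a_constructed_peaks():
    t = np.linspace(0, 0.5, 500)
    v = 0.8 * _gauss(t, 0.15, 0.02) + 0.4 * _gauss(t, 0.35, 0.02)
    assert e_over_a(t, v) == pytest.approx(2.0, rel=0.01)
    v_eq = 0.5 * _gauss(t, 0.15, 0.02) + 0.5 * _gauss(t, 0.35, 0.02)
    assert e_over_a(t, v_eq) == pytest.approx(1.0, rel=0.01)


def test_e_over_a_missing_a_wave():
    t = np.linspace(0, 0.5, 500)
    v = 0.8 * _gauss(t, 0.2, 0.03)
    with pytest.raises(ValueError, match="A wave"):
        e_over_a(t, v)


# ---------------------------------------------------------------------------
# RVOT / RVCT / ET


def _trapezoid_trace(rise_ms=30.0, fall_ms=50.0, plateau_ms=190.0,
                     dt_ms=1.0, pre_ms=50.0, post_ms=50.0, amp=0.1):
    """Leaflet-belly radial velocity resembling rapid opening, open
    plateau and rapid closing."""
    t = np.arange(0.0, pre_ms + rise_ms + plateau_ms + fall_ms + post_ms + dt_ms,
                  dt_ms) * 1e-3
    v = np.zeros_like(t)
    t0, t1 = pre_ms * 1e-3, (pre_ms + rise_ms) * 1e-3
    t2, t3 = t1 + plateau_ms * 1e-3, t1 + (plateau_ms + fall_ms) * 1e-3
    v += np.where((t >= t0) & (t < t1), amp * (t - t0) / (t1 - t0), 0.0)
    v += np.where((t >= t1) & (t < t2), amp, 0.0)
    v += np.where((t >= t2) & (t < t3), amp * (1 - (t - t2) / (t3 - t2)), 0.0)
    return t, v


def test_rvot_rvct_et_trapezoid():
    """A 30 ms opening ramp and 50 ms closing ramp are recovered as
    RVOT/RVCT (within the 1 ms sampling smear of the slope estimate);
    ET spans opening start to closing end."""
    t, v = _trapezoid_trace()
    rvot, rvct, et = detect_rvot_rvct_et(t, v)
    assert rvot == pytest.approx(30.0, abs=2.0)
    assert rvct == pytest.approx(50.0, abs=2.0)
    assert et == pytest.approx(30.0 + 190.0 + 50.0, abs=4.0)
    assert et >= rvot + rvct


def test_rvot_rvct_time_reversal_swaps_roles():
    t, v = _trapezoid_trace()
    rvot, rvct, _ = detect_rvot_rvct_et(t, v)
    rvot_r, rvct_r, _ = detect_rvot_rvct_et(t, v[::-1])
    assert rvot_r == pytest.approx(rvct, abs=1.0)
    assert rvct_r == pytest.approx(rvot, abs=1.0)


def test_rvot_rvct_flat_trace_error():
    t = np.linspace(0, 0.5, 100)
    with pytest.raises(ValueError, match="flat"):
        detect_rvot_rvct_et(t, np.full_like(t, 0.3))


# ---------------------------------------------------------------------------
# opening angle


def test_opening_angle_reference_cases():
    hinge = np.zeros(3)
    n = np.array([0.0, 0.0, 1.0])
    assert opening_angle(hinge, np.array([1.0, 0, 0]), n) == pytest.approx(0.0)
    assert opening_angle(hinge, np.array([0, 0, 2.0]), n) == pytest.approx(90.0)
    ang = np.deg2rad(30.0)
    tip = np.array([np.cos(ang), 0.0, np.sin(ang)])
    assert opening_angle(hinge, tip, n) == pytest.approx(30.0, abs=1e-9)


def test_opening_angle_trace_and_errors():
    hinge = np.zeros((3, 3))
    tips = np.array([[1, 0, 0], [0, 1, 1], [0, 0, 1.0]])
    out = opening_angle(hinge, tips, np.array([0, 0, 1.0]))
    np.testing.assert_allclose(out, [0.0, 45.0, 90.0], atol=1e-9)
    with pytest.raises(ValueError):
        opening_angle(np.zeros(3), np.zeros(3), np.array([0, 0, 1.0]))


# ---------------------------------------------------------------------------
# reports


def test_report_invariants():
    rep = HemodynamicsReport(sv_ml=65.0, ef_percent=58.0, rv_av_ml=4.8)
    rep.validate()
    bad = HemodynamicsReport(ef_percent=140.0)
    with pytest.raises(ValueError):
        bad.validate()
    kin = KinematicsReport(rvot_ms=30.0, rvct_ms=50.0, et_ms=270.0)
    kin.validate()
    with pytest.raises(ValueError):
        KinematicsReport(rvot_ms=30.0, rvct_ms=50.0, et_ms=60.0).validate()
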