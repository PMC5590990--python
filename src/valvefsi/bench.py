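"""Validation benchmark runners.

Each runner builds its scene at the default (desk-scale) resolution,
runs it, and returns a plain dict with the measured quantities, the
analytic references and relative errors.  The test suite, the ``bench``
CLI subcommand and the acceptance script all share these entry points
so they measure exactly the same thing.
"""

from __future__ import annotations

import numpy as np

from .metrics import regurgitant_volume
from .scenes import (make_elastic_gate, make_hydrostatic_tank, make_idealized_lv,
                     make_poiseuille_channel, make_tube_valve, orifice_area)
from .simulate import Simulation

__all__ = [
    "run_hydrostatic_benchmark",
    "run_poiseuille_benchmark",
    "run_elastic_gate_benchmark",
    "run_tube_valve_protocol",
    "run_lv_conservation",
]


def run_hydrostatic_benchmark(**scene_kwargs) -> dict:
    """Settle the hydrostatic tank; compare interior probe pressures
    against P = rho g (H - z).  Tolerance 5%."""
    sc = make_hydrostatic_tank(**scene_kwargs)
    sim = Simulation(sc).run(log_every=0)
    H = sc.metadata["height"]
    g = sc.metadata["g"]
    rho0 = sc.eos.rho0
    errors = {}
    for name, pt in sc.pressure_probes.items():
        _, p = sim.trace(f"pressure:{name}")
        analytic = rho0 * g * (H - pt[-1])
        errors[name] = abs(float(p[-1]) - analytic) / analytic
    max_err = max(errors.values())
    return {"name": "hydrostatic_tank", "errors": errors, "max_rel_error": max_err,
            "tolerance": 0.05, "passed": max_err < 0.05, "n_particles": sc.fluid.n,
            "scene": sc, "simulation": sim}


def run_poiseuille_benchmark(n_profile_bins: int = 12, **scene_kwargs) -> dict:
    """Run the plane channel to steady state; compare the bin-averaged
    velocity profile against the analytic parabola.  Tolerance 5% of
    the centerline speed."""
    sc = make_poiseuille_channel(**scene_kwargs)
    sim = Simulation(sc).run(log_every=0)
    f = sc.fluid
    H = sc.metadata["height"]
    umax = sc.metadata["u_max"]
    free = ~f.frozen
    y = f.pos[free, 1]
    u = f.vel[free, 0]
    u_an = 4.0 * umax * y * (H - y) / H**2
    bins = np.linspace(0.0, H, n_profile_bins + 1)
    idx = np.clip(np.digitize(y, bins) - 1, 0, n_profile_bins - 1)
    prof = np.array([u[idx == b].mean() for b in range(n_profile_bins)])
    prof_an = np.array([u_an[idx == b].mean() for b in range(n_profile_bins)])
    err = float(np.abs(prof - prof_an).max() / umax)
    return {"name": "poiseuille_channel", "max_rel_error": err, "tolerance": 0.05,
            "passed": err < 0.05, "profile": prof, "profile_analytic": prof_an,
            "n_particles": sc.fluid.n, "scene": sc, "simulation": sim}


def run_elastic_gate_benchmark(tail: int = 20, **scene_kwargs) -> dict:
    """Rigid-limit gate: steady contact load vs the hydrostatic
    resultant rho g H^2 W / 2.  Tolerance 5%."""
    sc = make_elastic_gate(**scene_kwargs)
    sim = Simulation(sc).run(log_every=0)
    _, F = sim.trace("contact_force:gate")
    load = float(np.asarray(F)[-tail:, 0].mean())
    analytic = sc.metadata["analytic_gate_load"]
    err = abs(load - analytic) / analytic
    return {"name": "elastic_gate", "gate_load_n": load, "analytic_n": analytic,
            "max_rel_error": err, "tolerance": 0.05, "passed": err < 0.05,
            "n_particles": sc.fluid.n, "scene": sc, "simulation": sim}


def run_tube_valve_protocol(t_reverse: float = 0.07, duration: float = 0.13,
                            sample_every: int = 150, **scene_kwargs) -> dict:
    """Forward-then-reverse pressure protocol on the tri-leaflet tube
    valve: forward transvalvular pressure opens the valve (orifice area
    grows), reversed pressure closes it, with a positive regurgitant
    volume during closure."""
    sc = make_tube_valve(
        inlet_mmhg=lambda t: 20.0 if t < t_reverse else 5.0,
        outlet_mmhg=lambda t: 10.0 if t < t_reverse else 30.0,
        duration=duration, **scene_kwargs)
    valve = sc.structures[0]
    fes = sc.metadata["free_edge_sets"]
    times, areas = [], []

    def sample(sim):
        if sim.step_count % sample_every == 0:
            times.append(sim.t)
            areas.append(orifice_area(valve.mesh, valve.state.disp, fes))

    sim = Simulation(sc)
    sample(sim)
    sim.run(callback=sample, log_every=0)
    times_a = np.asarray(times)
    areas_a = np.asarray(areas)
    t_q, q = sc.flux_probes["valve"].trace_ml_s()
    closing = t_q >= t_reverse
    rv_ml = regurgitant_volume(t_q[closing], q[closing])
    fwd = areas_a[times_a < t_reverse]
    return {
        "name": "tube_valve", "t_reverse": t_reverse,
        "times": times_a, "orifice_area_cm2": areas_a * 1e4,
        "initial_area_cm2": float(areas_a[0] * 1e4),
        "peak_open_area_cm2": float(fwd.max() * 1e4),
        "final_area_cm2": float(areas_a[-1] * 1e4),
        "regurgitant_volume_ml": float(rv_ml),
        "flux_trace": (t_q, q),
        "opened": bool(fwd.max() > 1.5 * areas_a[0]),
        "closed": bool(areas_a[-1] < 0.5 * fwd.max()),
        "n_particles": sc.fluid.n, "scene": sc, "simulation": sim,
    }


def run_valve_static_closed(duration: float = 0.05, reverse_mmhg: float = 10.0,
                            **scene_kwargs) -> dict:
    """Pressurized closed-valve static test: reverse transvalvular load
    on the closed reference configuration; measures the largest steady
    contact penetration (must stay below 0.1 particle spacing)."""
    from .coupling import detect_contacts
    kwargs = dict(upstream=0.012, downstream=0.014)
    kwargs.update(scene_kwargs)
    sc = make_tube_valve(inlet_mmhg=5.0, outlet_mmhg=5.0 + reverse_mmhg,
                         duration=duration, **kwargs)
    sim = Simulation(sc).run(log_every=0)
    valve = sc.structures[0]
    f = sc.fluid
    free = np.nonzero(~f.frozen)[0]
    cs = detect_contacts(f.pos[free], valve.current_nodes(),
                         valve.mesh.triangles, valve.contact)
    max_depth = float(cs.depth.max()) if cs.n else 0.0
    return {"name": "valve_static_closed", "max_penetration_m": max_depth,
            "max_penetration_dx": max_depth / sc.dx, "dx": sc.dx,
            "n_contacts": int(cs.n), "scene": sc, "simulation": sim}


def run_lv_conservation(duration: float = 0.34, **scene_kwargs) -> dict:
    """Systolic ejection of the idealized LV.

    Conservation check: the cycle-integrated plane flux must equal the
    change of fluid volume (sum m/rho) in the chamber region below the
    flux plane (2%).  The ejected volume is also compared against the
    nominal wall-track volume change; that comparison is limited by the
    half-spacing uncertainty of the dummy-particle wall position at
    desk-scale resolution (see the methods note) and is judged at 20%.
    """
    sc = make_idealized_lv(duration=duration, **scene_kwargs)
    md = sc.metadata
    f = sc.fluid
    free = ~f.frozen
    z_plane = md["z_plane"]

    def chamber_volume_ml():
        below = free & (f.pos[:, 2] < z_plane)
        return float(np.sum(f.mass[below] / f.rho[below]) * 1e6)

    v0 = chamber_volume_ml()
    sim = Simulation(sc).run(log_every=0)
    v1 = chamber_volume_ml()
    flux_ml = sc.flux_probes["outlet"].integrated_volume_ml()
    dv_fluid = v0 - v1
    dv_track = md["volume_of_t"](0.0) - md["volume_of_t"](sim.t)
    conservation_err = abs(flux_ml - dv_fluid) / max(dv_fluid, 1e-9)
    track_err = abs(flux_ml - dv_track) / dv_track
    return {
        "name": "idealized_lv", "flux_ml": float(flux_ml),
        "chamber_dv_ml": float(dv_fluid), "track_dv_ml": float(dv_track),
        "conservation_rel_error": float(conservation_err),
        "track_rel_error": float(track_err),
        "tolerance": 0.02, "passed": conservation_err < 0.02,
        "n_particles": sc.fluid.n, "scene": sc, "simulation": sim,
    }
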