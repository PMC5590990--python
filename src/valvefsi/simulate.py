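"""Coupled SPH--FE time stepping.

A :class:`Scene` bundles a fluid particle system, optional tissue
structures, boundary conditions (body force, frozen-wall motion,
pistons) and probes.  :class:`Simulation` advances it with a partitioned
explicit scheme per fluid step:

1. piston servos set the plug velocities against their pressure targets;
2. prescribed wall motions update frozen-particle kinematics;
3. node-to-surface contacts between fluid particles and each structure
   surface are detected and penalty forces computed (equal and opposite
   on particles and surface nodes);
4. deformable structures substep with central differences under the
   contact loads (the fluid load is held constant across substeps);
   rigid structures follow their motion tracks directly;
5. the fluid advances one weakly-compressible SPH step.

The fluid time step is fixed per scene from the CFL bound at the design
flow speed; structures substep below their own stable increment.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.spatial import cKDTree

from .boundaries import Piston, PrescribedMotionTrack, apply_piston
from .coupling import (ContactConfig, detect_contacts, penalty_forces,
                       penalty_forces_current)
from .fe import StructuralMesh, StructuralState, lumped_mass, step_structure
from .fluid import (EquationOfState, FluidState, KernelSpec, compute_rates,
                    density_rate_cached, dummy_wall_pressure, neighbor_search,
                    noslip_wall_velocity)
from .metrics import FluxProbe

logger = logging.getLogger(__name__)

__all__ = ["Structure", "WallMotion", "Scene", "Simulation"]


@dataclass
class Structure:
    """One tissue structure coupled to the fluid through contact."""

    name: str
    mesh: StructuralMesh
    state: StructuralState
    contact: ContactConfig
    rigid: bool = False
    track: PrescribedMotionTrack | None = None    # drives tracked_nodes
    tracked_nodes: np.ndarray | None = None       # default: all (rigid) / none
    fixed_nodes: np.ndarray | None = None         # clamped at zero displacement
    substeps: int = 4
    damping: float = 0.0                          # mass-proportional, 1/s
    allow_truss_compression: bool = False
    extra_prescribed: Callable | None = None      # t -> list[(idx, disp, vel)]
    couple: bool = True                           # participate in fluid contact
    mass_scale: float = 1.0                       # explicit-dynamics mass scaling

    def __post_init__(self) -> None:
        self._mass = (lumped_mass(self.mesh) * self.mass_scale
                      if not self.rigid else None)
        if self.tracked_nodes is None and self.track is not None:
            self.tracked_nodes = np.arange(self.mesh.n_nodes)

    def prescribed(self, t: float) -> list:
        out = []
        if self.track is not None and self.tracked_nodes is not None:
            d = self.track.displacement(t)
            v = self.track.velocity(t)
            out.append((self.tracked_nodes, d, v))
        if self.fixed_nodes is not None and len(self.fixed_nodes):
            out.append((self.fixed_nodes,
                        np.zeros((len(self.fixed_nodes), 3)),
                        np.zeros((len(self.fixed_nodes), 3))))
        if self.extra_prescribed is not None:
            out.extend(self.extra_prescribed(t))
        return out

    def current_nodes(self) -> np.ndarray:
        return self.mesh.nodes + self.state.disp

    def node_velocities(self) -> np.ndarray:
        return self.state.vel


@dataclass
class WallMotion:
    """Analytic prescribed motion of a group of frozen particles.

    ``mapping(t, ref)`` returns (positions, velocities) for the group's
    reference coordinates; positions are assigned exactly each step
    (no drift accumulation)."""

    indices: np.ndarray
    reference: np.ndarray
    mapping: Callable[[float, np.ndarray], tuple[np.ndarray, np.ndarray]]

    def apply(self, t: float, fluid: FluidState) -> None:
        pos, vel = self.mapping(t, self.reference)
        fluid.pos[self.indices] = pos
        fluid.vel[self.indices] = vel


@dataclass
class Scene:
    """A ready-to-run configuration: geometry, materials, boundaries."""

    name: str
    fluid: FluidState
    kernel: KernelSpec
    eos: EquationOfState
    dt: float
    duration: float
    dx: float
    periodic: np.ndarray | None = None
    body_force: np.ndarray | None = None
    structures: list = field(default_factory=list)
    pistons: list = field(default_factory=list)
    wall_motions: list = field(default_factory=list)
    settle_damping: float = 0.0        # bulk velocity damping (1/s), settling scenes
    settle_until: float = np.inf
    artificial_visc_alpha: float = 0.0
    noslip_walls: bool = False         # Morris-style wall velocity extrapolation
    adami_walls: bool = True           # interpolated dummy-wall pressure/density
    shepard_every: int = 0             # density re-init interval (0 = off)
    flux_probes: dict = field(default_factory=dict)       # name -> FluxProbe
    pressure_probes: dict = field(default_factory=dict)   # name -> point
    marker_nodes: dict = field(default_factory=dict)      # name -> (structure, node id)
    piston_control_every: int = 2
    record_every: int = 10
    metadata: dict = field(default_factory=dict)

    def particle_mass(self) -> float:
        return float(np.median(self.fluid.mass))

    def config_hash(self) -> str:
        payload = {
            "name": self.name, "dx": self.dx, "dt": self.dt,
            "duration": self.duration, "n": int(self.fluid.n),
            "c0": self.eos.c0, "rho0": self.eos.rho0,
            "metadata": {k: str(v) for k, v in sorted(self.metadata.items())},
        }
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


class Simulation:
    """Advance a scene and record traces."""

    def __init__(self, scene: Scene) -> None:
        self.scene = scene
        self.t = 0.0
        self.step_count = 0
        self.traces: dict[str, list] = {"t": []}
        for s in scene.structures:
            self.traces[f"contact_force:{s.name}"] = []
        for name in scene.pressure_probes:
            self.traces[f"pressure:{name}"] = []
        for name in scene.marker_nodes:
            self.traces[f"marker:{name}"] = []
        for p_i, _ in enumerate(scene.pistons):
            self.traces[f"piston{p_i}:offset"] = []
        logger.info("scene '%s' [%s]: n=%d dt=%.3e c0=%.2f",
                    scene.name, scene.config_hash(), scene.fluid.n,
                    scene.dt, scene.eos.c0)

    # -- stepping ----------------------------------------------------------

    def _neighbor_pairs(self):
        """Pair list with a Verlet skin: the search radius is enlarged by
        ``skin`` and the list only rebuilt once any particle has moved
        more than skin/2 since the last build (the pair kernels ignore
        pairs beyond the true 2h support)."""
        sc = self.scene
        fluid = sc.fluid
        if sc.periodic is not None:
            # periodic scenes are small; rebuild every step with the exact cutoff
            return neighbor_search(fluid.pos, sc.kernel.support_radius, sc.periodic)
        skin = 0.3 * sc.kernel.h
        cached = getattr(self, "_nb_cache", None)
        if cached is not None:
            ref_pos, pairs = cached
            moved2 = np.einsum("ij,ij->i", fluid.pos - ref_pos, fluid.pos - ref_pos)
            if moved2.max(initial=0.0) < (0.5 * skin) ** 2:
                return pairs
        tree = cKDTree(fluid.pos)
        pairs_arr = tree.query_pairs(sc.kernel.support_radius + skin,
                                     output_type="ndarray")
        if pairs_arr.size:
            pairs = (pairs_arr[:, 0].astype(np.int64), pairs_arr[:, 1].astype(np.int64))
        else:
            pairs = (np.empty(0, np.int64), np.empty(0, np.int64))
        self._nb_cache = (fluid.pos.copy(), pairs)
        return pairs

    def step(self) -> None:
        sc = self.scene
        fluid = sc.fluid
        dt = sc.dt
        t = self.t

        # wall motion and piston control act on frozen-particle kinematics
        for wm in sc.wall_motions:
            wm.apply(t, fluid)

        pairs = self._neighbor_pairs()

        if sc.adami_walls and fluid.frozen.any():
            fluid.pressure[:] = sc.eos.pressure(fluid.rho)
            rho_w, _ = dummy_wall_pressure(fluid, pairs, sc.kernel, sc.eos,
                                           sc.body_force, sc.periodic)
            fluid.rho[fluid.frozen] = rho_w

        if sc.pistons and self.step_count % sc.piston_control_every == 0:
            fluid.pressure[:] = sc.eos.pressure(fluid.rho)
            ptree = cKDTree(fluid.pos)

            def _probe_pressure(pt, _tree=ptree):
                idx = _tree.query_ball_point(pt, sc.kernel.support_radius)
                if not idx:
                    return 0.0
                idx = np.asarray(idx)
                d = np.linalg.norm(fluid.pos[idx] - pt[None, :], axis=1)
                from .kernels import _w_scalar
                w = np.array([_w_scalar(q, sc.kernel.sigma) for q in d / sc.kernel.h])
                vol = fluid.mass[idx] / fluid.rho[idx]
                den = float((vol * w).sum())
                return float((vol * w * fluid.pressure[idx]).sum() / den) if den > 0 else 0.0

            for piston in sc.pistons:
                apply_piston(piston, t, fluid, sc.kernel, sc.eos.rho0, sc.eos.c0,
                             dt, pressure_fn=_probe_pressure)
        for piston in sc.pistons:
            piston.offset += piston.velocity_state * dt

        # contact detection (free fluid particles only; frozen walls are
        # boundary geometry, not contact partners)
        ext_accel = None
        free_idx = None
        contact_sets = {}
        for s in sc.structures:
            if not s.couple:
                continue
            if free_idx is None:
                free_idx = np.nonzero(~fluid.frozen)[0]
            cs = detect_contacts(fluid.pos[free_idx], s.current_nodes(),
                                 s.mesh.triangles, s.contact, warn_degenerate=False)
            contact_sets[s.name] = cs
            if s.rigid or not s.couple:
                fp, fn = penalty_forces(
                    cs, s.contact, s.mesh.triangles, len(free_idx), s.mesh.n_nodes,
                    particle_vel=fluid.vel[free_idx], node_vel=s.node_velocities(),
                )
                if ext_accel is None:
                    ext_accel = np.zeros_like(fluid.pos)
                ext_accel[free_idx] += fp / fluid.mass[free_idx, None]
                self._record_structure_force(s, fn)

        # structures advance; deformable surfaces see the contact as a
        # live spring (penetration re-evaluated every substep) and the
        # fluid receives the substep-averaged reaction
        for s in sc.structures:
            if s.rigid:
                if s.track is not None:
                    s.state.disp[s.tracked_nodes] = s.track.displacement(t + dt)
                    s.state.vel[s.tracked_nodes] = s.track.velocity(t + dt)
                continue
            cs = contact_sets.get(s.name)
            sub_dt = dt / s.substeps
            fp_mean = None
            fn_mean = None
            for k in range(s.substeps):
                t_sub = t + (k + 1) * sub_dt
                if cs is not None and cs.n:
                    fp, fn = penalty_forces_current(
                        cs, s.contact, fluid.pos[free_idx], s.current_nodes(),
                        s.mesh.triangles, len(free_idx), s.mesh.n_nodes,
                        particle_vel=fluid.vel[free_idx],
                        node_vel=s.node_velocities(),
                    )
                    fp_mean = fp if fp_mean is None else fp_mean + fp
                    fn_mean = fn if fn_mean is None else fn_mean + fn
                else:
                    fn = np.zeros_like(s.mesh.nodes)
                step_structure(
                    s.mesh, s.state, fn,
                    sub_dt, nodal_mass=s._mass, damping=s.damping,
                    prescribed=s.prescribed(t_sub),
                    allow_truss_compression=s.allow_truss_compression,
                )
            if fp_mean is not None:
                if ext_accel is None:
                    ext_accel = np.zeros_like(fluid.pos)
                ext_accel[free_idx] += (fp_mean / s.substeps) / fluid.mass[free_idx, None]
                self._record_structure_force(s, fn_mean / s.substeps)
            elif s.couple:
                self._record_structure_force(s, np.zeros_like(s.mesh.nodes))

        # fluid advances
        vmax = float(np.linalg.norm(fluid.vel, axis=1).max(initial=0.0))
        limit = sc.kernel.h / (sc.eos.c0 + vmax)
        if dt > limit:
            raise ValueError(f"dt={dt:.3e} violates CFL bound {limit:.3e} at t={t:.4f}")
        vel_visc = None
        if sc.noslip_walls:
            vel_visc = noslip_wall_velocity(fluid, pairs, sc.kernel, sc.periodic)
        _, acc, pair_grad = compute_rates(
            fluid, pairs, sc.kernel, sc.eos, sc.periodic,
            sc.artificial_visc_alpha, sc.body_force, vel_visc=vel_visc,
        )
        if ext_accel is not None:
            acc += ext_accel
        free = ~fluid.frozen
        fluid.vel[free] += dt * acc[free]
        if sc.settle_damping > 0.0 and t < sc.settle_until:
            fluid.vel[free] *= np.exp(-sc.settle_damping * dt)
        # symplectic coupling: continuity integrated with the kicked
        # velocities at the pre-drift positions
        drho = density_rate_cached(fluid, pairs, pair_grad)
        if sc.adami_walls:
            drho[fluid.frozen] = 0.0
        fluid.pos += dt * fluid.vel
        fluid.rho += dt * drho
        if np.any(fluid.rho <= 0.0):
            raise FloatingPointError(f"non-positive density at t={t:.4f}")
        fluid.pressure[:] = sc.eos.pressure(fluid.rho)
        if sc.periodic is not None:
            for d in range(fluid.dim):
                if sc.periodic[d] > 0:
                    fluid.pos[:, d] = np.mod(fluid.pos[:, d], sc.periodic[d])

        if sc.shepard_every and (self.step_count + 1) % sc.shepard_every == 0:
            from .fluid import summation_density
            pairs2 = neighbor_search(fluid.pos, sc.kernel.support_radius, sc.periodic)
            fluid.rho[:] = summation_density(fluid, pairs2, sc.kernel, sc.periodic)
            fluid.pressure[:] = sc.eos.pressure(fluid.rho)

        self.t += dt
        self.step_count += 1

        for probe in sc.flux_probes.values():
            probe.update(fluid, self.t, dt)
        if self.step_count % sc.record_every == 0:
            self._record()

    def _record_structure_force(self, s: Structure, fn: np.ndarray) -> None:
        # reaction exerted BY the fluid ON the surface nodes
        key = f"contact_force:{s.name}"
        self._pending_forces = getattr(self, "_pending_forces", {})
        self._pending_forces[key] = fn.sum(axis=0)

    def _record(self) -> None:
        sc = self.scene
        self.traces["t"].append(self.t)
        pending = getattr(self, "_pending_forces", {})
        for s in sc.structures:
            key = f"contact_force:{s.name}"
            self.traces[key].append(pending.get(key, np.zeros(3)).copy())
        if sc.pressure_probes:
            from .fluid import kernel_interpolate
            for name, pt in sc.pressure_probes.items():
                val = kernel_interpolate(
                    sc.fluid.pressure, sc.fluid,
                    np.asarray(pt, dtype=float)[: sc.fluid.dim],
                    sc.kernel, shepard=True,
                )
                self.traces[f"pressure:{name}"].append(float(val))
        for name, (s_idx, node) in sc.marker_nodes.items():
            s = sc.structures[s_idx]
            self.traces[f"marker:{name}"].append(
                (s.mesh.nodes[node] + s.state.disp[node]).copy())
        for p_i, piston in enumerate(sc.pistons):
            self.traces[f"piston{p_i}:offset"].append(piston.offset)

    def run(self, duration: float | None = None,
            callback: Callable | None = None,
            log_every: int = 500) -> "Simulation":
        duration = self.scene.duration if duration is None else duration
        n_steps = int(round(duration / self.scene.dt))
        for i in range(n_steps):
            self.step()
            if callback is not None:
                callback(self)
            if log_every and self.step_count % log_every == 0:
                f = self.scene.fluid
                vmax = float(np.linalg.norm(f.vel, axis=1).max(initial=0.0))
                drho = float(np.abs(f.rho / self.scene.eos.rho0 - 1.0).max())
                logger.info("step %d t=%.4f dt=%.2e max|v|=%.3f drho/rho0=%.3f",
                            self.step_count, self.t, self.scene.dt, vmax, drho)
        return self

    def trace(self, key: str) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.traces["t"]), np.asarray(self.traces[key])
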