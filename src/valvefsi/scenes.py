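"""Synthetic geometry and benchmark scene generators.

Every solver feature and every metric is testable without external
data: scenes build their particle lattices, wall layers, tissue meshes
and boundary conditions from a handful of geometric parameters.
Available kinds:

* ``hydrostatic_tank``  -- box of fluid under gravity (3D or planar),
  analytic pressure field P = rho g (H - z).
* ``poiseuille_channel`` -- planar body-force-driven channel, periodic
  streamwise, analytic parabolic profile.
* ``elastic_gate``      -- tank whose downstream face is an FE membrane
  gate (rigid-limit or deformable) loaded by the hydrostatic column.
* ``tube_valve``        -- straight tube with a parametric tri-leaflet
  membrane valve, pressure pistons at both ends.
* ``idealized_lv``      -- truncated-ellipsoid left-ventricle chamber
  whose wall follows a 10-keyframe volume waveform
  (EDV 112 ml, ESV 47 ml, 0.8 s cycle), with an outlet tube.

Scenes are bit-reproducible from their spec (the default seeding is a
regular lattice; any jitter would take the explicit seed).
Resolutions default to desk-scale particle counts (~10^3-10^4).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .boundaries import Piston, PrescribedMotionTrack
from .coupling import ContactConfig
from .fe import StructuralMesh, StructuralState
from .fluid import EquationOfState, FluidState, KernelSpec
from .materials import TISSUE_PARAMETERS, MHGOParams, OgdenParams
from .metrics import FluxProbe
from .simulate import Scene, Structure, WallMotion
from .units import ml_to_m3

__all__ = [
    "SceneSpec", "build_scene",
    "make_hydrostatic_tank", "make_poiseuille_channel", "make_elastic_gate",
    "make_tube_valve", "make_idealized_lv",
    "default_lv_volume_waveform", "aortic_pressure_waveform",
    "mesh_volume", "tri_leaflet_valve_mesh", "orifice_area",
]

RHO_BLOOD = 1056.0     # kg/m^3
MU_BLOOD = 0.0035      # Pa s
H_FACTOR = 1.3         # smoothing length h = 1.3 dx
CFL = 0.25


@dataclass
class SceneSpec:
    """Declarative scene description (config-file friendly)."""

    kind: str
    dx: float | None = None
    duration: float | None = None
    seed: int = 0
    params: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.dx is not None and self.dx <= 0:
            raise ValueError("resolution dx must be positive")


_BUILDERS: dict = {}


def build_scene(spec: SceneSpec) -> Scene:
    """Dispatch a SceneSpec to its builder."""
    spec.validate()
    try:
        builder = _BUILDERS[spec.kind]
    except KeyError:
        raise ValueError(
            f"unknown scene kind '{spec.kind}'; available: {sorted(_BUILDERS)}"
        ) from None
    kwargs = dict(spec.params)
    if spec.dx is not None:
        kwargs["dx"] = spec.dx
    if spec.duration is not None:
        kwargs["duration"] = spec.duration
    kwargs["seed"] = spec.seed
    return builder(**kwargs)


def _register(kind):
    def deco(fn):
        _BUILDERS[kind] = fn
        return fn
    return deco


# ---------------------------------------------------------------------------
# lattice helpers


def lattice_box(lo, hi, dx: float) -> np.ndarray:
    """Cell-centered cubic lattice filling the box [lo, hi)."""
    lo = np.asarray(lo, dtype=float)
    hi = np.asarray(hi, dtype=float)
    counts = np.maximum(np.round((hi - lo) / dx).astype(int), 0)
    axes = [lo[d] + (np.arange(counts[d]) + 0.5) * dx for d in range(lo.size)]
    if any(c == 0 for c in counts):
        return np.zeros((0, lo.size))
    grids = np.meshgrid(*axes, indexing="ij")
    return np.stack([g.ravel() for g in grids], axis=1)


def _assemble_fluid(pts_fluid, pts_frozen, dx, dim, rho_init=None,
                    rho0=RHO_BLOOD, mu=MU_BLOOD) -> FluidState:
    pos = np.vstack([pts_fluid, pts_frozen]) if len(pts_frozen) else np.asarray(pts_fluid)
    n = pos.shape[0]
    frozen = np.zeros(n, dtype=bool)
    frozen[len(pts_fluid):] = True
    rho = np.full(n, rho0) if rho_init is None else np.asarray(rho_init, dtype=float)
    return FluidState(
        pos=pos, vel=np.zeros_like(pos), rho=rho,
        mass=np.full(n, rho0 * dx**dim), mu=mu, frozen=frozen,
    )


def surface_lattice_ellipsoid(a: float, c: float, dx: float,
                              hemisphere: str = "lower") -> np.ndarray:
    """Roughly uniform point sampling (spacing ~ dx) of the half
    ellipsoid x^2/a^2 + y^2/a^2 + z^2/c^2 = 1, z <= 0."""
    pts = []
    quarter = 0.5 * np.pi * c                      # meridian arc estimate
    n_theta = max(int(np.ceil(quarter / dx)), 3)
    for i in range(n_theta + 1):
        th = 0.5 * np.pi * i / n_theta             # 0 at equator, pi/2 at apex
        r = a * np.cos(th)
        z = -c * np.sin(th)
        circ = 2.0 * np.pi * r
        n_phi = max(int(np.ceil(circ / dx)), 1)
        for j in range(n_phi):
            ph = 2.0 * np.pi * (j + 0.5 * (i % 2)) / n_phi
            pts.append([r * np.cos(ph), r * np.sin(ph), z])
    return np.asarray(pts)


# ---------------------------------------------------------------------------
# hydrostatic tank


@_register("hydrostatic_tank")
def make_hydrostatic_tank(
    width: float = 0.012,
    height: float = 0.012,
    dx: float = 0.0012,
    dim: int = 3,
    g: float = 9.81,
    wall_layers: int = 3,
    duration: float = 0.18,
    c0: float | None = None,
    seed: int = 0,
) -> Scene:
    """Box of fluid under gravity with rigid frozen-particle walls.

    The settled state carries the analytic hydrostatic pressure
    P(z) = rho g (H - z); the density field is pre-initialized on that
    profile and a bulk velocity damping removes the residual transient.
    Pressure probes at several interior depths feed the validation.
    """
    if c0 is None:
        c0 = 10.0 * np.sqrt(g * height)
    wall = wall_layers * dx
    if dim == 3:
        pts_f = lattice_box([0, 0, 0], [width, width, height], dx)
        all_pts = lattice_box([-wall] * 3, [width + wall, width + wall, height + 2 * dx], dx)
        interior = np.all((all_pts >= 0) & (all_pts < [width, width, height + 3 * dx]), axis=1)
        pts_w = all_pts[~interior]
        gvec = np.array([0.0, 0.0, -g])
        zcol = 2
    elif dim == 2:
        pts_f = lattice_box([0, 0], [width, height], dx)
        all_pts = lattice_box([-wall] * 2, [width + wall, height + 2 * dx], dx)
        interior = np.all((all_pts >= 0) & (all_pts < [width, height + 3 * dx]), axis=1)
        pts_w = all_pts[~interior]
        gvec = np.array([0.0, -g])
        zcol = 1
    else:
        raise ValueError("hydrostatic tank supports dim 2 or 3")

    rho0 = RHO_BLOOD
    z_all = np.concatenate([pts_f[:, zcol], pts_w[:, zcol]])
    depth = np.clip(height - z_all, 0.0, None)
    rho_init = rho0 * (1.0 + g * depth / c0**2)
    fluid = _assemble_fluid(pts_f, pts_w, dx, dim, rho_init=rho_init)

    kernel = KernelSpec(h=H_FACTOR * dx, dim=dim)
    eos = EquationOfState(rho0=rho0, c0=float(c0))
    dt = CFL * kernel.h / (eos.c0 + np.sqrt(2 * g * height))

    probes = {}
    for frac in (0.25, 0.5, 0.75):
        z = frac * height
        pt = [width / 2] * (dim - 1) + [z]
        probes[f"z{frac:.2f}"] = np.asarray(pt)
    return Scene(
        name="hydrostatic_tank", fluid=fluid, kernel=kernel, eos=eos,
        dt=dt, duration=duration, dx=dx, body_force=gvec,
        settle_damping=25.0, settle_until=0.6 * duration,
        artificial_visc_alpha=0.1,
        pressure_probes=probes,
        metadata={"height": height, "width": width, "g": g, "dim": dim,
                  "analytic": "P(z) = rho g (H - z)"},
    )


# ---------------------------------------------------------------------------
# plane Poiseuille channel


@_register("poiseuille_channel")
def make_poiseuille_channel(
    height: float = 0.001,
    dx: float | None = None,
    n_across: int = 24,
    length_cells: int = 20,
    u_max: float = 0.005,
    wall_layers: int = 3,
    duration: float | None = None,
    seed: int = 0,
) -> Scene:
    """Planar body-force-driven channel flow, periodic streamwise.

    The steady solution is the parabola u(y) = 4 u_max y (H - y)/H^2;
    the body force g_x = 8 nu u_max / H^2 is derived from the requested
    centerline speed.  No-slip is imposed by frozen wall layers.
    """
    if dx is None:
        dx = height / n_across
    nu = MU_BLOOD / RHO_BLOOD
    gx = 8.0 * nu * u_max / height**2
    L = length_cells * dx
    pts_f = lattice_box([0, 0], [L, height], dx)
    wall = wall_layers * dx
    pts_w = np.vstack([
        lattice_box([0, -wall], [L, 0], dx),
        lattice_box([0, height], [L, height + wall], dx),
    ])
    fluid = _assemble_fluid(pts_f, pts_w, dx, dim=2)
    kernel = KernelSpec(h=H_FACTOR * dx, dim=2)
    c0 = max(10.0 * u_max, 40.0 * u_max)  # low-Mach margin for the transient
    eos = EquationOfState(rho0=RHO_BLOOD, c0=c0)
    dt = CFL * kernel.h / (c0 + u_max)
    if duration is None:
        duration = 0.55 * height**2 / nu   # ~ 5 diffusion e-foldings
    return Scene(
        name="poiseuille_channel", fluid=fluid, kernel=kernel, eos=eos,
        dt=dt, duration=duration, dx=dx,
        periodic=np.array([L, 0.0]),
        body_force=np.array([gx, 0.0]),
        noslip_walls=True,
        metadata={"height": height, "u_max": u_max, "gx": gx, "nu": nu,
                  "analytic": "u(y) = 4 u_max y (H-y)/H^2"},
    )


# ---------------------------------------------------------------------------
# elastic gate


@_register("elastic_gate")
def make_elastic_gate(
    height: float = 0.008,
    column: float = 0.005,
    width: float = 0.0035,
    gate_height: float | None = None,
    dx: float = 0.0005,
    g: float = 9.81,
    rigid: bool = True,
    gate_thickness: float = 4.0e-4,
    duration: float = 0.14,
    seed: int = 0,
) -> Scene:
    """Water column retained by a membrane gate on the downstream face.

    With ``rigid=True`` every gate node is clamped and the steady
    contact load equals the hydrostatic resultant rho g H^2 W / 2.
    With ``rigid=False`` only the top edge is clamped; the gate bulges
    downstream under load (the classic elastic-gate FSI benchmark,
    qualitatively).
    """
    if gate_height is None:
        gate_height = height * 1.2
    # realized column dimensions after lattice quantization
    height = round(height / dx) * dx
    column = round(column / dx) * dx
    width = round(width / dx) * dx
    wall = 3 * dx
    pts_f = lattice_box([0, 0, 0], [column, width, height], dx)
    # frozen walls: -x face, both y faces, floor; the +x face is the gate
    box_lo = np.array([-wall, -wall, -wall])
    box_hi = np.array([column, width + wall, gate_height + 2 * dx])
    all_pts = lattice_box(box_lo, box_hi, dx)
    inside = (
        (all_pts[:, 0] >= 0)
        & (all_pts[:, 1] >= 0) & (all_pts[:, 1] < width)
        & (all_pts[:, 2] >= 0)
    )
    pts_w = all_pts[~inside]
    z_all = np.concatenate([pts_f[:, 2], pts_w[:, 2]])
    c0 = 10.0 * np.sqrt(g * height)
    depth = np.clip(height - z_all, 0.0, None)
    rho_init = RHO_BLOOD * (1.0 + g * depth / c0**2)
    fluid = _assemble_fluid(pts_f, pts_w, dx, dim=3, rho_init=rho_init)
    kernel = KernelSpec(h=H_FACTOR * dx, dim=3)
    eos = EquationOfState(rho0=RHO_BLOOD, c0=c0)
    dt = CFL * kernel.h / (c0 + np.sqrt(2 * g * height))

    # gate mesh spanning the full slot width.  The penalty contact holds
    # fluid one contact-thickness away from the mesh, so the mesh is set
    # back so that its hydraulic (wetted) plane lies at x = column, the
    # same convention as the frozen walls (particle centers 0.5 dx in).
    m_p = RHO_BLOOD * dx**3
    contact = ContactConfig.auto(m_p, CFL * H_FACTOR * dx / (c0 + np.sqrt(2 * g * height)),
                                 dx, damping_ratio=0.3)
    x_gate = column - 0.5 * dx + contact.thickness
    ny = max(int(round((width + 2 * dx) / dx / 2)), 2)
    nz = max(int(round(gate_height / dx / 2)), 4)
    ys = np.linspace(-dx, width + dx, ny + 1)
    zs = np.linspace(0.0, gate_height, nz + 1)
    nodes, tris = _rect_grid_mesh(ys, zs, plane="yz", offset=x_gate)
    mesh = StructuralMesh(
        nodes=nodes, triangles=tris, thickness=gate_thickness,
        membrane_material=TISSUE_PARAMETERS["av_leaflet"],
    )
    node_z = nodes[:, 2]
    if rigid:
        fixed = np.arange(nodes.shape[0])
    else:
        fixed = np.nonzero(node_z > gate_height - 1e-12)[0]
    gate = Structure(
        name="gate", mesh=mesh, state=StructuralState.rest(mesh),
        contact=contact, rigid=rigid, fixed_nodes=fixed,
        substeps=8, damping=300.0,
    )
    return Scene(
        name="elastic_gate", fluid=fluid, kernel=kernel, eos=eos,
        dt=dt, duration=duration, dx=dx,
        body_force=np.array([0.0, 0.0, -g]),
        structures=[gate],
        settle_damping=25.0, settle_until=0.6 * duration,
        artificial_visc_alpha=0.1,
        metadata={"height": height, "width": width, "g": g, "rigid": rigid,
                  "analytic_gate_load": RHO_BLOOD * g * height**2 * width / 2.0},
    )


def _rect_grid_mesh(u: np.ndarray, v: np.ndarray, plane: str, offset: float):
    """Structured triangulated rectangle in the given coordinate plane."""
    uu, vv = np.meshgrid(u, v, indexing="ij")
    nu, nv = uu.shape
    if plane == "yz":
        nodes = np.stack([np.full(uu.size, offset), uu.ravel(), vv.ravel()], axis=1)
    elif plane == "xy":
        nodes = np.stack([uu.ravel(), vv.ravel(), np.full(uu.size, offset)], axis=1)
    else:
        raise ValueError(plane)
    tris = []
    for i in range(nu - 1):
        for j in range(nv - 1):
            n00 = i * nv + j
            n10 = (i + 1) * nv + j
            tris.append([n00, n10, n00 + 1])
            tris.append([n10, n10 + 1, n00 + 1])
    return nodes, np.asarray(tris, dtype=np.int64)


# ---------------------------------------------------------------------------
# tri-leaflet valve geometry


def tri_leaflet_valve_mesh(
    annulus_radius: float,
    leaflet_height: float,
    z_annulus: float,
    thickness: float = 4.0e-4,
    free_edge_radius: float | None = None,
    n_s: int = 4,
    n_phi: int = 10,
    gap_deg: float = 1.0,
    material: MHGOParams | None = None,
    downstream: float = 1.0,
) -> tuple[StructuralMesh, dict]:
    """Parametric tri-leaflet membrane valve.

    Three independent conical-patch leaflets span 120-degree sectors of
    the annulus ring at ``z_annulus``; each tapers from the annulus
    radius to a small free-edge radius (closed reference configuration,
    watertight up to the contact thickness) while rising ``downstream``
    by ``leaflet_height``.  Element fiber frames are circumferential /
    meridional.  Returns the mesh and a dict of node sets:
    ``annulus`` (clamped ring) and ``free_edge`` per leaflet.
    """
    if material is None:
        material = TISSUE_PARAMETERS["av_leaflet"]
    if free_edge_radius is None:
        free_edge_radius = 0.18 * annulus_radius
    nodes_all, tris_all, frames_all = [], [], []
    sets: dict = {"annulus": [], "free_edge": [], "belly": []}
    offset = 0
    for k in range(3):
        phi0 = np.deg2rad(120.0 * k + gap_deg / 2.0)
        phi1 = np.deg2rad(120.0 * (k + 1) - gap_deg / 2.0)
        phis = np.linspace(phi0, phi1, n_phi + 1)
        ss = np.linspace(0.0, 1.0, n_s + 1)
        nid = np.empty((n_s + 1, n_phi + 1), dtype=np.int64)
        for i, s in enumerate(ss):
            r = (1.0 - s) * annulus_radius + s * free_edge_radius
            z = z_annulus + downstream * leaflet_height * np.sin(0.5 * np.pi * s)
            for j, ph in enumerate(phis):
                nid[i, j] = offset + len(nodes_all)
                nodes_all.append([r * np.cos(ph), r * np.sin(ph), z])
        local = []
        for i in range(n_s):
            for j in range(n_phi):
                local.append([nid[i, j], nid[i + 1, j], nid[i, j + 1]])
                local.append([nid[i + 1, j], nid[i + 1, j + 1], nid[i, j + 1]])
        tris_all.extend(local)
        sets["annulus"].extend(nid[0, :].tolist())
        sets["free_edge"].append(nid[-1, :].tolist())
        sets["belly"].append(int(nid[n_s // 2, n_phi // 2]))
    nodes = np.asarray(nodes_all)
    tris = np.asarray(tris_all, dtype=np.int64)
    # circumferential / meridional fiber frame per element
    frames = np.empty((tris.shape[0], 2, 3))
    cent = nodes[tris].mean(axis=1)
    e_c = np.stack([-cent[:, 1], cent[:, 0], np.zeros(len(cent))], axis=1)
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)
    d1 = nodes[tris[:, 1]] - nodes[tris[:, 0]]
    d2 = nodes[tris[:, 2]] - nodes[tris[:, 0]]
    nrm = np.cross(d1, d2)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    # project the circumferential direction into the element plane
    e_c = e_c - np.einsum("ei,ei->e", e_c, nrm)[:, None] * nrm
    e_c /= np.linalg.norm(e_c, axis=1, keepdims=True)
    e_r = np.cross(nrm, e_c)
    frames[:, 0] = e_c
    frames[:, 1] = e_r
    mesh = StructuralMesh(
        nodes=nodes, triangles=tris, thickness=thickness,
        fiber_frames=frames, membrane_material=material,
        node_sets={k: v for k, v in sets.items()},
    )
    return mesh, sets


def add_chordae(
    mesh: StructuralMesh,
    insertion_nodes: list[list[int]],
    origin_points: np.ndarray,
    area: float = 4.0e-7,
    material: OgdenParams | None = None,
) -> tuple[StructuralMesh, np.ndarray]:
    """Append fork-shaped chordae: one origin node per fork branching
    into trusses that share it, inserted at the given leaflet nodes.

    Returns the augmented mesh and the indices of the new origin nodes
    (to be prescribed, e.g. between papillary-tip anchor positions).
    """
    if material is None:
        material = TISSUE_PARAMETERS["marginal_chordae"]
    nodes = mesh.nodes
    new_nodes = [nodes]
    trusses = [] if mesh.trusses.size == 0 else [mesh.trusses]
    origin_ids = []
    nid = nodes.shape[0]
    for fork, origin in zip(insertion_nodes, np.atleast_2d(origin_points)):
        new_nodes.append(origin[None, :])
        for ins in fork:
            trusses.append(np.array([[nid, ins]], dtype=np.int64))
        origin_ids.append(nid)
        nid += 1
    out = StructuralMesh(
        nodes=np.vstack(new_nodes),
        triangles=mesh.triangles, thickness=mesh.thickness,
        fiber_frames=mesh.fiber_frames, membrane_material=mesh.membrane_material,
        trusses=np.vstack(trusses), truss_area=area, truss_material=material,
        density=mesh.density, node_sets=dict(mesh.node_sets),
    )
    return out, np.asarray(origin_ids, dtype=np.int64)


def orifice_area(mesh: StructuralMesh, disp: np.ndarray, free_edge_sets,
                 axis: np.ndarray = np.array([0.0, 0.0, 1.0])) -> float:
    """Projected open area (m^2) spanned by the valve free edges.

    The free-edge nodes of all leaflets are projected on the annulus
    plane and ordered by angle; the polygon (shoelace) area is the
    geometric orifice.  Near-closed valves give a small area (the
    free-edge ring), fully open valves approach the annulus area.
    """
    x = mesh.nodes + disp
    ids = np.concatenate([np.asarray(s) for s in free_edge_sets])
    pts = x[ids]
    axis = axis / np.linalg.norm(axis)
    # in-plane coordinates
    e1 = np.array([1.0, 0.0, 0.0])
    e1 = e1 - (e1 @ axis) * axis
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    u = pts @ e1
    v = pts @ e2
    cu, cv = u.mean(), v.mean()
    order = np.argsort(np.arctan2(v - cv, u - cu))
    u, v = u[order], v[order]
    return float(0.5 * np.abs(np.dot(u, np.roll(v, -1)) - np.dot(v, np.roll(u, -1))))


@_register("tube_valve")
def make_tube_valve(
    radius: float = 0.010,
    dx: float = 0.0018,
    upstream: float = 0.018,
    downstream: float = 0.027,
    leaflet_height: float | None = None,
    leaflet_thickness: float = 4.0e-4,
    inlet_mmhg=20.0,
    outlet_mmhg=10.0,
    c0: float = 10.0,
    pressure_ramp: float = 0.02,
    duration: float = 0.12,
    material: str = "av_leaflet",
    with_chordae: bool = False,
    substeps: int = 24,
    seed: int = 0,
) -> Scene:
    """Straight tube with a tri-leaflet membrane valve and pressure
    pistons at both ends.

    The valve annulus sits at z = ``upstream``; leaflets point
    downstream and start closed.  ``inlet_mmhg``/``outlet_mmhg`` may be
    constants or callables of time (mmHg), enabling forward-then-reverse
    protocols.  A flux probe one radius downstream of the leaflet tips
    records the flow-rate trace.
    """
    if leaflet_height is None:
        leaflet_height = 0.6 * radius
    L = upstream + downstream
    shell = 2.5 * dx
    z_lo, z_hi = 0.0, L

    all_pts = lattice_box([-radius - shell, -radius - shell, z_lo],
                          [radius + shell, radius + shell, z_hi], dx)
    r_all = np.hypot(all_pts[:, 0], all_pts[:, 1])
    fluid_mask = r_all < radius
    shell_mask = (r_all >= radius) & (r_all < radius + shell)
    pts_shell = all_pts[shell_mask]
    pts_inner = all_pts[fluid_mask]
    # piston plugs: 3 frozen layers at each end of the fluid column
    plug_w = 3 * dx
    z = pts_inner[:, 2]
    inlet_plug_mask = z < z_lo + plug_w
    outlet_plug_mask = z > z_hi - plug_w
    pts_fluid = pts_inner[~(inlet_plug_mask | outlet_plug_mask)]
    pts_inlet = pts_inner[inlet_plug_mask]
    pts_outlet = pts_inner[outlet_plug_mask]
    pts_frozen = np.vstack([pts_shell, pts_inlet, pts_outlet])
    fluid = _assemble_fluid(pts_fluid, pts_frozen, dx, dim=3)
    n_f = len(pts_fluid)
    n_sh = len(pts_shell)
    inlet_ids = np.arange(n_f + n_sh, n_f + n_sh + len(pts_inlet))
    outlet_ids = np.arange(n_f + n_sh + len(pts_inlet), fluid.n)

    kernel = KernelSpec(h=H_FACTOR * dx, dim=3)
    eos = EquationOfState(rho0=RHO_BLOOD, c0=c0)
    dt = CFL * kernel.h / (c0 + 2.0)

    area = np.pi * radius**2

    def _ramped(wf):
        def wrapped(t, _wf=wf):
            base = _wf(t) if callable(_wf) else _wf
            return base * min(t / pressure_ramp, 1.0) if pressure_ramp > 0 else base
        return wrapped

    pist_in = Piston(origin=np.array([0.0, 0.0, z_lo + plug_w]),
                     normal=np.array([0.0, 0.0, 1.0]), area=area,
                     waveform=_ramped(inlet_mmhg), plug=inlet_ids, u_max=0.3)
    pist_out = Piston(origin=np.array([0.0, 0.0, z_hi - plug_w]),
                      normal=np.array([0.0, 0.0, -1.0]), area=area,
                      waveform=_ramped(outlet_mmhg), plug=outlet_ids, u_max=0.3)

    mesh, sets = tri_leaflet_valve_mesh(
        annulus_radius=radius, leaflet_height=leaflet_height,
        z_annulus=upstream, thickness=leaflet_thickness,
        material=TISSUE_PARAMETERS[material],
    )
    mesh.tension_field = True      # leaflets wrinkle rather than carry compression
    # carve the fluid lattice clear of the leaflet contact layer so no
    # particle starts in penetration
    from .coupling import detect_contacts as _dc
    carve_cfg = ContactConfig(stiffness=1.0, thickness=0.8 * dx + 0.6 * dx)
    cs0 = _dc(pts_fluid, mesh.nodes, mesh.triangles, carve_cfg)
    if cs0.n:
        keep = np.ones(len(pts_fluid), dtype=bool)
        keep[np.unique(cs0.particle)] = False
        pts_fluid = pts_fluid[keep]
        fluid = _assemble_fluid(pts_fluid, pts_frozen, dx, dim=3)
        n_f = len(pts_fluid)
        n_sh = len(pts_shell)
        inlet_ids = np.arange(n_f + n_sh, n_f + n_sh + len(pts_inlet))
        outlet_ids = np.arange(n_f + n_sh + len(pts_inlet), fluid.n)
        pist_in.plug = inlet_ids
        pist_out.plug = outlet_ids
    extra_prescribed = None
    if with_chordae:
        origin_pts = []
        forks = []
        for fe in sets["free_edge"]:
            mid = len(fe) // 2
            forks.append([fe[mid - 1], fe[mid], fe[mid + 1]])
            c = mesh.nodes[fe[mid]]
            origin_pts.append([1.4 * c[0], 1.4 * c[1], upstream - 0.6 * radius])
        mesh, origin_ids = add_chordae(mesh, forks, np.asarray(origin_pts))

        def extra_prescribed(t, _ids=origin_ids):
            return [(_ids, np.zeros((len(_ids), 3)), np.zeros((len(_ids), 3)))]

    m_p = RHO_BLOOD * dx**3
    contact = ContactConfig.auto(m_p, dt, dx, beta=40.0, damping_ratio=0.5)
    annulus = np.asarray(sets["annulus"], dtype=np.int64)
    valve = Structure(
        name="valve", mesh=mesh, state=StructuralState.rest(mesh),
        contact=contact, fixed_nodes=annulus, substeps=substeps,
        damping=400.0, extra_prescribed=extra_prescribed, mass_scale=8.0,
    )
    z_probe = upstream + leaflet_height + radius
    flux = FluxProbe(center=np.array([0.0, 0.0, z_probe]),
                     normal=np.array([0.0, 0.0, 1.0]), radius=radius)
    d = 2 * radius
    probes = {
        "upstream": np.array([0.0, 0.0, upstream - d]),
        "downstream": np.array([0.0, 0.0, min(upstream + 3 * d, L - plug_w - 2 * dx)]),
    }
    return Scene(
        name="tube_valve", fluid=fluid, kernel=kernel, eos=eos,
        dt=dt, duration=duration, dx=dx,
        structures=[valve], pistons=[pist_in, pist_out],
        flux_probes={"valve": flux},
        pressure_probes=probes,
        artificial_visc_alpha=0.15,
        metadata={"radius": radius, "upstream": upstream, "z_annulus": upstream,
                  "leaflet_height": leaflet_height, "free_edge_sets": sets["free_edge"],
                  "belly": sets["belly"]},
    )


# ---------------------------------------------------------------------------
# idealized left ventricle


def default_lv_volume_waveform(edv_ml: float = 112.0, esv_ml: float = 47.0,
                               period: float = 0.8) -> tuple[np.ndarray, np.ndarray]:
    """Ten-phase cavity-volume keyframes over one cycle (ml).

    The cycle starts at end-diastole / early systole; ejection runs to
    end-systole around 0.4 T, followed by early (E) and atrial (A)
    filling waves.  Shapes are normalized so min = ESV and max = EDV.
    """
    shape = np.array([1.0, 0.84, 0.50, 0.17, 0.0, 0.05, 0.38, 0.66, 0.83, 0.94])
    times = np.linspace(0.0, period, 11)
    vols = esv_ml + (edv_ml - esv_ml) * shape
    return times, np.append(vols, vols[0])


def aortic_pressure_waveform(period: float = 0.8, systolic: float = 120.0,
                             diastolic: float = 80.0):
    """Parametric two-phase physiological aortic pressure (mmHg):
    a systolic pulse riding on an exponential diastolic decay."""

    def wf(t: float) -> float:
        tt = np.mod(t, period)
        ts = 0.37 * period
        if tt < ts:
            return diastolic + (systolic - diastolic) * np.sin(np.pi * tt / ts) ** 2
        return diastolic + 5.0 * np.exp(-3.0 * (tt - ts) / period) - 5.0

    return wf


def mesh_volume(nodes: np.ndarray, tris: np.ndarray) -> float:
    """Volume enclosed by a closed triangulated surface (divergence
    theorem; orientation-consistent outward normals assumed)."""
    a = nodes[tris[:, 0]]
    b = nodes[tris[:, 1]]
    c = nodes[tris[:, 2]]
    return float(np.abs(np.einsum("ij,ij->i", a, np.cross(b, c)).sum()) / 6.0)


def _half_ellipsoid_params(a: float, c: float, dx: float, n_layers: int = 3):
    """Parameter sample (theta, phi, layer) for the LV wall particles:
    ~dx arc spacing on the reference (end-diastolic) surface."""
    thetas, phis, layers = [], [], []
    quarter = 0.5 * np.pi * c
    n_theta = max(int(np.ceil(quarter / dx)), 3)
    for i in range(n_theta + 1):
        th = 0.5 * np.pi * i / n_theta
        circ = 2.0 * np.pi * a * np.cos(th)
        n_phi = max(int(np.ceil(circ / dx)), 1)
        for j in range(n_phi):
            ph = 2.0 * np.pi * (j + 0.5 * (i % 2)) / n_phi
            for k in range(n_layers):
                thetas.append(th)
                phis.append(ph)
                layers.append(k)
    return np.asarray(thetas), np.asarray(phis), np.asarray(layers)


def _lv_wall_positions(thetas, phis, layer_ids, a: float, c: float, dx: float):
    """Wall particle positions: nominal surface point plus
    (0.5 + layer) dx along the outward surface normal."""
    ct, st = np.cos(thetas), np.sin(thetas)
    x = a * ct * np.cos(phis)
    y = a * ct * np.sin(phis)
    z = -c * st
    n = np.stack([x / a**2, y / a**2, z / c**2], axis=1)
    n /= np.linalg.norm(n, axis=1, keepdims=True)
    off = (0.5 + layer_ids) * dx
    return np.stack([x, y, z], axis=1) + off[:, None] * n


def _half_ellipsoid_mesh(a: float, c: float, n_theta: int = 20, n_phi: int = 40):
    """Closed triangulated surface: half ellipsoid (z <= 0) + flat lid."""
    nodes = [[0.0, 0.0, -c]]
    rows = []
    for i in range(1, n_theta + 1):
        th = 0.5 * np.pi * (1.0 - i / n_theta)   # apex (pi/2) -> equator (0)
        row = []
        for j in range(n_phi):
            ph = 2.0 * np.pi * j / n_phi
            row.append(len(nodes))
            nodes.append([a * np.cos(th) * np.cos(ph),
                          a * np.cos(th) * np.sin(ph),
                          -c * np.sin(th)])
        rows.append(row)
    center_top = len(nodes)
    nodes.append([0.0, 0.0, 0.0])
    tris = []
    first = rows[0]
    for j in range(n_phi):
        tris.append([0, first[j], first[(j + 1) % n_phi]])
    for i in range(len(rows) - 1):
        r0, r1 = rows[i], rows[i + 1]
        for j in range(n_phi):
            j1 = (j + 1) % n_phi
            tris.append([r0[j], r1[j], r0[j1]])
            tris.append([r1[j], r1[j1], r0[j1]])
    last = rows[-1]
    for j in range(n_phi):
        tris.append([last[j], center_top, last[(j + 1) % n_phi]])
    return np.asarray(nodes), np.asarray(tris, dtype=np.int64)


@_register("idealized_lv")
def make_idealized_lv(
    edv_ml: float = 112.0,
    esv_ml: float = 47.0,
    period: float = 0.8,
    dx: float = 0.003,
    orifice_radius: float = 0.0115,
    tube_length: float | None = None,
    aspect: float = 2.0,
    c0: float = 10.0,
    duration: float | None = None,
    with_valve: bool = False,
    seed: int = 0,
) -> Scene:
    """Truncated-ellipsoid left ventricle with prescribed wall motion.

    The cavity is the lower half of an ellipsoid with semi-axes
    (a, a, c = aspect * a), sized so its volume equals EDV; the wall map
    scales the transverse axes so the cavity volume follows the
    ten-keyframe waveform (volume ~ a(t)^2).  The base is closed by a
    rigid lid with a central outlet orifice leading into a straight tube
    extension open at its far end; a flux probe in the tube measures the
    ejected volume.  Cycle begins at end-diastole (early systole).

    ``with_valve=True`` mounts a tri-leaflet membrane valve at the
    orifice (desk-scale stand-in for the aortic valve).
    """
    v_ed = ml_to_m3(edv_ml)
    a0 = (v_ed / (2.0 / 3.0 * np.pi * aspect)) ** (1.0 / 3.0)
    c_ax = aspect * a0
    if tube_length is None:
        tube_length = 2.0 * (2.0 * orifice_radius)
    if duration is None:
        duration = period

    times, vols = default_lv_volume_waveform(edv_ml, esv_ml, period)
    vol_spline_nodes = np.asarray(vols, dtype=float)
    scales = np.sqrt(vol_spline_nodes / vol_spline_nodes[0])

    # --- frozen-particle wall: three layers of dummy particles attached
    # along the outward normal of the *nominal* cavity surface, so the
    # hydraulic boundary (half a spacing inside the innermost layer)
    # coincides with the nominal ellipsoid at every instant of the cycle
    thetas, phis, layer_ids = _half_ellipsoid_params(a0, c_ax, dx)
    pts_wall = _lv_wall_positions(thetas, phis, layer_ids, a0, c_ax, dx)

    # rigid lid: frozen annulus just above the base plane
    lid_pts = lattice_box([-a0 - 4 * dx, -a0 - 4 * dx, 0.0],
                          [a0 + 4 * dx, a0 + 4 * dx, 2.5 * dx], dx)
    r_lid = np.hypot(lid_pts[:, 0], lid_pts[:, 1])
    lid_pts = lid_pts[(r_lid >= orifice_radius) & (r_lid < a0 + 4 * dx)]
    # outlet tube shell
    shell_pts = lattice_box([-orifice_radius - 3 * dx, -orifice_radius - 3 * dx, 0.0],
                            [orifice_radius + 3 * dx, orifice_radius + 3 * dx,
                             tube_length], dx)
    r_sh = np.hypot(shell_pts[:, 0], shell_pts[:, 1])
    shell_pts = shell_pts[(r_sh >= orifice_radius) & (r_sh < orifice_radius + 2.5 * dx)
                          & (shell_pts[:, 2] > 2.5 * dx)]

    # --- fluid lattice: cavity interior + tube stub up to the flux plane
    z_plane = min(0.5 * tube_length, 8 * dx)
    cav = lattice_box([-a0, -a0, -c_ax], [a0, a0, 0.0], dx)
    u = (np.hypot(cav[:, 0], cav[:, 1]) / (a0 - 0.5 * dx)) ** 2 \
        + (cav[:, 2] / (c_ax - 0.5 * dx)) ** 2
    cav = cav[u < 1.0]
    tube_f = lattice_box([-orifice_radius, -orifice_radius, 0.0],
                         [orifice_radius, orifice_radius, z_plane], dx)
    tube_f = tube_f[np.hypot(tube_f[:, 0], tube_f[:, 1]) < orifice_radius - 0.5 * dx]
    pts_fluid = np.vstack([cav, tube_f])
    pts_frozen = np.vstack([pts_wall, lid_pts, shell_pts])
    fluid = _assemble_fluid(pts_fluid, pts_frozen, dx, dim=3)
    n_f = len(pts_fluid)
    wall_ids = np.arange(n_f, n_f + len(pts_wall))

    # --- wall motion: the transverse semi-axis follows the volume spline
    # (V ~ a^2 at fixed long axis); layer offsets ride the surface normal
    from scipy.interpolate import CubicSpline
    s_spline = CubicSpline(times, scales, bc_type="periodic")

    def wall_map(t, ref, eps=1e-5):
        tt = np.mod(t, period)
        s = float(s_spline(tt))
        pos = _lv_wall_positions(thetas, phis, layer_ids, s * a0, c_ax, dx)
        sp = float(s_spline(np.mod(tt + eps, period)))
        sm = float(s_spline(np.mod(tt - eps, period)))
        pos_p = _lv_wall_positions(thetas, phis, layer_ids, sp * a0, c_ax, dx)
        pos_m = _lv_wall_positions(thetas, phis, layer_ids, sm * a0, c_ax, dx)
        vel = (pos_p - pos_m) / (2.0 * eps)
        return pos, vel

    wall_motion = WallMotion(indices=wall_ids, reference=pts_wall.copy(),
                             mapping=wall_map)

    kernel = KernelSpec(h=H_FACTOR * dx, dim=3)
    eos = EquationOfState(rho0=RHO_BLOOD, c0=c0)
    dt = CFL * kernel.h / (c0 + 2.0)

    # --- reporting mesh (closed) + keyframe displacement track
    mesh_nodes, mesh_tris = _half_ellipsoid_mesh(a0, c_ax)
    disp_frames = []
    for s in scales:
        scaled = mesh_nodes.copy()
        scaled[:, 0] *= s
        scaled[:, 1] *= s
        disp_frames.append(scaled - mesh_nodes)
    track = PrescribedMotionTrack(times, np.asarray(disp_frames), periodic=True)
    wall_mesh = StructuralMesh(nodes=mesh_nodes, triangles=mesh_tris,
                               thickness=1e-3,
                               membrane_material=TISSUE_PARAMETERS["av_leaflet"])
    wall_struct = Structure(
        name="lv_wall", mesh=wall_mesh, state=StructuralState.rest(wall_mesh),
        contact=ContactConfig(stiffness=1.0, thickness=dx), rigid=True,
        track=track, couple=False,
    )
    structures = [wall_struct]

    if with_valve:
        vmesh, vsets = tri_leaflet_valve_mesh(
            annulus_radius=orifice_radius, leaflet_height=0.6 * orifice_radius,
            z_annulus=2.5 * dx + 0.5 * dx,
        )
        m_p = RHO_BLOOD * dx**3
        vcontact = ContactConfig.auto(m_p, dt, dx, damping_ratio=0.3)
        structures.append(Structure(
            name="valve", mesh=vmesh, state=StructuralState.rest(vmesh),
            contact=vcontact,
            fixed_nodes=np.asarray(vsets["annulus"], dtype=np.int64),
            substeps=8, damping=400.0,
        ))

    flux = FluxProbe(center=np.array([0.0, 0.0, z_plane]),
                     normal=np.array([0.0, 0.0, 1.0]), radius=orifice_radius)
    return Scene(
        name="idealized_lv", fluid=fluid, kernel=kernel, eos=eos,
        dt=dt, duration=duration, dx=dx,
        wall_motions=[wall_motion],
        structures=structures,
        flux_probes={"outlet": flux},
        artificial_visc_alpha=0.15,
        metadata={
            "edv_ml": edv_ml, "esv_ml": esv_ml, "period": period,
            "a0": a0, "c_ax": c_ax, "orifice_radius": orifice_radius,
            "keyframe_times": times, "keyframe_volumes_ml": vols,
            "volume_spline": s_spline, "z_plane": z_plane,
            "volume_of_t": lambda t: float(
                s_spline(np.mod(t, period)) ** 2 * vol_spline_nodes[0]),
        },
    )
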