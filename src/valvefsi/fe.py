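"""Explicit-dynamics finite-element solver for valve tissue.

Leaflets are discretized as constant-strain membrane triangles carrying
the anisotropic MHGO law under a plane-stress condition: the
through-thickness stretch of each element is solved so that the normal
Cauchy stress vanishes, with near-incompressibility enforced by the
volumetric penalty of the energy.  Chordae tendineae are two-node truss
elements with the Ogden law, slack in compression, and may branch into
fork-shaped insertions simply by sharing insertion nodes.  Bending
stiffness is neglected (membrane kinematics) -- a documented limitation
relative to shell or solid discretizations.

Time integration is explicit central difference with a row-sum lumped
mass matrix and optional mass-proportional damping.  Prescribed-motion
node sets (annulus attachments, chordal origins) overwrite computed
kinematics every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .materials import MHGOParams, OgdenParams, ogden_fiber_tension

__all__ = ["StructuralMesh", "StructuralState", "membrane_internal_forces",
           "truss_internal_forces", "internal_forces", "lumped_mass",
           "step_structure", "plane_stress_stretch"]

KPA = 1.0e3  # material laws carry kPa; forces are assembled in SI


@dataclass
class StructuralMesh:
    """Reference configuration of a tissue structure.

    ``fiber_frames[e]`` holds the (circumferential, radial) unit vectors
    of element ``e`` in its reference plane; the two MHGO fiber families
    lie at +/- theta about the circumferential axis.
    """

    nodes: np.ndarray                        # (N, 3) reference coords, m
    triangles: np.ndarray = None             # (M, 3) int
    thickness: np.ndarray | float = 4.0e-4   # m, scalar or (M,)
    fiber_frames: np.ndarray = None          # (M, 2, 3)
    membrane_material: MHGOParams | None = None
    trusses: np.ndarray = None               # (K, 2) int
    truss_area: np.ndarray | float = 4.0e-7  # m^2, scalar or (K,)
    truss_material: OgdenParams | None = None
    density: float = 1100.0                  # tissue density, kg/m^3
    membrane_viscosity: float = 0.0          # Kelvin-Voigt in-plane viscosity, kPa s
    tension_field: bool = False              # wrinkling model: no compressive stress
    tension_field_residual: float = 0.1      # kept fraction of compressive stress
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.ascontiguousarray(self.nodes, dtype=float)
        n = self.nodes.shape[0]
        self.triangles = (np.zeros((0, 3), dtype=np.int64) if self.triangles is None
                          else np.ascontiguousarray(self.triangles, dtype=np.int64))
        self.trusses = (np.zeros((0, 2), dtype=np.int64) if self.trusses is None
                        else np.ascontiguousarray(self.trusses, dtype=np.int64))
        m, k = self.triangles.shape[0], self.trusses.shape[0]
        self.thickness = np.broadcast_to(np.asarray(self.thickness, dtype=float), (m,)).copy()
        self.truss_area = np.broadcast_to(np.asarray(self.truss_area, dtype=float), (k,)).copy()
        for name, conn in (("triangles", self.triangles), ("trusses", self.trusses)):
            if conn.size and (conn.min() < 0 or conn.max() >= n):
                raise ValueError(f"{name} reference nodes outside [0, {n})")
        if m and self.fiber_frames is None:
            self.fiber_frames = default_fiber_frames(self.nodes, self.triangles)
        if self.fiber_frames is not None:
            self.fiber_frames = np.ascontiguousarray(self.fiber_frames, dtype=float)
        self.validate()
        self._precompute()

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def validate(self) -> None:
        n = self.n_nodes
        for name, conn in (("triangles", self.triangles), ("trusses", self.trusses)):
            if conn.size and (conn.min() < 0 or conn.max() >= n):
                raise ValueError(f"{name} reference nodes outside [0, {n})")
        if np.any(self.thickness <= 0.0):
            raise ValueError("membrane thickness must be positive")
        if np.any(self.truss_area <= 0.0):
            raise ValueError("truss cross-section area must be positive")
        m = self.triangles.shape[0]
        if m:
            ff = self.fiber_frames
            if ff.shape != (m, 2, 3):
                raise ValueError("fiber_frames must have shape (n_elements, 2, 3)")
            norms = np.linalg.norm(ff, axis=2)
            if not np.allclose(norms, 1.0, atol=1e-8):
                raise ValueError("fiber frame vectors must be unit length")
            dots = np.einsum("ei,ei->e", ff[:, 0], ff[:, 1])
            if not np.allclose(dots, 0.0, atol=1e-8):
                raise ValueError("fiber frame vectors must be orthogonal")

    def _precompute(self) -> None:
        tri = self.triangles
        if tri.shape[0]:
            x = self.nodes
            e1 = self.fiber_frames[:, 0]
            e2 = self.fiber_frames[:, 1]
            d1 = x[tri[:, 1]] - x[tri[:, 0]]
            d2 = x[tri[:, 2]] - x[tri[:, 0]]
            # reference edge matrix in the local (circ, rad) frame
            dm = np.empty((tri.shape[0], 2, 2))
            dm[:, 0, 0] = np.einsum("ei,ei->e", d1, e1)
            dm[:, 1, 0] = np.einsum("ei,ei->e", d1, e2)
            dm[:, 0, 1] = np.einsum("ei,ei->e", d2, e1)
            dm[:, 1, 1] = np.einsum("ei,ei->e", d2, e2)
            det = dm[:, 0, 0] * dm[:, 1, 1] - dm[:, 0, 1] * dm[:, 1, 0]
            if np.any(np.abs(det) < 1e-18):
                raise ValueError("degenerate reference triangle")
            self._dm_inv = np.empty_like(dm)
            self._dm_inv[:, 0, 0] = dm[:, 1, 1] / det
            self._dm_inv[:, 1, 1] = dm[:, 0, 0] / det
            self._dm_inv[:, 0, 1] = -dm[:, 0, 1] / det
            self._dm_inv[:, 1, 0] = -dm[:, 1, 0] / det
            self._area0 = 0.5 * np.abs(det)
        if self.trusses.shape[0]:
            d = self.nodes[self.trusses[:, 1]] - self.nodes[self.trusses[:, 0]]
            self._truss_len0 = np.linalg.norm(d, axis=1)
            if np.any(self._truss_len0 <= 0.0):
                raise ValueError("zero-length truss element")

    def current_nodes(self, disp: np.ndarray) -> np.ndarray:
        return self.nodes + disp


def default_fiber_frames(nodes: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """In-plane orthonormal frame per element: first edge direction and
    its in-plane perpendicular.  Scenes with a physiological fiber
    architecture supply their own circumferential/radial frames."""
    d1 = nodes[triangles[:, 1]] - nodes[triangles[:, 0]]
    d2 = nodes[triangles[:, 2]] - nodes[triangles[:, 0]]
    e1 = d1 / np.linalg.norm(d1, axis=1, keepdims=True)
    nrm = np.cross(d1, d2)
    nrm /= np.linalg.norm(nrm, axis=1, keepdims=True)
    e2 = np.cross(nrm, e1)
    return np.stack([e1, e2], axis=1)


@dataclass
class StructuralState:
    disp: np.ndarray   # (N, 3) displacements, m
    vel: np.ndarray    # (N, 3) velocities, m/s

    @classmethod
    def rest(cls, mesh: StructuralMesh) -> "StructuralState":
        return cls(np.zeros_like(mesh.nodes), np.zeros_like(mesh.nodes))

    def copy(self) -> "StructuralState":
        return StructuralState(self.disp.copy(), self.vel.copy())


# ---------------------------------------------------------------------------
# vectorized plane-stress MHGO over elements


def _mhgo_block_S(c2mat: np.ndarray, lam3: np.ndarray, p: MHGOParams):
    """Second PK stress (kPa) for block-diagonal C = diag(C2, lam3^2),
    vectorized over elements.  Returns (S2 (m,2,2), S33 (m,))."""
    det2 = c2mat[:, 0, 0] * c2mat[:, 1, 1] - c2mat[:, 0, 1] * c2mat[:, 1, 0]
    J = np.sqrt(np.maximum(det2, 0.0)) * lam3
    if np.any(J <= 0.0):
        raise ValueError("non-positive Jacobian: membrane element inversion")
    jm23 = J ** (-2.0 / 3.0)
    tr2 = c2mat[:, 0, 0] + c2mat[:, 1, 1]
    i1b = jm23 * (tr2 + lam3**2)

    c2inv = np.empty_like(c2mat)
    c2inv[:, 0, 0] = c2mat[:, 1, 1] / det2
    c2inv[:, 1, 1] = c2mat[:, 0, 0] / det2
    c2inv[:, 0, 1] = -c2mat[:, 0, 1] / det2
    c2inv[:, 1, 0] = -c2mat[:, 1, 0] / det2
    inv_l32 = 1.0 / lam3**2

    psi1 = p.c1 * p.c2 * np.exp(np.minimum(p.c2 * (i1b - 3.0), 60.0))
    S2 = np.zeros_like(c2mat)
    S33 = np.zeros_like(lam3)
    fibers2 = p.fiber_directions()[:, :2]  # in-plane components
    for a in fibers2:
        aa = np.outer(a, a)
        i4raw = np.einsum("i,eij,j->e", a, c2mat, a)
        i4b = jm23 * i4raw
        e = p.kappa * i1b + (1.0 - 3.0 * p.kappa) * i4b - 1.0
        act = e > 0.0
        g = np.where(act, p.k1 * e * np.exp(np.minimum(p.k2 * e * e, 60.0)), 0.0)
        psi1 = psi1 + g * p.kappa
        psi4 = g * (1.0 - 3.0 * p.kappa)
        S2 += 2.0 * psi4[:, None, None] * (
            jm23[:, None, None] * aa[None, :, :] - (i4b / 3.0)[:, None, None] * c2inv
        )
        S33 += 2.0 * psi4 * (-(i4b / 3.0) * inv_l32)
    eye2 = np.eye(2)
    S2 += 2.0 * psi1[:, None, None] * (
        jm23[:, None, None] * eye2[None, :, :] - (i1b / 3.0)[:, None, None] * c2inv
    )
    S33 += 2.0 * psi1 * (jm23 - (i1b / 3.0) * inv_l32)
    psiJ = 2.0 / p.D * (J - 1.0)
    S2 += (psiJ * J)[:, None, None] * c2inv
    S33 += psiJ * J * inv_l32
    return S2, S33


def _clamp_compressive(S2: np.ndarray, residual: float = 0.0) -> np.ndarray:
    """Scale the negative principal values of symmetric 2x2 stresses
    down to ``residual`` of their elastic value."""
    a = S2[:, 0, 0]
    b = S2[:, 1, 1]
    c = S2[:, 0, 1]
    tr = 0.5 * (a + b)
    disc = np.sqrt(np.maximum(0.25 * (a - b) ** 2 + c * c, 0.0))
    l1 = tr + disc
    l2 = tr - disc
    if np.all(l2 >= 0.0):
        return S2
    # eigenvectors of the 2x2 symmetric matrix
    theta = 0.5 * np.arctan2(2.0 * c, a - b)
    ct, st = np.cos(theta), np.sin(theta)
    l1c = np.where(l1 >= 0.0, l1, residual * l1)
    l2c = np.where(l2 >= 0.0, l2, residual * l2)
    out = np.empty_like(S2)
    out[:, 0, 0] = l1c * ct * ct + l2c * st * st
    out[:, 1, 1] = l1c * st * st + l2c * ct * ct
    out[:, 0, 1] = (l1c - l2c) * ct * st
    out[:, 1, 0] = out[:, 0, 1]
    return out


def plane_stress_stretch(
    c2mat: np.ndarray, params: MHGOParams, tol: float = 1e-10, max_iter: int = 40,
    lam3_init: np.ndarray | None = None,
) -> np.ndarray:
    """Through-thickness stretch ``lam3`` solving S33 = 0 per element.

    Newton iteration with a numerical tangent; the incompressible guess
    ``lam3 = 1/sqrt(det C2)`` is an excellent starting point because the
    volumetric penalty (1/D, with D = 1e-5 kPa^-1) keeps J near one.
    Callers stepping in time may pass the previous solution as a warm
    start.
    """
    det2 = c2mat[:, 0, 0] * c2mat[:, 1, 1] - c2mat[:, 0, 1] * c2mat[:, 1, 0]
    if np.any(det2 <= 0.0):
        raise ValueError("non-positive in-plane metric: membrane element inversion")
    lam3 = 1.0 / np.sqrt(det2) if lam3_init is None else lam3_init.copy()
    scale_ref = 2.0 / params.D  # penalty stiffness sets the residual scale
    for _ in range(max_iter):
        _, s33 = _mhgo_block_S(c2mat, lam3, params)
        if np.all(np.abs(s33) < tol * scale_ref):
            break
        eps = 1e-7 * np.maximum(lam3, 1e-3)
        _, s33p = _mhgo_block_S(c2mat, lam3 + eps, params)
        ds = (s33p - s33) / eps
        bad = np.abs(ds) < 1e-30
        step = np.where(bad, 0.0, s33 / np.where(bad, 1.0, ds))
        step = np.clip(step, -0.2 * lam3, 0.2 * lam3)
        lam3 = lam3 - step
        lam3 = np.maximum(lam3, 1e-3)
    else:
        _, s33 = _mhgo_block_S(c2mat, lam3, params)
        if np.any(np.abs(s33) > 1e-6 * scale_ref):
            raise RuntimeError("plane-stress thickness solve failed to converge")
    return lam3


def membrane_internal_forces(
    mesh: StructuralMesh, disp: np.ndarray, vel: np.ndarray | None = None
) -> tuple[np.ndarray, dict]:
    """Nodal internal forces (N) of the membrane triangles.

    Per element: the in-plane deformation gradient maps the local
    reference frame to the deformed triangle; the thickness stretch is
    solved for zero normal stress; the 2nd PK stress is pushed to a
    first PK map and integrated over reference area x thickness.
    Rigid-body motion produces zero force by construction (the stress
    depends on C only).

    Returns (forces (N,3), info dict with per-element 'lam3', 'S2', 'F32').
    """
    f = np.zeros_like(mesh.nodes)
    info: dict = {}
    tri = mesh.triangles
    if tri.shape[0] == 0:
        return f, info
    if mesh.membrane_material is None:
        raise ValueError("mesh has membrane elements but no membrane material")
    x = mesh.current_nodes(disp)
    d1 = x[tri[:, 1]] - x[tri[:, 0]]
    d2 = x[tri[:, 2]] - x[tri[:, 0]]
    dworld = np.stack([d1, d2], axis=2)           # (m, 3, 2)
    f32 = dworld @ mesh._dm_inv                   # (m, 3, 2)
    c2mat = np.einsum("eik,eil->ekl", f32, f32)   # (m, 2, 2)
    warm = getattr(mesh, "_lam3_warm", None)
    if warm is not None and warm.shape[0] != c2mat.shape[0]:
        warm = None
    lam3 = plane_stress_stretch(c2mat, mesh.membrane_material, lam3_init=warm)
    mesh._lam3_warm = lam3
    S2, _ = _mhgo_block_S(c2mat, lam3, mesh.membrane_material)
    if mesh.tension_field:
        # wrinkling (tension-field) model: membranes cannot sustain
        # compressive in-plane stress; negative principal values are
        # reduced to a small residual that preserves mesh integrity
        S2 = _clamp_compressive(S2, mesh.tension_field_residual)
    if vel is not None and mesh.membrane_viscosity > 0.0:
        # Kelvin-Voigt in-plane viscosity: S_visc = eta * dC2/dt (tissue
        # viscoelasticity; also damps membrane wrinkling modes)
        v1 = vel[tri[:, 1]] - vel[tri[:, 0]]
        v2 = vel[tri[:, 2]] - vel[tri[:, 0]]
        f32dot = np.stack([v1, v2], axis=2) @ mesh._dm_inv
        c2dot = (np.einsum("eik,eil->ekl", f32dot, f32)
                 + np.einsum("eik,eil->ekl", f32, f32dot))
        S2 = S2 + mesh.membrane_viscosity * c2dot
    P = f32 @ (S2 * KPA)                          # first PK, (m, 3, 2), Pa
    coeff = (mesh._area0 * mesh.thickness)[:, None, None]
    grad = P @ np.transpose(mesh._dm_inv, (0, 2, 1))   # dW/d(d1,d2), (m,3,2)
    g = coeff * grad
    np.add.at(f, tri[:, 1], -g[:, :, 0])
    np.add.at(f, tri[:, 2], -g[:, :, 1])
    np.add.at(f, tri[:, 0], g[:, :, 0] + g[:, :, 1])
    info["lam3"] = lam3
    info["S2_kpa"] = S2
    info["F32"] = f32
    return f, info


def truss_internal_forces(
    mesh: StructuralMesh, disp: np.ndarray, allow_compression: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Nodal forces (N) and per-element tensions (N) of chordae trusses."""
    f = np.zeros_like(mesh.nodes)
    k = mesh.trusses.shape[0]
    tensions = np.zeros(k)
    if k == 0:
        return f, tensions
    if mesh.truss_material is None:
        raise ValueError("mesh has truss elements but no truss material")
    x = mesh.current_nodes(disp)
    d = x[mesh.trusses[:, 1]] - x[mesh.trusses[:, 0]]
    length = np.linalg.norm(d, axis=1)
    if np.any(length <= 0.0):
        raise ValueError("collapsed truss element")
    lam = length / mesh._truss_len0
    axis = d / length[:, None]
    for e in range(k):
        # material carries kPa; tension assembled in N
        tensions[e] = KPA * ogden_fiber_tension(
            float(lam[e]), mesh.truss_material, float(mesh.truss_area[e]),
            allow_compression=allow_compression,
        )
    fa = tensions[:, None] * axis
    np.add.at(f, mesh.trusses[:, 0], fa)
    np.add.at(f, mesh.trusses[:, 1], -fa)
    return f, tensions


def internal_forces(
    mesh: StructuralMesh, disp: np.ndarray, allow_truss_compression: bool = False,
    vel: np.ndarray | None = None,
) -> np.ndarray:
    """Total internal nodal force vector (membranes + trusses), in N."""
    f_m, _ = membrane_internal_forces(mesh, disp, vel)
    f_t, _ = truss_internal_forces(mesh, disp, allow_truss_compression)
    return f_m + f_t


def lumped_mass(mesh: StructuralMesh) -> np.ndarray:
    """Row-sum lumped nodal masses (kg): a third of each membrane
    element mass per vertex, half of each truss element mass per end."""
    m = np.zeros(mesh.n_nodes)
    if mesh.triangles.shape[0]:
        elem_mass = mesh.density * mesh._area0 * mesh.thickness
        for c in range(3):
            np.add.at(m, mesh.triangles[:, c], elem_mass / 3.0)
    if mesh.trusses.shape[0]:
        elem_mass = mesh.density * mesh.truss_area * mesh._truss_len0
        for c in range(2):
            np.add.at(m, mesh.trusses[:, c], elem_mass / 2.0)
    return m


def step_structure(
    mesh: StructuralMesh,
    state: StructuralState,
    ext_force: np.ndarray,
    dt: float,
    nodal_mass: np.ndarray | None = None,
    damping: float = 0.0,
    prescribed: list | None = None,
    allow_truss_compression: bool = False,
    max_dt: float | None = None,
) -> StructuralState:
    """One central-difference step (in place).

    ``damping`` is a mass-proportional coefficient (1/s).  ``prescribed``
    is a list of ``(node_indices, disp_target, vel_target)`` triples that
    overwrite the computed kinematics (annulus boundaries, chordal
    origins).  ``max_dt``, when given, guards the stable increment.
    """
    if max_dt is not None and dt > max_dt:
        raise ValueError(f"structural dt={dt:.3e} exceeds stable increment {max_dt:.3e}")
    if nodal_mass is None:
        nodal_mass = lumped_mass(mesh)
    f_int = internal_forces(mesh, state.disp, allow_truss_compression, vel=state.vel)
    acc = (ext_force + f_int) / np.maximum(nodal_mass, 1e-30)[:, None]
    acc -= damping * state.vel
    state.vel += dt * acc
    vmax2 = float(np.einsum("ij,ij->i", state.vel, state.vel).max(initial=0.0))
    if vmax2 > 1.0e6:  # > 1 km/s: the explicit step has gone unstable
        raise FloatingPointError(
            "structural velocities diverged: reduce the substep size or "
            "soften the contact")
    state.disp += dt * state.vel
    if prescribed:
        for idx, dtar, vtar in prescribed:
            idx = np.asarray(idx)
            state.disp[idx] = dtar
            state.vel[idx] = vtar
    return state
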