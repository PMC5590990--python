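"""Node-to-surface penalty contact between SPH particles and FE surfaces.

Each fluid particle within the contact thickness of a triangular face
receives a normal penalty force proportional to its penetration depth;
the exact opposite force is distributed to the face nodes by the
barycentric weights of the closest point, so the coupled system
conserves linear momentum to machine precision (Newton's third law by
construction).  Together with kernel smoothing near the interface this
approximates no-penetration and (loosely) no-slip; the tangential
response is frictionless by default with an optional velocity-
proportional damping.

The penalty stiffness defaults to ``k = m_p / (beta dt^2)`` with
``beta ~ 4``, which keeps the contact stable at the fluid CFL time step
without a separate stability limit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numba
import numpy as np
from scipy.spatial import cKDTree

__all__ = ["ContactConfig", "ContactSet", "detect_contacts", "penalty_forces"]


@dataclass
class ContactConfig:
    """Penalty-contact parameters.

    stiffness : N/m of penetration per particle (auto-scaled from
        particle mass and time step when built via :meth:`auto`).
    thickness : contact detection distance, m (default 0.8 x spacing).
    normal_damping : N s/m, velocity-proportional normal damping.
    tangential_damping : N s/m, optional tangential coupling emulating
        no-slip more closely (0 = frictionless).
    """

    stiffness: float
    thickness: float
    normal_damping: float = 0.0
    tangential_damping: float = 0.0

    def __post_init__(self) -> None:
        if self.stiffness <= 0.0:
            raise ValueError("contact stiffness must be positive")
        if self.thickness <= 0.0:
            raise ValueError("contact thickness must be positive")

    @classmethod
    def auto(
        cls,
        particle_mass: float,
        dt: float,
        spacing: float,
        beta: float = 4.0,
        damping_ratio: float = 0.0,
        tangential_damping: float = 0.0,
    ) -> "ContactConfig":
        """Stiffness from the stability heuristic ``k = m/(beta dt^2)``."""
        k = particle_mass / (beta * dt * dt)
        c = 2.0 * damping_ratio * np.sqrt(k * particle_mass)
        return cls(stiffness=k, thickness=0.8 * spacing,
                   normal_damping=c, tangential_damping=tangential_damping)


@dataclass
class ContactSet:
    """Active contacts: parallel arrays of particle index, element index,
    penetration depth (m), push direction (unit, towards the particle
    side), and barycentric weights of the closest point."""

    particle: np.ndarray   # (c,) int
    element: np.ndarray    # (c,) int
    depth: np.ndarray      # (c,) float, >= 0
    normal: np.ndarray     # (c, 3)
    bary: np.ndarray       # (c, 3)

    @property
    def n(self) -> int:
        return self.particle.shape[0]

    @classmethod
    def empty(cls) -> "ContactSet":
        return cls(np.zeros(0, np.int64), np.zeros(0, np.int64),
                   np.zeros(0), np.zeros((0, 3)), np.zeros((0, 3)))


@numba.njit(cache=True)
def _closest_point_triangle(p, a, b, c):
    """Closest point on triangle abc to p; returns (point, bary)."""
    ab = b - a
    ac = c - a
    ap = p - a
    d1 = ab @ ap
    d2 = ac @ ap
    if d1 <= 0.0 and d2 <= 0.0:
        return a, np.array([1.0, 0.0, 0.0])
    bp = p - b
    d3 = ab @ bp
    d4 = ac @ bp
    if d3 >= 0.0 and d4 <= d3:
        return b, np.array([0.0, 1.0, 0.0])
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        v = d1 / (d1 - d3)
        return a + v * ab, np.array([1.0 - v, v, 0.0])
    cp = p - c
    d5 = ab @ cp
    d6 = ac @ cp
    if d6 >= 0.0 and d5 <= d6:
        return c, np.array([0.0, 0.0, 1.0])
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        w = d2 / (d2 - d6)
        return a + w * ac, np.array([1.0 - w, 0.0, w])
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        w = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return b + w * (c - b), np.array([0.0, 1.0 - w, w])
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return a + ab * v + ac * w, np.array([1.0 - v - w, v, w])


@numba.njit(cache=True)
def _detect_kernel(pos, verts, tris, cand_p, cand_t, thickness,
                   out_p, out_t, out_depth, out_normal, out_bary, out_point):
    m = 0
    for k in range(cand_p.shape[0]):
        ip = cand_p[k]
        it = cand_t[k]
        a = verts[tris[it, 0]]
        b = verts[tris[it, 1]]
        c = verts[tris[it, 2]]
        n = np.cross(b - a, c - a)
        nn = np.sqrt(n @ n)
        if nn < 1e-20:
            continue  # degenerate face, excluded
        n = n / nn
        p = pos[ip]
        cp, bary = _closest_point_triangle(p, a, b, c)
        dvec = p - cp
        dist = np.sqrt(dvec @ dvec)
        if dist >= thickness:
            continue
        side = dvec @ n
        if dist > 1e-14:
            if side >= 0.0:
                push = n
            else:
                push = -n
        else:
            push = n
        out_p[m] = ip
        out_t[m] = it
        out_depth[m] = thickness - dist
        out_normal[m] = push
        out_bary[m] = bary
        out_point[m] = cp
        m += 1
    return m


def detect_contacts(
    particle_pos: np.ndarray,
    surface_nodes: np.ndarray,
    triangles: np.ndarray,
    config: ContactConfig,
    warn_degenerate: bool = True,
) -> ContactSet:
    """Find every (particle, face) pair closer than the contact thickness.

    A particle may legitimately contact several faces (e.g. across a
    fold); a particle whose closest point falls exactly on a shared edge
    or vertex of several faces is assigned only to the lowest-index face
    among the duplicates (deterministic tie-break).  Degenerate zero-
    area faces are excluded with a warning.
    """
    particle_pos = np.ascontiguousarray(particle_pos, dtype=float)
    verts = np.ascontiguousarray(surface_nodes, dtype=float)
    tris = np.ascontiguousarray(triangles, dtype=np.int64)
    if tris.shape[0] == 0 or particle_pos.shape[0] == 0:
        return ContactSet.empty()

    tv = verts[tris]                      # (m, 3, 3)
    cent = tv.mean(axis=1)
    circum = np.linalg.norm(tv - cent[:, None, :], axis=2).max(axis=1)
    areas = 0.5 * np.linalg.norm(
        np.cross(tv[:, 1] - tv[:, 0], tv[:, 2] - tv[:, 0]), axis=1
    )
    n_degen = int((areas < 1e-20).sum())
    if n_degen and warn_degenerate:
        warnings.warn(f"{n_degen} degenerate (zero-area) face(s) excluded from contact",
                      RuntimeWarning)

    radius = float(circum.max()) + config.thickness
    tree = cKDTree(cent)
    ptree = cKDTree(particle_pos)
    groups = ptree.query_ball_tree(tree, radius)
    n_cand = sum(len(g) for g in groups)
    if n_cand == 0:
        return ContactSet.empty()
    cand_p = np.empty(n_cand, np.int64)
    cand_t = np.empty(n_cand, np.int64)
    ofs = 0
    for ip, g in enumerate(groups):
        for it in sorted(g):
            cand_p[ofs] = ip
            cand_t[ofs] = it
            ofs += 1

    out_p = np.empty(n_cand, np.int64)
    out_t = np.empty(n_cand, np.int64)
    out_depth = np.empty(n_cand)
    out_normal = np.empty((n_cand, 3))
    out_bary = np.empty((n_cand, 3))
    out_point = np.empty((n_cand, 3))
    m = _detect_kernel(particle_pos, verts, tris, cand_p, cand_t, config.thickness,
                       out_p, out_t, out_depth, out_normal, out_bary, out_point)
    if m == 0:
        return ContactSet.empty()
    keep = np.zeros(m, dtype=np.bool_)
    _smooth_patch_filter(out_p[:m], out_depth[:m], out_normal[:m], keep)
    cs = ContactSet(out_p[:m][keep].copy(), out_t[:m][keep].copy(),
                    out_depth[:m][keep].copy(), out_normal[:m][keep].copy(),
                    out_bary[:m][keep].copy())
    return _dedupe_shared_features(cs, out_point[:m][keep].copy())


@numba.njit(cache=True)
def _smooth_patch_filter(particles, depths, normals, keep, cos_same=0.85):
    """Per particle, keep only the deepest contact of each smooth
    surface patch: contacts whose push directions agree within ~30 deg
    are duplicates of the same surface (coplanar neighbour faces seen
    across an edge); genuinely folded surfaces (distinct normals) keep
    one contact per fold.  Candidates arrive grouped by particle."""
    n = particles.shape[0]
    i = 0
    while i < n:
        j = i
        while j < n and particles[j] == particles[i]:
            j += 1
        # insertion sort of the group by depth, descending
        order = np.arange(i, j)
        for a in range(i + 1, j):
            key = order[a - i]
            b = a - i - 1
            while b >= 0 and depths[order[b]] < depths[key]:
                order[b + 1] = order[b]
                b -= 1
            order[b + 1] = key
        for a in range(i, j):
            ia = order[a - i]
            dup = False
            for b in range(i, a):
                ib = order[b - i]
                if not keep[ib]:
                    continue
                dot = (normals[ia, 0] * normals[ib, 0]
                       + normals[ia, 1] * normals[ib, 1]
                       + normals[ia, 2] * normals[ib, 2])
                if dot > cos_same:
                    dup = True
                    break
            keep[ia] = not dup
        i = j


def _dedupe_shared_features(cs: ContactSet, points: np.ndarray) -> ContactSet:
    """Drop duplicate contacts where the same particle's closest point is
    a shared edge/vertex of several faces; the lowest element index wins."""
    if cs.n < 2:
        return cs
    keep = np.ones(cs.n, dtype=bool)
    order = np.lexsort((cs.element, cs.particle))
    for a_i in range(len(order)):
        i = order[a_i]
        if not keep[i]:
            continue
        for a_j in range(a_i + 1, len(order)):
            j = order[a_j]
            if cs.particle[j] != cs.particle[i]:
                break
            if keep[j] and np.linalg.norm(points[j] - points[i]) < 1e-12:
                keep[j] = False  # i has the lower element index (sorted)
    if keep.all():
        return cs
    return ContactSet(cs.particle[keep], cs.element[keep], cs.depth[keep],
                      cs.normal[keep], cs.bary[keep])


def penalty_forces_current(
    contacts: ContactSet,
    config: ContactConfig,
    particle_pos: np.ndarray,
    nodes_current: np.ndarray,
    triangles: np.ndarray,
    n_particles: int,
    n_nodes: int,
    particle_vel: np.ndarray | None = None,
    node_vel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalty forces for an existing contact set, with the penetration
    re-evaluated against the *current* surface geometry.

    Used inside the structural substep loop so the contact acts as a
    true spring while the surface yields (the pairing from
    :func:`detect_contacts` is kept fixed over the fluid step; the gap
    is measured as plane distance at the stored barycentric point, and
    contacts that have separated exert no force).  Particle forces and
    nodal reactions still balance exactly.
    """
    fp = np.zeros((n_particles, 3))
    fn = np.zeros((n_nodes, 3))
    if contacts.n == 0:
        return fp, fn
    tris = np.asarray(triangles, dtype=np.int64)[contacts.element]
    a = nodes_current[tris[:, 0]]
    b = nodes_current[tris[:, 1]]
    c = nodes_current[tris[:, 2]]
    nrm = np.cross(b - a, c - a)
    ln = np.linalg.norm(nrm, axis=1)
    ok = ln > 1e-20
    nrm[ok] /= ln[ok, None]
    cp = (contacts.bary[:, 0, None] * a + contacts.bary[:, 1, None] * b
          + contacts.bary[:, 2, None] * c)
    dvec = particle_pos[contacts.particle] - cp
    gap = np.einsum("ck,ck->c", dvec, nrm)
    depth = config.thickness - np.abs(gap)
    active = ok & (depth > 0.0)
    push = np.where(gap[:, None] >= 0.0, nrm, -nrm)
    force = np.where(active[:, None],
                     config.stiffness * depth[:, None] * push, 0.0)
    if (config.normal_damping > 0.0 or config.tangential_damping > 0.0) and \
            particle_vel is not None and node_vel is not None:
        surf_vel = np.einsum("cj,cjk->ck", contacts.bary, node_vel[tris])
        rel = particle_vel[contacts.particle] - surf_vel
        rel_n = np.einsum("ck,ck->c", rel, push)[:, None] * push
        rel_t = rel - rel_n
        damp = config.normal_damping * rel_n + config.tangential_damping * rel_t
        force = force - np.where(active[:, None], damp, 0.0)
    np.add.at(fp, contacts.particle, force)
    for corner in range(3):
        np.add.at(fn, tris[:, corner], -contacts.bary[:, corner, None] * force)
    return fp, fn


def penalty_forces(
    contacts: ContactSet,
    config: ContactConfig,
    triangles: np.ndarray,
    n_particles: int,
    n_nodes: int,
    particle_vel: np.ndarray | None = None,
    node_vel: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Penalty forces on particles and the equal-opposite nodal reactions.

    Normal force = stiffness x penetration along the push direction;
    optional normal/tangential damping uses the relative velocity of the
    particle against the barycentric surface velocity.  The sum of all
    particle forces and nodal reactions is zero exactly.

    Returns (particle_forces (n_particles, 3), node_forces (n_nodes, 3)).
    """
    fp = np.zeros((n_particles, 3))
    fn = np.zeros((n_nodes, 3))
    if contacts.n == 0:
        return fp, fn
    tris = np.asarray(triangles, dtype=np.int64)
    force = config.stiffness * contacts.depth[:, None] * contacts.normal
    if (config.normal_damping > 0.0 or config.tangential_damping > 0.0) and \
            particle_vel is not None and node_vel is not None:
        tri_nodes = tris[contacts.element]                     # (c, 3)
        surf_vel = np.einsum("cj,cjk->ck", contacts.bary, node_vel[tri_nodes])
        rel = particle_vel[contacts.particle] - surf_vel
        rel_n = np.einsum("ck,ck->c", rel, contacts.normal)[:, None] * contacts.normal
        rel_t = rel - rel_n
        force = force - config.normal_damping * rel_n - config.tangential_damping * rel_t
    np.add.at(fp, contacts.particle, force)
    tri_nodes = tris[contacts.element]
    for corner in range(3):
        np.add.at(fn, tri_nodes[:, corner], -contacts.bary[:, corner, None] * force)
    return fp, fn
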