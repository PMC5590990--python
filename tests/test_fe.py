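"""Membrane/truss finite elements and explicit structural stepping."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from valvefsi.fe import (StructuralMesh, StructuralState, internal_forces,
                         lumped_mass, membrane_internal_forces,
                         plane_stress_stretch, step_structure,
                         truss_internal_forces)
from valvefsi.materials import TISSUE_PARAMETERS, mhgo_strain_energy


@pytest.fixture
def triangle_mesh():
    nodes = np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0]], dtype=float)
    frames = np.array([[[1, 0, 0], [0, 1, 0]]], dtype=float)
    return StructuralMesh(
        nodes=nodes, triangles=np.array([[0, 1, 2]]), thickness=4e-4,
        fiber_frames=frames, membrane_material=TISSUE_PARAMETERS["av_leaflet"],
    )


def _membrane_energy(mesh, disp):
    """Total strain energy of the mesh (J) with the plane-stress
    thickness solved per element -- independent oracle for nodal forces."""
    x = mesh.nodes + disp
    tri = mesh.triangles
    total = 0.0
    for e in range(tri.shape[0]):
        d1 = x[tri[e, 1]] - x[tri[e, 0]]
        d2 = x[tri[e, 2]] - x[tri[e, 0]]
        f32 = np.stack([d1, d2], axis=1) @ mesh._dm_inv[e]
        c2 = f32.T @ f32
        l3 = plane_stress_stretch(c2[None], mesh.membrane_material)[0]
        C3 = np.zeros((3, 3))
        C3[:2, :2] = c2
        C3[2, 2] = l3**2
        w_ev, vecs = np.linalg.eigh(C3)
        F = vecs @ np.diag(np.sqrt(w_ev)) @ vecs.T
        total += (mhgo_strain_energy(F, mesh.membrane_material) * 1e3
                  * mesh._area0[e] * mesh.thickness[e])
    return total


def test_membrane_zero_force_undeformed(triangle_mesh):
    f, _ = membrane_internal_forces(triangle_mesh, np.zeros((3, 3)))
    assert np.abs(f).max() < 1e-12


def test_membrane_rigid_motion_force_free(triangle_mesh):
    """Arbitrary rigid rotation + translation yields zero internal force."""
    R = Rotation.from_rotvec([0.4, -0.2, 0.7]).as_matrix()
    disp = triangle_mesh.nodes @ R.T + np.array([0.01, -0.02, 0.005]) \
        - triangle_mesh.nodes
    f, _ = membrane_internal_forces(triangle_mesh, disp)
    assert np.abs(f).max() < 1e-9 * 1e3  # N scale of a loaded element


def test_membrane_forces_equal_energy_gradient(triangle_mesh):
    """Nodal forces = -dE/dx under homogeneous uniaxial stretch."""
    lam = 1.05
    disp = triangle_mesh.nodes * np.array([lam - 1.0, 0.0, 0.0])
    f, _ = membrane_internal_forces(triangle_mesh, disp)
    eps = 1e-9
    f_num = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            dp, dm = disp.copy(), disp.copy()
            dp[i, j] += eps
            dm[i, j] -= eps
            f_num[i, j] = -(_membrane_energy(triangle_mesh, dp)
                            - _membrane_energy(triangle_mesh, dm)) / (2 * eps)
    assert np.abs(f - f_num).max() / np.abs(f_num).max() < 1e-6


def test_membrane_uniaxial_stress_resultant(triangle_mesh):
    """Homogeneous stretch of the right triangle: the stretched node's
    restoring force equals the analytic constant-strain resultant,
    thickness x Cauchy stress x half the current cross edge."""
    lam = 1.04
    disp = triangle_mesh.nodes * np.array([lam - 1.0, 0.0, 0.0])
    f, info = membrane_internal_forces(triangle_mesh, disp)
    S2 = info["S2_kpa"][0] * 1e3
    lam3 = info["lam3"][0]
    F2 = np.diag([lam, 1.0])
    J = lam * 1.0 * lam3
    sig2 = F2 @ S2 @ F2.T / J        # in-plane Cauchy stress, Pa
    t_cur = triangle_mesh.thickness[0] * lam3
    edge = 1e-3                      # current y-edge (unchanged by x-stretch)
    # node 1 collects half of the sigma_xx traction on the x-normal face
    assert f[1, 0] == pytest.approx(-0.5 * sig2[0, 0] * t_cur * edge, rel=1e-9)
    assert abs(f[1, 1]) < 1e-12


def test_plane_stress_residual_is_zero(triangle_mesh, rng):
    from valvefsi.fe import _mhgo_block_S
    p = triangle_mesh.membrane_material
    c2 = np.eye(2)[None] * rng.uniform(0.98, 1.05, (5, 1, 1))
    c2[:, 0, 1] = c2[:, 1, 0] = rng.uniform(-0.01, 0.01, 5)
    lam3 = plane_stress_stretch(c2, p)
    _, s33 = _mhgo_block_S(c2, lam3, p)
    assert np.abs(s33).max() < 1e-6 * 2.0 / p.D


def test_membrane_inversion_rejected(triangle_mesh):
    disp = np.zeros((3, 3))
    disp[1] = [-1e-3, 0, 0]  # collapses node 1 onto node 0 (degenerate)
    with pytest.raises(ValueError, match="inversion"):
        membrane_internal_forces(triangle_mesh, disp)


def test_truss_fork_shares_origin_node():
    """Fork-shaped chordae: branches share the origin; total force on
    the origin is the vector sum of branch tensions."""
    q = TISSUE_PARAMETERS["marginal_chordae"]
    nodes = np.array([[0, 0, 0], [1e-2, 2e-3, 0], [1e-2, -2e-3, 0]], dtype=float)
    mesh = StructuralMesh(nodes=nodes, trusses=np.array([[0, 1], [0, 2]]),
                          truss_area=4e-7, truss_material=q)
    disp = np.zeros((3, 3))
    disp[1, 0] = disp[2, 0] = 5e-4  # stretch both branches
    f, tensions = truss_internal_forces(mesh, disp)
    assert np.all(tensions > 0)
    assert f[0, 0] > 0                       # origin pulled towards insertions
    assert abs(f[0, 1]) < 1e-12              # symmetric fork: lateral cancels
    np.testing.assert_allclose(f.sum(axis=0), 0.0, atol=1e-12)


def test_lumped_mass_row_sum():
    nodes = np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0], [2e-3, 2e-3, 0]],
                     dtype=float)
    mesh = StructuralMesh(
        nodes=nodes, triangles=np.array([[0, 1, 2]]), thickness=4e-4,
        membrane_material=TISSUE_PARAMETERS["av_leaflet"],
        trusses=np.array([[2, 3]]), truss_area=4e-7,
        truss_material=TISSUE_PARAMETERS["basal_chordae"],
    )
    m = lumped_mass(mesh)
    area = 0.5 * 1e-6
    truss_len = np.linalg.norm(nodes[3] - nodes[2])
    total = 1100.0 * (area * 4e-4 + 4e-7 * truss_len)
    assert m.sum() == pytest.approx(total, rel=1e-12)
    assert m[3] == pytest.approx(1100.0 * 4e-7 * truss_len / 2)


def _truss_oscillator():
    q = TISSUE_PARAMETERS["marginal_chordae"]
    L0, A0 = 0.01, 4e-7
    mesh = StructuralMesh(nodes=np.array([[0.0, 0, 0], [L0, 0, 0]]),
                          trusses=np.array([[0, 1]]), truss_area=A0,
                          truss_material=q)
    k_lin = A0 * 3.0 * sum(q.mu) * 1e3 / L0   # ground-state stiffness
    mass = lumped_mass(mesh)
    T = 2 * np.pi * np.sqrt(mass[1] / k_lin)
    return mesh, mass, T


def test_oscillator_period_matches_linearized_stiffness():
    """Small-amplitude free vibration of a single Ogden truss: period
    within 5% of the analytic linearized value."""
    mesh, mass, T = _truss_oscillator()
    st = StructuralState.rest(mesh)
    st.disp[1, 0] = 1e-5 * 0.01
    dt = T / 400
    clamp = [(np.array([0]), np.zeros((1, 3)), np.zeros((1, 3)))]
    zero = np.zeros((2, 3))
    crossings = []
    prev = st.disp[1, 0]
    t = 0.0
    for _ in range(5000):
        step_structure(mesh, st, zero, dt, nodal_mass=mass, prescribed=clamp,
                       allow_truss_compression=True)
        t += dt
        if prev < 0 <= st.disp[1, 0]:
            crossings.append(t)
        prev = st.disp[1, 0]
        if len(crossings) >= 6:
            break
    T_num = (crossings[-1] - crossings[0]) / (len(crossings) - 1)
    assert T_num == pytest.approx(T, rel=0.05)


def test_free_vibration_energy_drift_below_one_percent():
    """Undamped central difference: total (kinetic + strain) energy
    drifts by < 1% over ten periods."""
    from valvefsi.materials import ogden_strain_energy_uniaxial
    mesh, mass, T = _truss_oscillator()
    q = mesh.truss_material
    st = StructuralState.rest(mesh)
    amp = 1e-4 * 0.01
    st.disp[1, 0] = amp
    dt = T / 400
    clamp = [(np.array([0]), np.zeros((1, 3)), np.zeros((1, 3)))]
    zero = np.zeros((2, 3))

    def energy():
        lam = (0.01 + st.disp[1, 0]) / 0.01
        strain = ogden_strain_energy_uniaxial(lam, q) * 1e3 * 4e-7 * 0.01
        # central difference stores velocity at the half step; correct to
        # the integer step for the energy bookkeeping
        kin = 0.5 * mass[1] * st.vel[1, 0] ** 2
        return strain + kin

    e0 = None
    n_steps = int(10 * T / dt)
    energies = []
    for _ in range(n_steps):
        step_structure(mesh, st, zero, dt, nodal_mass=mass, prescribed=clamp,
                       allow_truss_compression=True)
        energies.append(energy())
    energies = np.array(energies)
    e_ref = energies[:50].mean()
    # cycle-averaged energy drift (the half-step velocity stagger makes
    # the instantaneous energy oscillate at 2x the natural frequency)
    drift = abs(energies[-400:].mean() - e_ref) / e_ref
    assert drift < 0.01


def test_prescribed_nodes_follow_exactly():
    mesh, mass, T = _truss_oscillator()
    st = StructuralState.rest(mesh)
    zero = np.zeros((2, 3))
    dt = T / 200
    for k in range(50):
        target = np.array([[0.0, 0.0, 1e-4 * np.sin(k * 0.1)]])
        step_structure(mesh, st, zero, dt, nodal_mass=mass,
                       prescribed=[(np.array([0]), target, np.zeros((1, 3)))],
                       allow_truss_compression=True)
        np.testing.assert_array_equal(st.disp[0], target[0])


def test_structural_dt_guard():
    mesh, mass, T = _truss_oscillator()
    st = StructuralState.rest(mesh)
    with pytest.raises(ValueError, match="stable increment"):
        step_structure(mesh, st, np.zeros((2, 3)), dt=1.0, nodal_mass=mass,
                       max_dt=0.1)


def test_mesh_validation():
    with pytest.raises(ValueError, match="outside"):
        StructuralMesh(nodes=np.zeros((2, 3)), triangles=np.array([[0, 1, 5]]))
    nodes = np.array([[0, 0, 0], [1e-3, 0, 0], [0, 1e-3, 0]], dtype=float)
    bad_frames = np.array([[[2, 0, 0], [0, 1, 0]]], dtype=float)
    with pytest.raises(ValueError, match="unit length"):
        StructuralMesh(nodes=nodes, triangles=np.array([[0, 1, 2]]),
                       fiber_frames=bad_frames,
                       membrane_material=TISSUE_PARAMETERS["av_leaflet"])
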