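"""Hyperelastic constitutive models for valve tissue.

Two laws are implemented:

* **MHGO** (modified Holzapfel--Gasser--Ogden) for leaflet membranes: an
  exponential isotropic matrix, two dispersed collagen-fiber families at
  +/- theta about the circumferential axis, and a volumetric penalty,

      W = c1 {exp[c2 (I1b - 3)] - 1}
        + k1/(2 k2) sum_{i=1,2} [exp{k2 (kappa I1b + (1-3 kappa) I4ib - 1)^2} - 1]
        + (1/D) (J - 1)^2

  with isochoric invariants ``I1b = tr(Cb)`` and ``I4ib = a_i . Cb a_i``
  of ``Cb = J^(-2/3) C``.  A fiber family contributes only while its
  exponent argument ``kappa I1b + (1-3 kappa) I4ib - 1`` is positive
  (tension-only switch, the standard convention for dispersed collagen).

* **Ogden** (three-term, isotropic) for chordae tendineae trusses,

      W = sum_i 2 mu_i / a_i^2 (l1b^a_i + l2b^a_i + l3b^a_i - 3)

  in modified principal stretches; chordae carry force only in tension
  by default (they go slack in compression).

Stresses are returned as Cauchy stress.  Parameter units follow the
tissue-mechanics convention of kPa; deformation is dimensionless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "MHGOParams",
    "OgdenParams",
    "mhgo_strain_energy",
    "mhgo_cauchy_stress",
    "mhgo_second_pk",
    "ogden_strain_energy_uniaxial",
    "ogden_fiber_tension",
    "TISSUE_PARAMETERS",
]


@dataclass(frozen=True)
class MHGOParams:
    """MHGO leaflet parameters.

    c1 (kPa) and c2 (-) govern the matrix; k1 (kPa) and k2 (-) the fiber
    families; theta_deg is the fiber angle from the circumferential axis
    (two symmetric families at +/- theta); kappa in [0, 1/3] is the fiber
    dispersion (1/3 = isotropic); D (1/kPa) the incompressibility penalty.
    """

    c1: float
    c2: float
    k1: float
    k2: float
    theta_deg: float
    kappa: float
    D: float

    def __post_init__(self) -> None:
        if self.c1 <= 0.0:
            raise ValueError("c1 must be positive")
        if self.k2 <= 0.0:
            raise ValueError("k2 must be positive")
        if not 0.0 <= self.kappa <= 1.0 / 3.0:
            raise ValueError("fiber dispersion kappa must lie in [0, 1/3]")
        if self.D <= 0.0:
            raise ValueError("penalty constant D must be positive")

    def fiber_directions(self) -> np.ndarray:
        """Unit fiber directions of the two families in the local frame
        (circumferential, radial, normal)."""
        th = np.deg2rad(self.theta_deg)
        return np.array(
            [[np.cos(th), np.sin(th), 0.0], [np.cos(th), -np.sin(th), 0.0]]
        )


@dataclass(frozen=True)
class OgdenParams:
    """Three-term Ogden chordae parameters (mu_i in kPa, a_i dimensionless)."""

    mu: tuple[float, float, float]
    a: tuple[float, float, float]

    def __post_init__(self) -> None:
        if sum(m * e for m, e in zip(self.mu, self.a)) <= 0.0:
            raise ValueError("sum(mu_i a_i) must be positive (ground-state stiffness)")


#: Tissue parameter sets fitted to multiprotocol biaxial/uniaxial testing
#: of healthy human valve tissue (leaflets: MHGO rows; chordae: Ogden rows).
TISSUE_PARAMETERS: dict[str, MHGOParams | OgdenParams] = {
    "av_leaflet": MHGOParams(1.738, 11.368, 2159.4, 1158.9, 4.59, 0.2359, 1.00e-5),
    "mv_anterior_leaflet": MHGOParams(0.1245, 13.665, 11.007, 84.848, 13.09, 0.0800, 1.00e-5),
    "mv_posterior_leaflet": MHGOParams(0.0502, 15.004, 3.021, 144.48, 25.51, 0.0534, 1.00e-5),
    "basal_chordae": OgdenParams((10256.1, 10653.8, 10671.3), (16.579, 16.554, 16.554)),
    "strut_chordae": OgdenParams((24341.7, 10331.9, 14913.6), (11.338, 11.167, 11.188)),
    "marginal_chordae": OgdenParams((12995.5, 13082.9, 12869.7), (15.651, 15.683, 15.662)),
}


# ---------------------------------------------------------------------------
# MHGO


def _invariants(F: np.ndarray, fibers: np.ndarray):
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ValueError(f"non-positive Jacobian det(F) = {J}: element inversion")
    C = F.T @ F
    Cb = J ** (-2.0 / 3.0) * C
    i1b = float(np.trace(Cb))
    i4b = np.array([float(a @ Cb @ a) for a in fibers])
    return J, C, Cb, i1b, i4b


def mhgo_strain_energy(F: np.ndarray, params: MHGOParams) -> float:
    """MHGO strain energy density (kPa) at deformation gradient ``F``.

    Fiber directions are the two symmetric families at +/- theta in the
    local (circumferential, radial, normal) frame; ``F`` is expressed in
    that same frame.
    """
    fibers = params.fiber_directions()
    J, _, _, i1b, i4b = _invariants(np.asarray(F, dtype=float), fibers)
    w = params.c1 * (np.exp(params.c2 * (i1b - 3.0)) - 1.0)
    for i4 in i4b:
        e = params.kappa * i1b + (1.0 - 3.0 * params.kappa) * i4 - 1.0
        if e > 0.0:  # tension-only fiber switch
            w += params.k1 / (2.0 * params.k2) * (np.exp(params.k2 * e * e) - 1.0)
    w += (1.0 / params.D) * (J - 1.0) ** 2
    return float(w)


def mhgo_second_pk(F: np.ndarray, params: MHGOParams) -> np.ndarray:
    """Second Piola-Kirchhoff stress ``S = 2 dW/dC`` (kPa) in the local frame."""
    F = np.asarray(F, dtype=float)
    fibers = params.fiber_directions()
    J, C, Cb, i1b, i4b = _invariants(F, fibers)
    Cinv = np.linalg.inv(C)
    Jm23 = J ** (-2.0 / 3.0)
    eye = np.eye(3)

    # psi1 = dW/dI1b, psi4i = dW/dI4ib, psiJ = dW/dJ
    psi1 = params.c1 * params.c2 * np.exp(params.c2 * (i1b - 3.0))
    S = np.zeros((3, 3))
    dI1b_dC = Jm23 * eye - (i1b / 3.0) * Cinv
    for a_vec, i4 in zip(fibers, i4b):
        e = params.kappa * i1b + (1.0 - 3.0 * params.kappa) * i4 - 1.0
        if e <= 0.0:
            continue
        g = params.k1 * e * np.exp(params.k2 * e * e)
        psi1 += g * params.kappa
        psi4 = g * (1.0 - 3.0 * params.kappa)
        dI4b_dC = Jm23 * np.outer(a_vec, a_vec) - (i4 / 3.0) * Cinv
        S += 2.0 * psi4 * dI4b_dC
    S += 2.0 * psi1 * dI1b_dC
    psiJ = 2.0 / params.D * (J - 1.0)
    S += psiJ * J * Cinv
    return S


def mhgo_cauchy_stress(F: np.ndarray, params: MHGOParams) -> np.ndarray:
    """Cauchy stress (kPa): ``sigma = J^-1 F S F^T``.

    Raises if ``det F <= 0`` (element inversion).
    """
    F = np.asarray(F, dtype=float)
    J = float(np.linalg.det(F))
    if J <= 0.0:
        raise ValueError(f"non-positive Jacobian det(F) = {J}: element inversion")
    S = mhgo_second_pk(F, params)
    return (F @ S @ F.T) / J


# ---------------------------------------------------------------------------
# Ogden (uniaxial truss kinematics)


def ogden_strain_energy_uniaxial(lam: float, params: OgdenParams) -> float:
    """Ogden energy density (kPa) under incompressible uniaxial stretch:
    principal stretches (lam, lam^-1/2, lam^-1/2)."""
    if lam <= 0.0:
        raise ValueError("stretch must be positive")
    w = 0.0
    for mu_i, a_i in zip(params.mu, params.a):
        w += 2.0 * mu_i / a_i**2 * (lam**a_i + 2.0 * lam ** (-a_i / 2.0) - 3.0)
    return float(w)


def _ogden_dW_dlam(lam: float, params: OgdenParams) -> float:
    s = 0.0
    for mu_i, a_i in zip(params.mu, params.a):
        s += 2.0 * mu_i / a_i * (lam ** (a_i - 1.0) - lam ** (-a_i / 2.0 - 1.0))
    return s


def ogden_fiber_tension(
    lam: float, params: OgdenParams, area: float, allow_compression: bool = False
) -> float:
    """Axial force (N when W is in Pa; the solver scales kPa -> Pa) in a
    chordae truss of reference cross-section ``area`` at stretch ``lam``.

    Under incompressible uniaxial kinematics the force is
    ``A0 dW/dlam`` -- identically equal to Cauchy stress times the
    current (contracted) area.  By default chordae go slack below
    lam = 1; ``allow_compression`` enables the symmetric response for
    debugging.
    """
    if lam <= 0.0:
        raise ValueError(f"non-positive stretch {lam}: corrupted kinematics")
    if area <= 0.0:
        raise ValueError("cross-section area must be positive")
    if lam < 1.0 and not allow_compression:
        return 0.0
    return float(area * _ogden_dW_dlam(lam, params))
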