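"""Cubic spline smoothing kernels for SPH interpolation.

The fluid solver interpolates particle-carried fields with the classic
cubic (M4) B-spline kernel of compact support ``2h``, where ``h`` is the
smoothing length.  In normalized coordinates ``q = |r|/h``:

    W(q) = sigma_d * (1 - 1.5 q^2 + 0.75 q^3)   for 0 <= q <= 1
    W(q) = sigma_d * 0.25 (2 - q)^3             for 1 <  q <  2
    W(q) = 0                                    for q >= 2

with dimension-dependent normalization ``sigma_d`` chosen so that the
kernel integrates to one over its support (1/(pi h^3) in 3D,
10/(7 pi h^2) in 2D).  The planar constants exist for the 2D validation
scenes (hydrostatic tank, plane Poiseuille); production valve scenes
are three-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numba
import numpy as np

__all__ = ["KernelSpec", "cubic_spline_kernel", "cubic_spline_w", "cubic_spline_grad"]


@numba.njit(cache=True)
def _w_scalar(q: float, sigma: float) -> float:
    if q >= 2.0:
        return 0.0
    if q < 1.0:
        return sigma * (1.0 - 1.5 * q * q + 0.75 * q * q * q)
    d = 2.0 - q
    return sigma * 0.25 * d * d * d


@numba.njit(cache=True)
def _dwdq_scalar(q: float, sigma: float) -> float:
    """d W / d q (per unit q)."""
    if q >= 2.0:
        return 0.0
    if q < 1.0:
        return sigma * (-3.0 * q + 2.25 * q * q)
    d = 2.0 - q
    return -sigma * 0.75 * d * d


def _sigma(h: float, dim: int) -> float:
    if dim == 3:
        return 1.0 / (np.pi * h**3)
    if dim == 2:
        return 10.0 / (7.0 * np.pi * h**2)
    if dim == 1:
        return 2.0 / (3.0 * h)
    raise ValueError(f"unsupported dimension {dim}")


@dataclass(frozen=True)
class KernelSpec:
    """Cubic spline kernel configuration.

    Parameters
    ----------
    h : float
        Smoothing length in metres.  Interactions vanish beyond ``2 h``.
    dim : int
        Spatial dimension (2 for planar benchmark scenes, 3 otherwise).
    """

    h: float
    dim: int = 3
    sigma: float = field(init=False)

    def __post_init__(self) -> None:
        if self.h <= 0.0:
            raise ValueError(f"smoothing length must be positive, got {self.h}")
        object.__setattr__(self, "sigma", _sigma(self.h, self.dim))

    @property
    def support_radius(self) -> float:
        """Radius of compact support, ``2 h``."""
        return 2.0 * self.h

    def w(self, r: np.ndarray | float) -> np.ndarray | float:
        """Kernel value at displacement(s) ``r`` (vector(s) or |r| scalar(s))."""
        r = np.asarray(r, dtype=float)
        if r.ndim and r.shape[-1] == self.dim and r.ndim >= 1 and not np.isscalar(r):
            dist = np.linalg.norm(np.atleast_2d(r), axis=-1)
            if r.ndim == 1:
                dist = dist[0]
        else:
            dist = np.abs(r)
        out = cubic_spline_w(dist, self.h, self.dim)
        return float(out[0]) if np.ndim(dist) == 0 else out

    def grad_w(self, r: np.ndarray) -> np.ndarray:
        """Analytic gradient of W with respect to the displacement ``r``."""
        w, g = cubic_spline_kernel(np.asarray(r, dtype=float), self.h, self.dim)
        return g


def cubic_spline_w(dist: np.ndarray, h: float, dim: int = 3) -> np.ndarray:
    """Kernel value W(|r|, h) for an array of distances (1/m^dim)."""
    if h <= 0.0:
        raise ValueError(f"smoothing length must be positive, got {h}")
    sigma = _sigma(h, dim)
    dist = np.atleast_1d(np.asarray(dist, dtype=float))
    out = np.empty_like(dist)
    flat_d, flat_o = dist.ravel(), out.ravel()
    for i in range(flat_d.size):
        flat_o[i] = _w_scalar(flat_d[i] / h, sigma)
    return out


def cubic_spline_kernel(
    r: np.ndarray, h: float, dim: int = 3
) -> tuple[float | np.ndarray, np.ndarray]:
    """Evaluate the cubic spline kernel and its gradient at displacement ``r``.

    Parameters
    ----------
    r : array, shape (dim,) or (n, dim)
        Displacement vector(s) from neighbour to evaluation point (m).
    h : float
        Smoothing length (m).

    Returns
    -------
    W : float or array (1/m^dim)
    gradW : array matching ``r`` (1/m^(dim+1))
        The analytic gradient of W with respect to ``r``; zero at ``r = 0``
        (radial symmetry) and outside the ``2 h`` support.
    """
    if h <= 0.0:
        raise ValueError(f"smoothing length must be positive, got {h}")
    r = np.asarray(r, dtype=float)
    single = r.ndim == 1
    rv = np.atleast_2d(r)
    if rv.shape[1] != dim:
        raise ValueError(f"displacement has dimension {rv.shape[1]}, kernel is {dim}D")
    sigma = _sigma(h, dim)
    dist = np.linalg.norm(rv, axis=1)
    w = np.empty(rv.shape[0])
    grad = np.zeros_like(rv)
    for i in range(rv.shape[0]):
        q = dist[i] / h
        w[i] = _w_scalar(q, sigma)
        if dist[i] > 0.0 and q < 2.0:
            # dW/dr_vec = (dW/dq) * (1/h) * r/|r|
            grad[i] = _dwdq_scalar(q, sigma) / h * rv[i] / dist[i]
    if single:
        return float(w[0]), grad[0]
    return w, grad


def cubic_spline_grad(r: np.ndarray, h: float, dim: int = 3) -> np.ndarray:
    """Gradient of the cubic spline kernel (see :func:`cubic_spline_kernel`)."""
    return cubic_spline_kernel(r, h, dim)[1]
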