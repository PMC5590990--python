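"""Boundary conditions: keyframe wall motion, pressure pistons, chordal
origin tracking.

Cardiac wall kinematics are prescribed from a small number of keyframes
(ten phases over one 0.8 s cycle in the reference protocol) and
interpolated with cubic splines; periodic tracks use periodic end
conditions so position and velocity are continuous across the cycle
boundary.  Pressure boundary conditions are applied by plate pistons at
the ends of straight inlet/outlet tube extensions: a piston is a rigid
plug of frozen particles whose plate velocity is servo-controlled
against the imposed pressure waveform, emulating the massless
pressure-balancing plate of the physical setup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.interpolate import CubicSpline

from .fluid import FluidState, KernelSpec, kernel_interpolate
from .units import MMHG_TO_PA

__all__ = [
    "PrescribedMotionTrack",
    "PressureBoundary",
    "Piston",
    "interpolate_track",
    "chordal_origin_position",
    "apply_piston",
]


class PrescribedMotionTrack:
    """Cubic-spline keyframe displacement track for a set of nodes.

    Parameters
    ----------
    times : (K,) strictly increasing keyframe times, s.
    displacements : (K, n_nodes, dim) keyframe displacements, m.
    periodic : bool
        Periodic tracks must repeat their first keyframe at the last
        time (one cardiac cycle); interpolation is then C1-continuous
        across the cycle boundary and any t is wrapped into the cycle.
    """

    def __init__(self, times: np.ndarray, displacements: np.ndarray,
                 periodic: bool = False) -> None:
        self.times = np.asarray(times, dtype=float)
        self.displacements = np.asarray(displacements, dtype=float)
        self.periodic = bool(periodic)
        if self.times.ndim != 1 or self.times.size < 2:
            raise ValueError("a track needs at least two keyframe times")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("keyframe times must be strictly increasing")
        if self.displacements.shape[0] != self.times.size:
            raise ValueError("one displacement keyframe required per time")
        if self.periodic and not np.allclose(
            self.displacements[0], self.displacements[-1], atol=1e-12
        ):
            raise ValueError("periodic track endpoints must match")
        flat = self.displacements.reshape(self.times.size, -1)
        bc = "periodic" if self.periodic else "natural"
        self._spline = CubicSpline(self.times, flat, bc_type=bc)
        self._dspline = self._spline.derivative()

    @property
    def period(self) -> float:
        return float(self.times[-1] - self.times[0])

    def _wrap(self, t: float) -> float:
        if self.periodic:
            return self.times[0] + np.mod(t - self.times[0], self.period)
        if t < self.times[0] - 1e-12 or t > self.times[-1] + 1e-12:
            raise ValueError(
                f"t={t} outside non-periodic track range "
                f"[{self.times[0]}, {self.times[-1]}]"
            )
        return float(np.clip(t, self.times[0], self.times[-1]))

    def displacement(self, t: float) -> np.ndarray:
        """Interpolated per-node displacement at time t (m)."""
        return self._spline(self._wrap(t)).reshape(self.displacements.shape[1:])

    def velocity(self, t: float) -> np.ndarray:
        """Spline time derivative at time t (m/s)."""
        return self._dspline(self._wrap(t)).reshape(self.displacements.shape[1:])


def interpolate_track(track: PrescribedMotionTrack, t: float) -> np.ndarray:
    """Cubic-spline displacement of every tracked node at time ``t``."""
    return track.displacement(t)


def chordal_origin_position(
    t: float,
    pos_middiastole: np.ndarray,
    pos_midsystole: np.ndarray,
    t_middiastole: float,
    t_midsystole: float,
    period: float,
) -> np.ndarray:
    """Chordal-origin (papillary-tip) position on a smooth periodic
    trajectory between its mid-diastole and mid-systole anchors.

    The origin sits exactly at each anchor at its phase and transitions
    along the straight segment with a cosine ramp (C1 at the anchors),
    synchronized with the systole/diastole alternation.
    """
    p_d = np.asarray(pos_middiastole, dtype=float)
    p_s = np.asarray(pos_midsystole, dtype=float)
    td = np.mod(t_middiastole, period)
    ts = np.mod(t_midsystole, period)
    tt = np.mod(t - td, period)            # time since the diastolic anchor
    span_ds = np.mod(ts - td, period)      # diastole anchor -> systole anchor
    if span_ds <= 0.0 or span_ds >= period:
        raise ValueError("anchor phases must be distinct within the cycle")
    if tt <= span_ds:
        s = 0.5 * (1.0 - np.cos(np.pi * tt / span_ds))
    else:
        s = 0.5 * (1.0 + np.cos(np.pi * (tt - span_ds) / (period - span_ds)))
    return p_d + s * (p_s - p_d)


def chordal_origin_position_linear(
    t, pos_middiastole, pos_midsystole, t_middiastole, t_midsystole, period
):
    """Linear-ramp alternative to the default cosine transition."""
    p_d = np.asarray(pos_middiastole, dtype=float)
    p_s = np.asarray(pos_midsystole, dtype=float)
    td = np.mod(t_middiastole, period)
    ts = np.mod(t_midsystole, period)
    tt = np.mod(t - td, period)
    span = np.mod(ts - td, period)
    s = tt / span if tt <= span else 1.0 - (tt - span) / (period - span)
    return p_d + s * (p_s - p_d)


@dataclass
class PressureBoundary:
    """Piston pressure boundary on a plane bounding a fluid column.

    ``normal`` is the unit plate normal pointing into the fluid.
    ``waveform`` maps time (s) to pressure in mmHg (constant float or
    callable); ``area`` is the plate area used to report the imposed
    plate force.
    """

    origin: np.ndarray
    normal: np.ndarray
    area: float
    waveform: float | Callable[[float], float] = 0.0
    t_range: tuple[float, float] | None = None  # validity window for tables
    periodic: bool = False
    period: float = 0.0

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(self.normal)
        if not np.isclose(nn, 1.0, atol=1e-9):
            raise ValueError("piston normal must be unit length")

    def pressure_pa(self, t: float) -> float:
        """Imposed pressure at time t, Pa (waveforms are given in mmHg)."""
        if self.periodic and self.period > 0:
            t = np.mod(t, self.period)
        if self.t_range is not None and not self.periodic:
            if t < self.t_range[0] - 1e-12 or t > self.t_range[1] + 1e-12:
                raise ValueError(f"t={t} outside piston waveform range {self.t_range}")
        p = self.waveform(t) if callable(self.waveform) else self.waveform
        return float(p) * MMHG_TO_PA

    def imposed_force(self, t: float) -> float:
        """Plate force magnitude = pressure x area (N)."""
        return self.pressure_pa(t) * self.area

    @classmethod
    def from_table(cls, origin, normal, area, times, values_mmhg,
                   periodic=False) -> "PressureBoundary":
        """Piston from a time-value pressure table (linear interpolation)."""
        times = np.asarray(times, dtype=float)
        values = np.asarray(values_mmhg, dtype=float)
        period = float(times[-1] - times[0])

        def wf(t: float) -> float:
            tt = times[0] + np.mod(t - times[0], period) if periodic else t
            return float(np.interp(tt, times, values))

        return cls(origin=origin, normal=normal, area=area, waveform=wf,
                   t_range=(float(times[0]), float(times[-1])),
                   periodic=periodic, period=period)


@dataclass
class Piston(PressureBoundary):
    """A pressure boundary realized as a rigid frozen-particle plug.

    ``plug`` indexes the frozen particles forming the plate; the servo
    law drives the plate velocity towards balancing the imposed
    pressure against the fluid pressure measured one smoothing length
    inside the column:

        u = gain * (P_imposed - P_fluid) / (rho0 c0)

    (acoustic-impedance scaling), clamped to ``u_max``.  In the massless
    limit this settles exactly where plate pressure balances fluid
    pressure.
    """

    plug: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))
    gain: float = 0.5
    smoothing: float = 0.8  # low-pass factor on the servo velocity
    u_max: float = 2.0
    offset: float = 0.0   # travelled distance along +normal
    velocity_state: float = 0.0

    def probe_point(self, h: float, state: FluidState | None = None) -> np.ndarray:
        """Measurement point ~1.5 h inside the fluid column.  When the
        plug particle indices are known, the plate face is located from
        the actual plug positions (robust against drift)."""
        if state is not None and self.plug.size:
            proj = state.pos[self.plug] @ self.normal[: state.dim]
            face = float(proj.max())
            base = self.origin[: state.dim] - (self.origin[: state.dim]
                                               @ self.normal[: state.dim]
                                               ) * self.normal[: state.dim]
            return base + (face + 1.5 * h) * self.normal[: state.dim]
        return self.origin + (self.offset + 2.0 * h) * self.normal


def apply_piston(
    piston: Piston,
    t: float,
    state: FluidState,
    kernel: KernelSpec,
    rho0: float,
    c0: float,
    dt: float,
    pressure_fn=None,
) -> float:
    """Advance the piston servo one step and prescribe its plug velocity.

    Measures the SPH-interpolated fluid pressure just inside the plate
    and updates the (low-pass filtered) plate velocity along its normal,
    assigning it to the plug particles.  The caller advances the plate
    offset with this velocity every step.  Returns the plate speed
    (positive = pushing into the fluid).
    """
    target = piston.pressure_pa(t)
    dim = state.dim
    probe = piston.probe_point(kernel.h, state)[:dim]
    if pressure_fn is not None:
        p_meas = pressure_fn(probe)
    else:
        p_meas = kernel_interpolate(state.pressure, state, probe, kernel, shepard=True)
    u_raw = piston.gain * (target - float(p_meas)) / (rho0 * c0)
    u = piston.smoothing * piston.velocity_state + (1.0 - piston.smoothing) * u_raw
    u = float(np.clip(u, -piston.u_max, piston.u_max))
    piston.velocity_state = u
    if piston.plug.size:
        state.vel[piston.plug] = u * piston.normal[:dim][None, :]
    return u
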