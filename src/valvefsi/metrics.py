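"""Hemodynamic and valve-kinematic post-processing.

Clinical metric conventions used throughout:

* SV = EDV - ESV (ml) and EF = 100 SV/EDV (%).
* Effective orifice area by the Gorlin-type formulas
  ``EOA_AV = MSF / (51.6 sqrt(dP))`` and ``EOA_MV = MDF / (31 sqrt(dP))``
  with MSF/MDF the root-mean-square systolic/diastolic flow in ml/s and
  dP the mean transvalvular gradient in mmHg; EOA comes out in cm^2.
* Regurgitant volume RV = -integral of the negative part of the flow
  trace; regurgitant fraction RF = 100 RV/SV (%).
* Rapid valve opening/closing times (RVOT/RVCT) are the contiguous
  high-positive/high-negative slope tracts of the leaflet-belly radial
  velocity trace; ejection time (ET) runs from initial opening to
  complete closure.
* E/A is the ratio of the early (E) to atrial (A) diastolic inflow
  velocity peaks, in temporal order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .fluid import FluidState, KernelSpec, kernel_interpolate
from .units import pa_to_mmhg

__all__ = [
    "HemodynamicsReport", "KinematicsReport",
    "stroke_volume_ef", "eoa_av", "eoa_mv",
    "regurgitant_volume", "regurgitant_fraction",
    "FluxProbe", "flow_rate_through_plane",
    "transvalvular_pressure_drop", "hydrodynamic_axial_force",
    "e_over_a", "detect_rvot_rvct_et", "opening_angle",
]


# ---------------------------------------------------------------------------
# reports


@dataclass
class HemodynamicsReport:
    """Global hemodynamics of one cycle.  Units follow clinical tables:
    volumes ml, EF/RF %, EOA cm^2, pressure drops mmHg, forces N."""

    sv_ml: float = np.nan
    ef_percent: float = np.nan
    eoa_av_cm2: float = np.nan
    eoa_mv_cm2: float = np.nan
    mspd_mmhg: float = np.nan   # mean systolic pressure drop (AV)
    pspd_mmhg: float = np.nan   # peak systolic pressure drop (AV)
    mdpd_mmhg: float = np.nan   # mean diastolic pressure drop (MV)
    pdpd_mmhg: float = np.nan   # peak diastolic pressure drop (MV)
    rv_av_ml: float = np.nan
    rv_mv_ml: float = np.nan
    rf_av_percent: float = np.nan
    rf_mv_percent: float = np.nan
    e_over_a: float = np.nan
    force_traces_n: dict = field(default_factory=dict)
    flow_traces_ml_s: dict = field(default_factory=dict)

    def validate(self) -> None:
        if np.isfinite(self.ef_percent) and not 0.0 <= self.ef_percent <= 100.0:
            raise ValueError("EF must lie in [0, 100] %")
        for rv in (self.rv_av_ml, self.rv_mv_ml):
            if np.isfinite(rv) and rv < 0.0:
                raise ValueError("regurgitant volume must be non-negative")


@dataclass
class KinematicsReport:
    """Valve opening/closing kinematics (times in ms, angles in deg)."""

    rvot_ms: float = np.nan
    rvct_ms: float = np.nan
    et_ms: float = np.nan
    belly_velocity_traces: dict = field(default_factory=dict)
    opening_angle_traces: dict = field(default_factory=dict)

    def validate(self) -> None:
        if np.isfinite(self.rvot_ms) and self.rvot_ms < 0:
            raise ValueError("RVOT must be non-negative")
        if np.isfinite(self.rvct_ms) and self.rvct_ms < 0:
            raise ValueError("RVCT must be non-negative")
        if np.isfinite(self.et_ms) and self.et_ms < self.rvot_ms + self.rvct_ms:
            raise ValueError("ET cannot be shorter than RVOT + RVCT")


# ---------------------------------------------------------------------------
# scalar formulas


def stroke_volume_ef(edv_ml: float, esv_ml: float) -> tuple[float, float]:
    """Stroke volume (ml) and ejection fraction (%) from EDV/ESV."""
    if not edv_ml > esv_ml >= 0.0:
        raise ValueError(f"need EDV > ESV >= 0, got EDV={edv_ml}, ESV={esv_ml}")
    sv = edv_ml - esv_ml
    return sv, 100.0 * sv / edv_ml


def eoa_av(msf_ml_s: float, dp_mmhg: float) -> float:
    """AV effective orifice area (cm^2) from RMS systolic flow (ml/s)
    and mean systolic gradient (mmHg)."""
    if dp_mmhg <= 0.0:
        raise ValueError("mean systolic pressure gradient must be positive")
    return msf_ml_s / (51.6 * np.sqrt(dp_mmhg))


def eoa_mv(mdf_ml_s: float, dp_mmhg: float) -> float:
    """MV effective orifice area (cm^2) from RMS diastolic flow (ml/s)
    and mean diastolic gradient (mmHg)."""
    if dp_mmhg <= 0.0:
        raise ValueError("mean diastolic pressure gradient must be positive")
    return mdf_ml_s / (31.0 * np.sqrt(dp_mmhg))


def regurgitant_volume(t: np.ndarray, q_ml_s: np.ndarray) -> float:
    """Backward leaked volume (ml): minus the trapezoidal time integral
    of the negative part of the flow-rate trace."""
    t = np.asarray(t, dtype=float)
    q = np.asarray(q_ml_s, dtype=float)
    if t.size == 0 or t.size != q.size:
        raise ValueError("empty or incongruent flow trace")
    return float(-np.trapezoid(np.minimum(q, 0.0), t))


def regurgitant_fraction(rv_ml: float, sv_ml: float) -> float:
    """Regurgitant fraction RF = 100 RV/SV (%)."""
    if sv_ml <= 0.0:
        raise ValueError("stroke volume must be positive")
    return 100.0 * rv_ml / sv_ml


# ---------------------------------------------------------------------------
# flow-rate probe


class FluxProbe:
    """Signed volume flux through a disk, by particle crossings.

    Each particle crossing the disk plane within the disk radius during
    a step contributes its volume ``m/rho`` with the sign of the
    crossing direction relative to the disk normal; the flow rate is the
    crossed volume per time step.
    """

    def __init__(self, center: np.ndarray, normal: np.ndarray, radius: float) -> None:
        self.center = np.asarray(center, dtype=float)
        self.normal = np.asarray(normal, dtype=float)
        self.normal = self.normal / np.linalg.norm(self.normal)
        self.radius = float(radius)
        self._side: np.ndarray | None = None
        self.times: list[float] = []
        self.q_m3_s: list[float] = []

    def _signed(self, pos: np.ndarray) -> np.ndarray:
        d = pos - self.center[: pos.shape[1]][None, :]
        return d @ self.normal[: pos.shape[1]]

    def update(self, state: FluidState, t: float, dt: float) -> float:
        """Record the flux for the step ending at time t; returns m^3/s."""
        s = self._signed(state.pos)
        side = s > 0.0   # strict half-space: a particle exactly on the
        #                  plane counts once, when it leaves the - side
        if self._side is None:
            self._side = side
            return 0.0
        crossed = side != self._side
        vol = 0.0
        if np.any(crossed):
            idx = np.nonzero(crossed)[0]
            # radial check at the crossing (current-position approximation)
            mid = state.pos[idx]
            d = mid - self.center[: mid.shape[1]][None, :]
            d = d - np.outer(d @ self.normal[: mid.shape[1]], self.normal[: mid.shape[1]])
            inside = np.linalg.norm(d, axis=1) <= self.radius
            idx = idx[inside]
            sign = np.where(side[idx], 1.0, -1.0)
            vol = float(np.sum(sign * state.mass[idx] / state.rho[idx]))
        self._side = side
        q = vol / dt
        self.times.append(t)
        self.q_m3_s.append(q)
        return q

    def trace_ml_s(self) -> tuple[np.ndarray, np.ndarray]:
        return np.asarray(self.times), np.asarray(self.q_m3_s) * 1e6

    def integrated_volume_ml(self) -> float:
        """Net crossed volume (ml), positive along the disk normal."""
        t, q = self.trace_ml_s()
        if t.size < 2:
            return 0.0
        # q is piecewise-constant per step: sum q*dt reconstructed from times
        dts = np.diff(t, prepend=t[0] - (t[1] - t[0]) if t.size > 1 else 0.0)
        return float(np.sum(np.asarray(self.q_m3_s) * dts) * 1e6)


def flow_rate_through_plane(snapshots, center, normal, radius, dt) -> tuple[np.ndarray, np.ndarray]:
    """Flow-rate trace (ml/s) from a sequence of fluid snapshots.

    ``snapshots`` iterates over FluidState objects separated by ``dt``.
    """
    probe = FluxProbe(center, normal, radius)
    t = 0.0
    for st in snapshots:
        probe.update(st, t, dt)
        t += dt
    return probe.trace_ml_s()


# ---------------------------------------------------------------------------
# probes on particle fields


def transvalvular_pressure_drop(
    probe_up: np.ndarray,
    probe_down: np.ndarray,
    states,
    kernel: KernelSpec,
) -> np.ndarray:
    """Pressure drop (mmHg) upstream-minus-downstream for each state.

    Pressures are SPH-interpolated (Shepard-normalized) at the two probe
    points, conventionally one diameter upstream and three diameters
    downstream of the valve annulus.
    """
    drops = []
    for st in states:
        pu = kernel_interpolate(st.pressure, st, np.asarray(probe_up)[: st.dim],
                                kernel, shepard=True)
        pd_ = kernel_interpolate(st.pressure, st, np.asarray(probe_down)[: st.dim],
                                 kernel, shepard=True)
        drops.append(pa_to_mmhg(float(pu) - float(pd_)))
    return np.asarray(drops)


def hydrodynamic_axial_force(force_trace: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Axial hydrodynamic force trace (N) on a leaflet surface.

    ``force_trace`` holds the per-step vector sum of the contact
    reactions exerted by the fluid on the surface, shape (T, 3);
    the result is its projection on the (unit) axis, positive = opening.
    """
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.asarray(force_trace, dtype=float) @ axis


# ---------------------------------------------------------------------------
# kinematics


def e_over_a(t: np.ndarray, velocity: np.ndarray,
             min_separation_s: float = 0.1,
             prominence_fraction: float = 0.1) -> float:
    """E/A ratio of the two largest diastolic inflow-velocity peaks in
    temporal order (E first, A second).

    Peaks are found with a prominence threshold (fraction of the trace
    maximum) and a minimum separation of 100 ms by default.
    Raises if no A wave can be identified.
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(velocity, dtype=float)
    if v.size < 3:
        raise ValueError("velocity trace too short")
    dt = np.median(np.diff(t))
    dist = max(1, int(round(min_separation_s / dt)))
    vmax = float(v.max())
    if vmax <= 0:
        raise ValueError("no positive inflow velocity: E/A undefined")
    peaks, props = find_peaks(v, distance=dist, prominence=prominence_fraction * vmax)
    if len(peaks) < 2:
        raise ValueError("A wave not found")
    # two most prominent peaks, then temporal order
    top2 = peaks[np.argsort(props["prominences"])[-2:]]
    top2.sort()
    e_peak, a_peak = v[top2[0]], v[top2[1]]
    return float(e_peak / a_peak)


def detect_rvot_rvct_et(
    t: np.ndarray,
    radial_velocity: np.ndarray,
    slope_fraction: float = 0.2,
) -> tuple[float, float, float]:
    """Rapid valve opening/closing times and ejection time (ms).

    RVOT is the duration of the contiguous tract of high positive slope
    at the initial opening; RVCT the contiguous high-negative-slope
    tract at final closure; ET runs from the start of opening to the end
    of closure.  "High" slope means exceeding ``slope_fraction`` of the
    respective peak slope magnitude (0.2 by default).
    Raises on a flat trace (no valve events).
    """
    t = np.asarray(t, dtype=float)
    v = np.asarray(radial_velocity, dtype=float)
    if t.size < 3 or t.size != v.size:
        raise ValueError("trace too short or incongruent")
    dvdt = np.gradient(v, t)
    s_max = float(dvdt.max())
    s_min = float(dvdt.min())
    scale = max(abs(v.max()), abs(v.min()))
    if scale <= 0 or s_max <= 0.0 or s_min >= 0.0 or (s_max - s_min) < 1e-14:
        raise ValueError("flat radial-velocity trace: no opening/closing events")

    def _first_tract(mask: np.ndarray) -> tuple[int, int]:
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError("no slope tract found")
        start = idx[0]
        end = start
        while end + 1 < mask.size and mask[end + 1]:
            end += 1
        return start, end

    def _last_tract(mask: np.ndarray) -> tuple[int, int]:
        idx = np.nonzero(mask)[0]
        if idx.size == 0:
            raise ValueError("no slope tract found")
        end = idx[-1]
        start = end
        while start - 1 >= 0 and mask[start - 1]:
            start -= 1
        return start, end

    open_mask = dvdt >= slope_fraction * s_max
    close_mask = dvdt <= slope_fraction * s_min
    o0, o1 = _first_tract(open_mask)
    c0, c1 = _last_tract(close_mask)
    rvot = (t[o1] - t[o0]) * 1e3
    rvct = (t[c1] - t[c0]) * 1e3
    et = (t[c1] - t[o0]) * 1e3
    return float(rvot), float(rvct), float(et)


def opening_angle(
    hinge: np.ndarray, tip: np.ndarray, annulus_normal: np.ndarray
) -> float:
    """Angle (deg) between the annulus plane and the hinge-to-tip chord.

    0 deg = leaflet lying in the annulus plane, 90 deg = perpendicular.
    Accepts single points or (T, 3) trajectories (returns a trace).
    """
    hinge = np.atleast_2d(np.asarray(hinge, dtype=float))
    tip = np.atleast_2d(np.asarray(tip, dtype=float))
    n = np.asarray(annulus_normal, dtype=float)
    n = n / np.linalg.norm(n)
    chord = tip - hinge
    L = np.linalg.norm(chord, axis=1)
    if np.any(L <= 0):
        raise ValueError("coincident hinge and tip markers")
    sin_a = np.abs(chord @ n) / L
    ang = np.degrees(np.arcsin(np.clip(sin_a, 0.0, 1.0)))
    return float(ang[0]) if ang.size == 1 else ang
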