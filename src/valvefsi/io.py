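"""File I/O: configs, particle/mesh snapshots, trace tables, reports.

Particle snapshots and surface meshes are written as legacy-ASCII VTK
(POLYDATA with point data for particles, triangle POLYDATA for
surfaces), readable by ParaView and friends; surfaces can also be
exported as Wavefront OBJ.  Traces go to CSV via pandas; run metadata
and metric reports to JSON.  Configs are YAML (JSON is a YAML subset
and therefore also accepted).
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fluid import FluidState

__all__ = [
    "load_config", "write_particles_vtk", "write_mesh_vtk", "write_mesh_obj",
    "write_traces_csv", "write_report_json", "load_waveform_csv",
]


def load_config(path) -> dict:
    """Load a YAML (or JSON) run/scene configuration."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must contain a mapping")
    return cfg


def load_waveform_csv(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a time-value table (CSV with columns time, value)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"waveform {path} needs at least two columns")
    return df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float)


def write_particles_vtk(path, state: FluidState) -> None:
    """Legacy-ASCII VTK polydata snapshot with density, pressure,
    velocity and the frozen flag as point data."""
    n = state.n
    pos = state.pos
    if state.dim == 2:
        pos = np.column_stack([pos, np.zeros(n)])
    vel = state.vel
    if state.dim == 2:
        vel = np.column_stack([vel, np.zeros(n)])
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvalvefsi particles\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {n} float\n")
        np.savetxt(f, pos, fmt="%.8e")
        f.write(f"VERTICES {n} {2 * n}\n")
        np.savetxt(f, np.column_stack([np.ones(n, int), np.arange(n)]), fmt="%d")
        f.write(f"POINT_DATA {n}\n")
        f.write("SCALARS density float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, state.rho, fmt="%.8e")
        f.write("SCALARS pressure float 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, state.pressure, fmt="%.8e")
        f.write("SCALARS frozen int 1\nLOOKUP_TABLE default\n")
        np.savetxt(f, state.frozen.astype(int), fmt="%d")
        f.write("VECTORS velocity float\n")
        np.savetxt(f, vel, fmt="%.8e")


def write_mesh_vtk(path, nodes: np.ndarray, triangles: np.ndarray,
                   cell_vectors: dict | None = None) -> None:
    """Legacy-ASCII VTK polydata for a triangle surface; optional cell
    vector fields (e.g. fiber frames)."""
    nodes = np.asarray(nodes, dtype=float)
    tris = np.asarray(triangles, dtype=int)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nvalvefsi surface\nASCII\n")
        f.write("DATASET POLYDATA\n")
        f.write(f"POINTS {len(nodes)} float\n")
        np.savetxt(f, nodes, fmt="%.8e")
        f.write(f"POLYGONS {len(tris)} {4 * len(tris)}\n")
        np.savetxt(f, np.column_stack([np.full(len(tris), 3), tris]), fmt="%d")
        if cell_vectors:
            f.write(f"CELL_DATA {len(tris)}\n")
            for name, vecs in cell_vectors.items():
                f.write(f"VECTORS {name} float\n")
                np.savetxt(f, np.asarray(vecs, dtype=float), fmt="%.8e")


def write_mesh_obj(path, nodes: np.ndarray, triangles: np.ndarray) -> None:
    """Wavefront OBJ surface export (1-based indices)."""
    with open(path, "w") as f:
        for p in np.asarray(nodes, dtype=float):
            f.write(f"v {p[0]:.8e} {p[1]:.8e} {p[2]:.8e}\n")
        for t in np.asarray(triangles, dtype=int):
            f.write(f"f {t[0] + 1} {t[1] + 1} {t[2] + 1}\n")


def write_traces_csv(path, traces: dict) -> None:
    """Write the simulation trace dict (time plus scalar/vector series)
    to a flat CSV (vector components expanded as _x/_y/_z)."""
    cols: dict = {}
    for key, values in traces.items():
        arr = np.asarray(values)
        if arr.ndim == 1:
            cols[key] = arr
        elif arr.ndim == 2 and arr.shape[1] <= 3:
            for i, suffix in enumerate("xyz"[: arr.shape[1]]):
                cols[f"{key}_{suffix}"] = arr[:, i]
    n = min(len(v) for v in cols.values()) if cols else 0
    pd.DataFrame({k: v[:n] for k, v in cols.items()}).to_csv(path, index=False)


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {k: _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_report_json(path, report) -> None:
    """Serialize a metrics report (dataclass or dict) to JSON."""
    with open(path, "w") as f:
        json.dump(_to_jsonable(report), f, indent=2, allow_nan=False)
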