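"""Snapshot and trace writers: legacy VTK / PLY meshes, CSV polylines and
observable traces, JSON run metadata."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import TriMesh, boundary_curvature


def write_vtk(mesh: TriMesh, path) -> None:
    """Legacy ASCII VTK unstructured grid with the material tag as cell
    data."""
    p = Path(path)
    n, m = len(mesh.vertices), len(mesh.triangles)
    lines = ["# vtk DataFile Version 3.0", "morphofem snapshot", "ASCII",
             "DATASET UNSTRUCTURED_GRID", f"POINTS {n} double"]
    lines += [f"{x:.17g} {y:.17g} 0" for x, y in mesh.vertices]
    lines.append(f"CELLS {m} {4 * m}")
    lines += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    lines.append(f"CELL_TYPES {m}")
    lines += ["5"] * m
    lines += [f"CELL_DATA {m}", "SCALARS region int 1",
              "LOOKUP_TABLE default"]
    lines += [str(int(t)) for t in mesh.tri_tags]
    p.write_text("\n".join(lines) + "\n")


def write_ply(mesh: TriMesh, path) -> None:
    p = Path(path)
    n, m = len(mesh.vertices), len(mesh.triangles)
    head = ["ply", "format ascii 1.0", f"element vertex {n}",
            "property double x", "property double y", "property double z",
            f"element face {m}", "property list uchar int vertex_indices",
            "end_header"]
    body = [f"{x:.17g} {y:.17g} 0" for x, y in mesh.vertices]
    body += [f"3 {a} {b} {c}" for a, b, c in mesh.triangles]
    p.write_text("\n".join(head + body) + "\n")


def write_boundary_csv(mesh: TriMesh, path) -> None:
    """Boundary polylines as CSV columns (x, y, label, s, kappa)."""
    rows = []
    for label in mesh.labels:
        if all(c.internal for c in mesh.chains_for(label)):
            continue
        curv = boundary_curvature(mesh, label)
        pts = mesh.vertices[curv.indices]
        for (x, y), s, k in zip(pts, curv.s, curv.kappa):
            rows.append({"x": x, "y": y, "label": label, "s": s, "kappa": k})
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def write_trace_csv(trace, path) -> None:
    """Observables per step as CSV (step, time, <observable columns>)."""
    df = pd.DataFrame({"step": np.arange(len(trace.times)),
                       "time": trace.times, **trace.observables})
    df.to_csv(path, index=False, float_format="%.17g")


def write_run_metadata(config, trace, path) -> None:
    meta = {
        "config": config.to_dict(),
        "steps": int(len(trace.times) - 1),
        "final_time": float(trace.times[-1]),
        "stop_reason": trace.stop_reason,
        "remesh_steps": [int(s) for s in trace.remesh_steps],
        "wall_time_s": round(trace.wall_time, 3),
    }
    Path(path).write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
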