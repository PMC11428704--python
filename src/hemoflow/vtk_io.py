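"""Legacy-ASCII VTK export of structured meshes and flow fields.

Writes VTK DataFile 3.0 unstructured grids of quadrilateral cells — a
plain-text format every VTK-based viewer (ParaView, VisIt) reads.  Meshes
carry their region/tag information as cell-data integer arrays; flow
series are written as one file per recorded instant plus a ``.series``
JSON index.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .geometry import StructuredMesh

__all__ = ["write_vtk_mesh", "write_vtk_flow_series", "write_vtk_wall_map"]


def _header(fh, title: str, points: np.ndarray) -> None:
    fh.write("# vtk DataFile Version 3.0\n")
    fh.write(f"{title}\n")
    fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
    fh.write(f"POINTS {points.shape[0]} double\n")
    for x, y in points:
        fh.write(f"{float(x)!r} {float(y)!r} 0.0\n")


def _quad_cells(fh, ni: int, nj: int) -> None:
    ncell = ni * nj
    fh.write(f"CELLS {ncell} {5 * ncell}\n")
    for i in range(ni):
        for j in range(nj):
            a = i * (nj + 1) + j
            b = (i + 1) * (nj + 1) + j
            fh.write(f"4 {a} {b} {b + 1} {a + 1}\n")
    fh.write(f"CELL_TYPES {ncell}\n")
    fh.write("9\n" * ncell)  # VTK_QUAD


def _cell_scalars(fh, name: str, data: np.ndarray, dtype: str = "double") -> None:
    fh.write(f"SCALARS {name} {dtype} 1\nLOOKUP_TABLE default\n")
    for val in np.asarray(data).reshape(-1):
        fh.write(f"{float(val)!r}\n" if dtype == "double" else f"{int(val)}\n")


def write_vtk_mesh(path, mesh: StructuredMesh,
                   cell_data: Optional[Dict[str, np.ndarray]] = None) -> None:
    """Write the mesh with region (fluid/septum/solid) and boundary-tag
    cell arrays, plus any extra per-cell arrays supplied."""
    ni, nj = mesh.shape
    points = mesh.nodes.reshape(-1, 2)
    region = np.where(mesh.fluid, 0, np.where(mesh.septum, 1, 2))
    tag_counts: Dict[str, np.ndarray] = {}
    for f in mesh.boundary_faces():
        arr = tag_counts.setdefault(f.tag, np.zeros((ni, nj), dtype=int))
        arr[f.i, f.j] += 1
    with Path(path).open("w") as fh:
        _header(fh, "vessel mesh", points)
        _quad_cells(fh, ni, nj)
        fh.write(f"CELL_DATA {ni * nj}\n")
        _cell_scalars(fh, "region", region, dtype="int")
        for tag, arr in sorted(tag_counts.items()):
            _cell_scalars(fh, f"tag_{tag}", arr, dtype="int")
        for name, arr in (cell_data or {}).items():
            _cell_scalars(fh, name, arr)


def write_vtk_flow_series(directory, basename: str, mesh: StructuredMesh,
                          series) -> list:
    """One VTK file per recorded instant (cell-centred velocity vector and
    pressure) plus a ParaView ``.series`` index; returns written paths."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    ni, nj = mesh.shape
    points = mesh.nodes.reshape(-1, 2)
    written = []
    entries = []
    for k in range(series.n_times):
        uc = 0.5 * (series.u[k][:-1] + series.u[k][1:])
        vc = 0.5 * (series.v[k][:, :-1] + series.v[k][:, 1:])
        p = series.p[k] + series.outlet_pressure[k]
        path = directory / f"{basename}_{k:04d}.vtk"
        with path.open("w") as fh:
            _header(fh, f"flow t={float(series.times[k])!r}", points)
            _quad_cells(fh, ni, nj)
            fh.write(f"CELL_DATA {ni * nj}\n")
            fh.write("VECTORS velocity double\n")
            for a, b in zip(uc.reshape(-1), vc.reshape(-1)):
                fh.write(f"{float(a)!r} {float(b)!r} 0.0\n")
            _cell_scalars(fh, "pressure", p)
        written.append(path)
        entries.append({"name": path.name, "time": float(series.times[k])})
    index = directory / f"{basename}.vtk.series"
    with index.open("w") as fh:
        json.dump({"file-series-version": "1.0", "files": entries}, fh,
                  indent=1, sort_keys=True)
    written.append(index)
    return written


def write_vtk_wall_map(path, maps, positions: np.ndarray) -> None:
    """Wall-point cloud (VTK vertices) with TAWSS/OSI/RRT/ECAP point data."""
    pts = np.asarray(positions)
    n = pts.shape[0]
    with Path(path).open("w") as fh:
        _header(fh, "wall index maps", pts)
        fh.write(f"CELLS {n} {2 * n}\n")
        for k in range(n):
            fh.write(f"1 {k}\n")
        fh.write(f"CELL_TYPES {n}\n")
        fh.write("1\n" * n)  # VTK_VERTEX
        fh.write(f"POINT_DATA {n}\n")
        for name, arr in (("TAWSS", maps.tawss), ("OSI", maps.osi),
                          ("RRT", maps.rrt), ("ECAP", maps.ecap)):
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            for val in arr:
                fh.write(f"{float(val)!r}\n")
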