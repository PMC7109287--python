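"""Output writers: probe CSV, run-summary JSON, and legacy-VTK mesh export."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_probes_csv", "write_summary_json", "write_vtk", "write_interface_vtk"]


def write_probes_csv(result, path):
    """Probe time series as CSV (columns t, field, region, x, y[, z], value)."""
    result.probes.to_csv(path, index=False)
    return Path(path)


def write_summary_json(result, path):
    with open(path, "w") as f:
        json.dump(result.summary, f, indent=2, default=_jsonable)
    return Path(path)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


_VTK_CELL_TYPE = {2: 5, 3: 10}       # triangle, tetrahedron
_VTK_FACET_TYPE = {2: 3, 3: 5}       # line, triangle


def write_vtk(mesh, path, point_data: dict | None = None, cell_data: dict | None = None):
    """Legacy-ASCII VTK unstructured grid with subdomain labels as cell data."""
    pts = mesh.points
    cells = mesh.cells
    dim = mesh.dim
    cell_data = dict(cell_data or {})
    cell_data.setdefault("subdomain", mesh.cell_labels)
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nknpemi mesh\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            xyz = list(p) + [0.0] * (3 - dim)
            f.write(" ".join(f"{v:.10g}" for v in xyz) + "\n")
        nv = cells.shape[1]
        f.write(f"CELLS {len(cells)} {len(cells) * (nv + 1)}\n")
        for c in cells:
            f.write(f"{nv} " + " ".join(str(int(v)) for v in c) + "\n")
        f.write(f"CELL_TYPES {len(cells)}\n")
        f.write("\n".join([str(_VTK_CELL_TYPE[dim])] * len(cells)) + "\n")
        if cell_data:
            f.write(f"CELL_DATA {len(cells)}\n")
            for name, arr in cell_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{float(v):.10g}" for v in np.asarray(arr)) + "\n")
        if point_data:
            f.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{float(v):.10g}" for v in np.asarray(arr)) + "\n")
    return Path(path)


def write_interface_vtk(mesh, path, point_data: dict | None = None):
    """The membrane mesh as its own VTK file (polylines in 2D, triangles in 3D)."""
    iface = mesh.interface
    pts = mesh.points[iface.vertices]
    dim = mesh.dim
    facets = iface.facets
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\nknpemi interface\nASCII\nDATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {len(pts)} double\n")
        for p in pts:
            xyz = list(p) + [0.0] * (3 - dim)
            f.write(" ".join(f"{v:.10g}" for v in xyz) + "\n")
        nv = facets.shape[1]
        f.write(f"CELLS {len(facets)} {len(facets) * (nv + 1)}\n")
        for c in facets:
            f.write(f"{nv} " + " ".join(str(int(v)) for v in c) + "\n")
        f.write(f"CELL_TYPES {len(facets)}\n")
        f.write("\n".join([str(_VTK_FACET_TYPE[dim])] * len(facets)) + "\n")
        f.write(f"CELL_DATA {len(facets)}\n")
        f.write("SCALARS membrane double 1\nLOOKUP_TABLE default\n")
        f.write("\n".join(str(int(v)) for v in iface.facet_cell) + "\n")
        if point_data:
            f.write(f"POINT_DATA {len(pts)}\n")
            for name, arr in point_data.items():
                f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                f.write("\n".join(f"{float(v):.10g}" for v in np.asarray(arr)) + "\n")
    return Path(path)
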