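"""State output: VTK legacy ASCII files plus a JSON manifest.

Tissue fields go to a VTK unstructured grid of hexahedra (``.vtk``), the
network to VTK polydata lines; both are plain-text legacy VTK readable by
standard viewers (ParaView, VisIt, meshio).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np


def _write_points(fh, pts):
    fh.write(f"POINTS {len(pts)} double\n")
    np.savetxt(fh, pts, fmt="%.10g")


def write_tissue_vtk(mesh, fields: dict, path) -> Path:
    """Write mesh + nodal scalar fields as a legacy VTK unstructured grid."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = mesh.n
    cells = []
    for i in range(n):
        for j in range(n):
            for k in range(n):
                c = [mesh.node_index(i + di, j + dj, k + dk)
                     for di, dj, dk in ((0, 0, 0), (1, 0, 0), (1, 1, 0),
                                        (0, 1, 0), (0, 0, 1), (1, 0, 1),
                                        (1, 1, 1), (0, 1, 1))]
                cells.append(c)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\noncoflow tissue state\n"
                 "ASCII\nDATASET UNSTRUCTURED_GRID\n")
        _write_points(fh, mesh.nodes)
        fh.write(f"CELLS {len(cells)} {len(cells) * 9}\n")
        for c in cells:
            fh.write("8 " + " ".join(map(str, c)) + "\n")
        fh.write(f"CELL_TYPES {len(cells)}\n")
        fh.write("\n".join(["12"] * len(cells)) + "\n")
        fh.write(f"POINT_DATA {mesh.n_nodes}\n")
        for name, data in fields.items():
            data = np.asarray(data)
            if data.ndim == 2 and data.shape[1] == 3:
                fh.write(f"VECTORS {name} double\n")
                np.savetxt(fh, data, fmt="%.10g")
            else:
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                np.savetxt(fh, data.ravel(), fmt="%.10g")
    return path


def write_network_vtk(network, path, segment_fields: dict | None = None) -> Path:
    """Write the vascular network as legacy VTK polydata line cells."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\noncoflow vascular network\n"
                 "ASCII\nDATASET POLYDATA\n")
        _write_points(fh, network.nodes)
        ns = network.n_segments
        fh.write(f"LINES {ns} {ns * 3}\n")
        for a, b in zip(network.node_a, network.node_b):
            fh.write(f"2 {a} {b}\n")
        fields = {"radius": network.radius, "state": network.state.astype(float)}
        fields.update(segment_fields or {})
        fh.write(f"CELL_DATA {ns}\n")
        for name, data in fields.items():
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(data, float).ravel(), fmt="%.10g")
    return path


def write_state(mesh, network, fields: dict, out_dir, tag: str = "state",
                units: dict | None = None) -> dict:
    """Write tissue + network snapshots and a manifest JSON; returns paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    tissue = write_tissue_vtk(mesh, fields, out_dir / f"{tag}_tissue.vtk")
    net = write_network_vtk(network, out_dir / f"{tag}_network.vtk")
    manifest = {
        "tissue_file": tissue.name,
        "network_file": net.name,
        "fields": {name: (units or {}).get(name, "dimensionless")
                   for name in fields},
        "n_mesh_nodes": int(mesh.n_nodes),
        "n_vascular_nodes": int(network.n_nodes),
        "n_segments": int(network.n_segments),
    }
    mpath = out_dir / f"{tag}_manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return {"tissue": tissue, "network": net, "manifest": mpath}


def read_vtk_point_count(path) -> int:
    """Vertex count of a legacy VTK file (independent light-weight check)."""
    with open(path) as fh:
        for line in fh:
            if line.startswith("POINTS"):
                return int(line.split()[1])
    raise ValueError(f"{path}: no POINTS record found")
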