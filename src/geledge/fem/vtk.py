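"""Minimal legacy-ASCII VTK writer for the axisymmetric quad mesh.

Writes an unstructured grid (cell type 9, VTK_QUAD) with optional per-point
and per-cell scalar fields, viewable in ParaView. The (r, z) plane maps to
VTK (x, y) with z = 0.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from geledge.fem.types import AxisymMesh


def write_vtk(
    mesh: AxisymMesh,
    path: str | Path,
    point_data: dict[str, np.ndarray] | None = None,
    cell_data: dict[str, np.ndarray] | None = None,
    title: str = "axisymmetric gel indentation",
) -> Path:
    path = Path(path)
    lines = [
        "# vtk DataFile Version 3.0",
        title,
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {mesh.n_nodes} float",
    ]
    for r, z in mesh.nodes:
        lines.append(f"{r:.6g} {z:.6g} 0")
    lines.append(f"CELLS {mesh.n_elements} {mesh.n_elements * 5}")
    for quad in mesh.elements:
        lines.append("4 " + " ".join(str(int(i)) for i in quad))
    lines.append(f"CELL_TYPES {mesh.n_elements}")
    lines.extend(["9"] * mesh.n_elements)

    def _scalars(data: dict[str, np.ndarray], n: int) -> None:
        for name, values in data.items():
            values = np.asarray(values)
            if values.ndim == 1:
                lines.append(f"SCALARS {name} float 1")
                lines.append("LOOKUP_TABLE default")
                lines.extend(f"{v:.6g}" for v in values)
            else:  # vector field, pad to 3 components
                lines.append(f"VECTORS {name} float")
                for row in values:
                    padded = list(row) + [0.0] * (3 - len(row))
                    lines.append(" ".join(f"{v:.6g}" for v in padded))
            assert len(values) == n, f"field {name} length mismatch"

    if point_data:
        lines.append(f"POINT_DATA {mesh.n_nodes}")
        _scalars(point_data, mesh.n_nodes)
    if cell_data:
        lines.append(f"CELL_DATA {mesh.n_elements}")
        _scalars(cell_data, mesh.n_elements)
    path.write_text("\n".join(lines) + "\n")
    return path
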