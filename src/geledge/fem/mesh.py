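"""Graded structured meshing of the axisymmetric gel cross-section."""

from __future__ import annotations

import logging

import numpy as np

from geledge.fem.types import AxisymMesh, GelGeometry, MeshParams

log = logging.getLogger(__name__)


def graded_line(length: float, fine: float, coarse: float, growth: float,
                fine_span: float) -> np.ndarray:
    """1D node coordinates on [0, length], spacing `fine` on [0, fine_span]
    then growing geometrically (ratio `growth`) up to `coarse`.

    The trailing spacings are rescaled so the last node lands exactly on
    `length`; the rescaling preserves the grading shape.
    """
    if length <= 0:
        raise ValueError("length must be > 0")
    fine_span = min(fine_span, length)
    n_fine = max(1, int(round(fine_span / fine)))
    spacings = [fine_span / n_fine] * n_fine
    pos = fine_span
    h = fine
    while pos < length - 1e-12:
        h = min(h * growth, coarse, length - pos)
        spacings.append(h)
        pos += h
    spacings = np.asarray(spacings)
    # exact landing: rescale only the graded tail
    tail = spacings[n_fine:]
    if tail.size:
        target = length - fine_span
        spacings[n_fine:] = tail * (target / tail.sum())
    coords = np.concatenate([[0.0], np.cumsum(spacings)])
    coords[-1] = length
    return coords


def build_axisym_mesh(geometry: GelGeometry, params: MeshParams | None = None) -> AxisymMesh:
    """Build a graded structured quad mesh for the gel cross-section.

    Finest elements sit under the indenter axis at the top surface (the
    contact zone); spacing grows geometrically toward the free side and the
    bonded bottom. Boundary node sets {bottom, axis, side, top} are tagged.
    """
    params = params or MeshParams()
    if geometry.height < 2.0 * params.fine_size:
        raise ValueError(
            f"degenerate geometry: height {geometry.height} µm < 2×fine_size "
            f"{params.fine_size} µm"
        )
    # radial coordinates: fine near the axis
    r = graded_line(geometry.radius, params.fine_size, params.coarse_size,
                    params.growth, fine_span=params.refine_radius)
    # vertical: fine near the top surface; measure depth from the top
    depth_span = min(params.refine_radius, geometry.height / 2.0)
    depth = graded_line(geometry.height, params.fine_size, params.coarse_size,
                        params.growth, fine_span=depth_span)
    z = geometry.height - depth[::-1]  # ascending, z=0 bottom … z=h top
    z = np.ascontiguousarray(z)
    z[0] = 0.0

    nr, nz = len(r), len(z)
    rr, zz = np.meshgrid(r, z, indexing="ij")
    nodes = np.column_stack([rr.ravel(), zz.ravel()])  # node id = i*nz + j

    i, j = np.meshgrid(np.arange(nr - 1), np.arange(nz - 1), indexing="ij")
    n00 = (i * nz + j).ravel()
    n10 = ((i + 1) * nz + j).ravel()
    n11 = ((i + 1) * nz + j + 1).ravel()
    n01 = (i * nz + j + 1).ravel()
    elements = np.column_stack([n00, n10, n11, n01]).astype(np.int64)

    ids = np.arange(nodes.shape[0])
    boundary = {
        "bottom": ids[nodes[:, 1] == 0.0],
        "top": ids[nodes[:, 1] == geometry.height],
        "axis": ids[nodes[:, 0] == 0.0],
        "side": ids[nodes[:, 0] == geometry.radius],
    }
    mesh = AxisymMesh(nodes=nodes, elements=elements, boundary=boundary)
    log.info(
        "mesh: %d nodes, %d elements (%d radial × %d vertical)",
        mesh.n_nodes, mesh.n_elements, nr - 1, nz - 1,
    )
    return mesh
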