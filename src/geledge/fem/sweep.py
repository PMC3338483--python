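"""Effective stiffness and interface stress across a range of gel heights."""

from __future__ import annotations

import logging
import time

import numpy as np
import pandas as pd

from geledge.fem.contact import solve_contact_indentation
from geledge.fem.mesh import build_axisym_mesh
from geledge.fem.postprocess import (
    effective_stiffness,
    interface_stress,
    von_mises_field,
)
from geledge.fem.types import (
    AxisymMesh,
    ElasticMaterial,
    GelGeometry,
    IndentationResult,
    IndenterSpec,
    MeshParams,
)

log = logging.getLogger(__name__)

SWEEP_COLUMNS = ["height_um", "stiffness_N_per_m", "max_vm_Pa", "interface_vm_Pa"]


def height_sweep(
    heights: list[float],
    material: ElasticMaterial,
    indenter: IndenterSpec,
    mesh_params: MeshParams | None = None,
    gel_radius: float = 500.0,
    keep_fields: bool = False,
) -> pd.DataFrame | tuple[pd.DataFrame, dict[float, tuple[AxisymMesh, IndentationResult]]]:
    """Solve the indentation at each gel height and tabulate stiffness/stress.

    Returns a DataFrame sorted by ascending height with columns
    ``height_um, stiffness_N_per_m, max_vm_Pa, interface_vm_Pa``. With
    ``keep_fields`` the per-height (mesh, result) pairs are returned too,
    e.g. for VTK export of the stress fields.
    """
    if len(heights) == 0:
        raise ValueError("heights list is empty")
    if any(h <= 0 for h in heights):
        raise ValueError("heights must be positive")
    rows = []
    fields: dict[float, tuple[AxisymMesh, IndentationResult]] = {}
    for h in sorted(heights):
        t0 = time.perf_counter()
        try:
            mesh = build_axisym_mesh(GelGeometry(height=h, radius=gel_radius),
                                     mesh_params)
            result = solve_contact_indentation(mesh, material, indenter)
        except Exception as err:
            raise RuntimeError(f"height sweep failed at h = {h:g} µm") from err
        vm = von_mises_field(result)
        rows.append({
            "height_um": h,
            "stiffness_N_per_m": effective_stiffness(result),
            "max_vm_Pa": float(vm.max()),
            "interface_vm_Pa": interface_stress(result, mesh),
        })
        if keep_fields:
            fields[h] = (mesh, result)
        log.info(
            "h = %6.1f µm: %d elements, k = %.4g N/m, %.1f s",
            h, mesh.n_elements, rows[-1]["stiffness_N_per_m"],
            time.perf_counter() - t0,
        )
    table = pd.DataFrame(rows, columns=SWEEP_COLUMNS)
    if not np.all(np.diff(table["stiffness_N_per_m"]) <= 1e-9):
        log.warning("stiffness is not monotone non-increasing in height")
    return (table, fields) if keep_fields else table
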