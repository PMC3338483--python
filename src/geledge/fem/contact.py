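"""Displacement-controlled frictionless contact with a rigid analytic sphere.

The sphere descends on the symmetry axis. Top-surface nodes under the sphere
carry a unilateral non-penetration constraint on u_z only (frictionless: the
radial dof stays free); the active set is found by direct elimination —
prescribe u_z on the trial contact set, then release nodes whose reaction is
tensile and add free nodes that penetrate, until the set is consistent.

For linear elasticity this problem is path-independent; the load stepping
exists to trace the force–deflection curve F(δ), whose superlinearity comes
entirely from the growing contact area.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from geledge.fem.assembly import assemble_system, element_stresses
from geledge.fem.types import (
    UM,
    AxisymMesh,
    ElasticMaterial,
    IndentationResult,
    IndenterSpec,
)


class ContactConvergenceError(RuntimeError):
    """Active set failed to settle; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[int, int]]):
        super().__init__(f"{message}; (iteration, active-set size) trace: {trace}")
        self.trace = trace


def sphere_gap(r_um: np.ndarray, radius_um: float, depth_um: float) -> np.ndarray:
    """Vertical gap g(r) (µm) between the undeformed surface and the sphere.

    The surface node at radius r may move down to at most u_z = g(r); g < 0
    under the indenter. Valid for r < R.
    """
    return -depth_um + radius_um - np.sqrt(radius_um**2 - r_um**2)


def _solve_dirichlet(k: sp.csr_matrix, fixed: np.ndarray, values: np.ndarray):
    """Solve K u = 0 subject to u[fixed] = values; return (u, reactions[fixed])."""
    n = k.shape[0]
    free = np.setdiff1d(np.arange(n), fixed, assume_unique=False)
    kff = k[free][:, free].tocsc()
    kfc = k[free][:, fixed]
    rhs = -kfc @ values
    try:
        u_free = spla.splu(kff).solve(rhs)
    except RuntimeError as err:  # pragma: no cover - defensive
        raise RuntimeError(
            "singular stiffness after constraints: an unconstrained rigid-body "
            "mode remains (check bottom/axis boundary tags)"
        ) from err
    u = np.zeros(n)
    u[free] = u_free
    u[fixed] = values
    reactions = k[fixed] @ u
    return u, reactions


def solve_contact_indentation(
    mesh: AxisymMesh,
    material: ElasticMaterial,
    indenter: IndenterSpec,
    max_active_iter: int = 60,
) -> IndentationResult:
    """Run the incremental indentation and return forces, fields and stresses.

    Reaction force at each step is the sum of vertical nodal reactions on the
    contact set (reported positive). Displacements/stresses are stored for
    the final step.
    """
    k = assemble_system(mesh, material)
    nodes = mesh.nodes
    top = mesh.boundary["top"]
    bottom = mesh.boundary["bottom"]
    axis = mesh.boundary["axis"]

    dirichlet = np.unique(np.concatenate([2 * bottom, 2 * bottom + 1, 2 * axis]))
    candidates = top[nodes[top, 0] < indenter.radius]
    cand_r = nodes[candidates, 0]

    steps = [(0.0, 0.0)]
    u = np.zeros(2 * mesh.n_nodes)
    active_mask = np.zeros(len(candidates), dtype=bool)

    depths = indenter.max_depth * np.arange(1, indenter.n_steps + 1) / indenter.n_steps
    for depth in depths:
        gap_um = sphere_gap(cand_r, indenter.radius, depth)
        gap_m = gap_um * UM
        # warm start: keep previous contacts, add rigid-overlap nodes
        active_mask |= gap_um < 0.0
        trace: list[tuple[int, int]] = []
        seen: set[bytes] = set()
        force = 0.0
        for it in range(max_active_iter):
            act = candidates[active_mask]
            fixed = np.concatenate([dirichlet, 2 * act + 1])
            values = np.concatenate([np.zeros(len(dirichlet)), gap_m[active_mask]])
            u, reactions = _solve_dirichlet(k, fixed, values)
            contact_reac = reactions[len(dirichlet):]

            f_tol = 1e-8 * max(np.abs(contact_reac).max(initial=0.0), 1e-30)
            release = contact_reac > f_tol  # tensile: constraint pulls gel up
            uz_free = u[2 * candidates + 1]
            g_tol = 1e-9 * max(depth, 1.0) * UM
            penetrate = (~active_mask) & (uz_free > gap_m + g_tol)

            trace.append((it, int(active_mask.sum())))
            if not release.any() and not penetrate.any():
                force = -float(contact_reac.sum())
                break
            new_mask = active_mask.copy()
            new_mask[np.flatnonzero(active_mask)[release]] = False
            new_mask |= penetrate
            key = new_mask.tobytes()
            if key in seen:  # cycle guard: grow-only fallback
                new_mask |= active_mask
            seen.add(key)
            active_mask = new_mask
        else:
            raise ContactConvergenceError(
                f"active set did not converge at depth {depth:g} µm", trace
            )
        steps.append((float(depth), force))
        if not active_mask.any() and depth > 0:
            raise ContactConvergenceError(
                f"empty contact set at depth {depth:g} µm", trace
            )

    stresses = (
        element_stresses(mesh, material, u)
        if indenter.max_depth > 0
        else np.zeros((mesh.n_elements, 4))
    )
    return IndentationResult(
        steps=np.asarray(steps),
        displacements=u.reshape(-1, 2) / UM,
        stresses=stresses,
        contact_nodes=candidates[active_mask],
    )
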