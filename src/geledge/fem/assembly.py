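"""Axisymmetric small-strain linear elasticity on bilinear quads.

Element: 4-node axisymmetric quadrilateral, 2×2 Gauss quadrature on the
shear/deviatoric term and single-point (selective reduced) integration on the
volumetric λ-term, which keeps the element usable at Poisson ratios near 0.5
where full integration locks.

Strain ordering throughout: (ε_rr, ε_zz, ε_θθ, γ_rz); displacement dofs per
node are (u_r, u_z), global dof = 2·node + component. Assembly is in SI
(metres); mesh coordinates arrive in µm and are converted here.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from geledge.fem.types import UM, AxisymMesh, ElasticMaterial

# parent-coordinate nodes of the quad, counter-clockwise
_XI_NODES = np.array([[-1.0, -1.0], [1.0, -1.0], [1.0, 1.0], [-1.0, 1.0]])
_GP_2X2 = np.array([[x, y] for x in (-1.0, 1.0) for y in (-1.0, 1.0)]) / np.sqrt(3.0)


def _shape(xi: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shape functions N (4,) and parent gradients dN/dξ (4, 2) at point ξ."""
    n = 0.25 * (1.0 + _XI_NODES[:, 0] * xi[0]) * (1.0 + _XI_NODES[:, 1] * xi[1])
    dn = 0.25 * np.column_stack([
        _XI_NODES[:, 0] * (1.0 + _XI_NODES[:, 1] * xi[1]),
        _XI_NODES[:, 1] * (1.0 + _XI_NODES[:, 0] * xi[0]),
    ])
    return n, dn


def _b_matrices(coords: np.ndarray, xi: np.ndarray):
    """Vectorized B matrices at one parent point for all elements.

    coords: (E, 4, 2) element node coordinates in metres.
    Returns B (E, 4, 8), detJ (E,), r_gp (E,).
    """
    n, dn = _shape(xi)
    # J_{kl} = Σ_a coords[a, k] · dn[a, l]
    jac = np.einsum("eak,al->ekl", coords, dn)
    det = jac[:, 0, 0] * jac[:, 1, 1] - jac[:, 0, 1] * jac[:, 1, 0]
    if np.any(det <= 0):
        raise ValueError("inverted element (non-positive Jacobian)")
    inv = np.empty_like(jac)
    inv[:, 0, 0] = jac[:, 1, 1]
    inv[:, 1, 1] = jac[:, 0, 0]
    inv[:, 0, 1] = -jac[:, 0, 1]
    inv[:, 1, 0] = -jac[:, 1, 0]
    inv /= det[:, None, None]
    # dN_a/dx_k = Σ_l dn[a, l] inv[l, k]
    dndx = np.einsum("al,elk->eak", dn, inv)
    r_gp = coords[:, :, 0] @ n

    ne = coords.shape[0]
    b = np.zeros((ne, 4, 8))
    for a in range(4):
        b[:, 0, 2 * a] = dndx[:, a, 0]          # ε_rr ← u_r
        b[:, 1, 2 * a + 1] = dndx[:, a, 1]      # ε_zz ← u_z
        b[:, 2, 2 * a] = n[a] / r_gp            # ε_θθ ← u_r / r
        b[:, 3, 2 * a] = dndx[:, a, 1]          # γ_rz ← u_r
        b[:, 3, 2 * a + 1] = dndx[:, a, 0]      # γ_rz ← u_z
    return b, det, r_gp


def elasticity_matrices(material: ElasticMaterial) -> tuple[np.ndarray, np.ndarray]:
    """(D_μ, D_λ) split of the isotropic stiffness: D = D_μ + D_λ."""
    mu = material.shear_modulus
    lam = material.lame_lambda
    d_mu = np.diag([2.0 * mu, 2.0 * mu, 2.0 * mu, mu])
    v = np.array([1.0, 1.0, 1.0, 0.0])
    d_lam = lam * np.outer(v, v)
    return d_mu, d_lam


def assemble_system(mesh: AxisymMesh, material: ElasticMaterial) -> sp.csr_matrix:
    """Assemble the global stiffness operator K (N/m per dof pair), SI units.

    Symmetric by construction; positive definite once the bottom (u_r = u_z
    = 0) and axis (u_r = 0) constraints are imposed.
    """
    coords = mesh.nodes[mesh.elements] * UM  # (E, 4, 2) metres
    d_mu, d_lam = elasticity_matrices(material)

    ke = np.zeros((mesh.n_elements, 8, 8))
    for gp in _GP_2X2:
        b, det, r = _b_matrices(coords, gp)
        w = 2.0 * np.pi * r * det  # gauss weight 1
        ke += np.einsum("eji,jk,ekl,e->eil", b, d_mu, b, w, optimize=True)
    b, det, r = _b_matrices(coords, np.zeros(2))
    w = 4.0 * 2.0 * np.pi * r * det  # centroid weight 4
    ke += np.einsum("eji,jk,ekl,e->eil", b, d_lam, b, w, optimize=True)

    dofs = np.empty((mesh.n_elements, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    rows = np.repeat(dofs, 8, axis=1).ravel()
    cols = np.tile(dofs, (1, 8)).ravel()
    k = sp.coo_matrix(
        (ke.ravel(), (rows, cols)), shape=(2 * mesh.n_nodes, 2 * mesh.n_nodes)
    ).tocsr()
    # enforce exact symmetry against floating-point asymmetry in assembly order
    return (k + k.T) * 0.5


def element_stresses(mesh: AxisymMesh, material: ElasticMaterial,
                     u: np.ndarray) -> np.ndarray:
    """Centroid stresses (σ_rr, σ_zz, σ_θθ, σ_rz) in Pa from displacements.

    ``u`` is the flat displacement vector in metres (SI, as solved).
    """
    coords = mesh.nodes[mesh.elements] * UM
    d_mu, d_lam = elasticity_matrices(material)
    d = d_mu + d_lam
    b, _, _ = _b_matrices(coords, np.zeros(2))
    dofs = np.empty((mesh.n_elements, 8), dtype=np.int64)
    dofs[:, 0::2] = 2 * mesh.elements
    dofs[:, 1::2] = 2 * mesh.elements + 1
    strain = np.einsum("eij,ej->ei", b, u[dofs])
    return strain @ d.T
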