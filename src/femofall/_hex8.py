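"""Trilinear 8-node hexahedron kernels (shape functions, B-bar operators).

Voigt convention: strain = [exx, eyy, ezz, gxy, gyz, gzx] with engineering
shears; stress = [sxx, syy, szz, sxy, syz, szx].  The volumetric part of the
strain-displacement operator is replaced by its element average (B-bar) to
avoid volumetric locking at nu = 0.3.
"""

from __future__ import annotations

import numpy as np

# natural coordinates of the corner nodes, VTK hexahedron ordering
NODE_XI = np.array(
    [
        [-1, -1, -1],
        [1, -1, -1],
        [1, 1, -1],
        [-1, 1, -1],
        [-1, -1, 1],
        [1, -1, 1],
        [1, 1, 1],
        [-1, 1, 1],
    ],
    dtype=float,
)

_g = 1.0 / np.sqrt(3.0)
GAUSS_POINTS = np.array(
    [[sx * _g, sy * _g, sz * _g] for sz in (-1, 1) for sy in (-1, 1) for sx in (-1, 1)]
)
GAUSS_WEIGHTS = np.ones(8)


def shape_functions(xi: np.ndarray) -> np.ndarray:
    """N_a(xi) for points ``xi`` of shape (m, 3); returns (m, 8)."""
    xi = np.atleast_2d(xi)
    return 0.125 * np.prod(1.0 + xi[:, None, :] * NODE_XI[None, :, :], axis=2)


def shape_gradients(xi: np.ndarray) -> np.ndarray:
    """dN_a/dxi_j at points ``xi`` (m, 3); returns (m, 8, 3)."""
    xi = np.atleast_2d(xi)
    m = xi.shape[0]
    grad = np.empty((m, 8, 3))
    for j in range(3):
        terms = 1.0 + xi[:, None, :] * NODE_XI[None, :, :]  # (m,8,3)
        prod = np.ones((m, 8))
        for k in range(3):
            if k != j:
                prod = prod * terms[:, :, k]
        grad[:, :, j] = 0.125 * NODE_XI[None, :, j] * prod
    return grad


_GRAD_GP = shape_gradients(GAUSS_POINTS)  # (8gp, 8node, 3)


def element_geometry(coords: np.ndarray):
    """Per-Gauss-point spatial gradients and Jacobian determinants.

    ``coords``: (n_elem, 8, 3) nodal coordinates.
    Returns ``dNdx`` (n_elem, 8gp, 8node, 3) and ``detJ`` (n_elem, 8gp).
    """
    # J[e,g,i,j] = sum_a dN[g,a,i] * x[e,a,j]  (i.e. d x_j / d xi_i)
    J = np.einsum("gai,eaj->egij", _GRAD_GP, coords)
    detJ = np.linalg.det(J)
    Jinv = np.linalg.inv(J)
    # dN/dx_j = sum_i dN/dxi_i * dxi_i/dx_j with (dxi/dx) = (dx/dxi)^-1,
    # whose (i, j) entry is Jinv[j, i] in this storage convention
    dNdx = np.einsum("gai,egji->egaj", _GRAD_GP, Jinv)
    return dNdx, detJ


def bbar_matrices(coords: np.ndarray):
    """B-bar strain-displacement matrices for a batch of elements.

    Returns ``B`` (n_elem, 8gp, 6, 24), integration weights ``w`` =
    detJ * gauss weight (n_elem, 8gp) and element volumes (n_elem,).
    """
    n_elem = coords.shape[0]
    dNdx, detJ = element_geometry(coords)
    if np.any(detJ <= 0):
        e = int(np.argwhere(detJ <= 0)[0][0])
        raise ValueError(f"non-positive Jacobian in element {e}")
    w = detJ * GAUSS_WEIGHTS[None, :]
    vol = w.sum(axis=1)
    # element-averaged gradients for the volumetric part
    dNdx_bar = np.einsum("egaj,eg->eaj", dNdx, w) / vol[:, None, None]

    B = np.zeros((n_elem, 8, 6, 24))
    cols = np.arange(8) * 3
    for a in range(8):
        bx = dNdx[:, :, a, 0]
        by = dNdx[:, :, a, 1]
        bz = dNdx[:, :, a, 2]
        # deviatoric-consistent B-bar correction on the normal rows
        cx = (dNdx_bar[:, None, a, 0] - bx) / 3.0
        cy = (dNdx_bar[:, None, a, 1] - by) / 3.0
        cz = (dNdx_bar[:, None, a, 2] - bz) / 3.0
        B[:, :, 0, cols[a] + 0] = bx + cx
        B[:, :, 0, cols[a] + 1] = cy
        B[:, :, 0, cols[a] + 2] = cz
        B[:, :, 1, cols[a] + 0] = cx
        B[:, :, 1, cols[a] + 1] = by + cy
        B[:, :, 1, cols[a] + 2] = cz
        B[:, :, 2, cols[a] + 0] = cx
        B[:, :, 2, cols[a] + 1] = cy
        B[:, :, 2, cols[a] + 2] = bz + cz
        B[:, :, 3, cols[a] + 0] = by
        B[:, :, 3, cols[a] + 1] = bx
        B[:, :, 4, cols[a] + 1] = bz
        B[:, :, 4, cols[a] + 2] = by
        B[:, :, 5, cols[a] + 0] = bz
        B[:, :, 5, cols[a] + 2] = bx
    return B, w, vol


def full_b_matrices(coords: np.ndarray):
    """Standard (non-B-bar) strain-displacement matrices, same shapes."""
    n_elem = coords.shape[0]
    dNdx, detJ = element_geometry(coords)
    if np.any(detJ <= 0):
        e = int(np.argwhere(detJ <= 0)[0][0])
        raise ValueError(f"non-positive Jacobian in element {e}")
    w = detJ * GAUSS_WEIGHTS[None, :]
    B = np.zeros((n_elem, 8, 6, 24))
    cols = np.arange(8) * 3
    for a in range(8):
        bx = dNdx[:, :, a, 0]
        by = dNdx[:, :, a, 1]
        bz = dNdx[:, :, a, 2]
        B[:, :, 0, cols[a] + 0] = bx
        B[:, :, 1, cols[a] + 1] = by
        B[:, :, 2, cols[a] + 2] = bz
        B[:, :, 3, cols[a] + 0] = by
        B[:, :, 3, cols[a] + 1] = bx
        B[:, :, 4, cols[a] + 1] = bz
        B[:, :, 4, cols[a] + 2] = by
        B[:, :, 5, cols[a] + 0] = bz
        B[:, :, 5, cols[a] + 2] = bx
    return B, w, w.sum(axis=1)
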