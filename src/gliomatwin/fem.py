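"""First-order Lagrange (P1) finite-element primitives on simplicial meshes.

Everything downstream (forward model, Matérn prior, adjoints) is built on the
handful of operations here: simplex geometry, consistent/lumped mass matrices,
stiffness matrices with piecewise-constant coefficients, boundary mass
matrices, and the gradient-pairing scatter used by the adjoint gradient of the
log-diffusion field.
"""

from __future__ import annotations

import math

import numpy as np
import scipy.sparse as sp


def simplex_geometry(vertices: np.ndarray, cells: np.ndarray):
    """Volumes and P1 basis gradients of every simplex.

    Returns
    -------
    volumes : (nc,) array
        Unsigned simplex measures (area in 2-D, volume in 3-D).
    grads : (nc, d+1, d) array
        Constant gradient of each barycentric basis function on each cell.
    """
    d = vertices.shape[1]
    x0 = vertices[cells[:, 0]]
    # E[:, :, k] = x_{k+1} - x_0 : edge vectors as matrix columns
    E = np.stack([vertices[cells[:, k + 1]] - x0 for k in range(d)], axis=2)
    detE = np.linalg.det(E)
    volumes = np.abs(detE) / math.factorial(d)
    if np.any(volumes <= 0.0) or np.any(~np.isfinite(volumes)):
        bad = int(np.argmin(volumes))
        raise ValueError(
            f"degenerate mesh: cell {bad} has zero/invalid measure {volumes[bad]!r}"
        )
    Einv = np.linalg.inv(E)
    grads = np.empty((len(cells), d + 1, d))
    grads[:, 1:, :] = Einv  # grad(lambda_{i+1}) is row i of E^{-1}
    grads[:, 0, :] = -Einv.sum(axis=1)
    return volumes, grads


def _assemble(cells: np.ndarray, local: np.ndarray, n: int) -> sp.csr_matrix:
    """Scatter (nc, k, k) local matrices into an n x n CSR matrix."""
    k = cells.shape[1]
    rows = np.repeat(cells, k, axis=1).ravel()
    cols = np.tile(cells, (1, k)).ravel()
    return sp.coo_matrix((local.ravel(), (rows, cols)), shape=(n, n)).tocsr()


def mass_matrix(vertices, cells, volumes) -> sp.csr_matrix:
    """Consistent P1 mass matrix: vol * (1 + delta_ij) / ((d+1)(d+2))."""
    d = vertices.shape[1]
    base = (np.ones((d + 1, d + 1)) + np.eye(d + 1)) / ((d + 1) * (d + 2))
    local = volumes[:, None, None] * base[None, :, :]
    return _assemble(cells, local, len(vertices))


def lumped_mass(vertices, cells, volumes) -> np.ndarray:
    """Row-sum (vertex-quadrature) lumped mass as a vector."""
    d = vertices.shape[1]
    ml = np.zeros(len(vertices))
    np.add.at(ml, cells.ravel(), np.repeat(volumes / (d + 1), d + 1))
    return ml


def stiffness_matrix(cells, volumes, grads, coeff_e=None) -> sp.csr_matrix:
    """P1 stiffness with a piecewise-constant (per-cell) coefficient."""
    w = volumes if coeff_e is None else volumes * coeff_e
    local = w[:, None, None] * np.einsum("cid,cjd->cij", grads, grads)
    n = int(cells.max()) + 1
    return _assemble(cells, local, n)


def cell_mean(cells: np.ndarray, nodal: np.ndarray) -> np.ndarray:
    """Per-cell arithmetic mean of a nodal field (the coefficient rule)."""
    return nodal[cells].mean(axis=1)


def grad_pairing_per_vertex(cells, volumes, grads, u, p) -> np.ndarray:
    """Scatter of vol_e * (grad u . grad p)|_e to the vertices of e.

    Used by the adjoint gradient of the log-diffusion block: with the
    coefficient rule D_e = mean_i exp(mD_i), d(p^T K(mD) u)/dmD_j
    = exp(mD_j)/(d+1) * sum_{e owns j} vol_e (grad p . grad u)|_e, and this
    helper returns the inner sum for every vertex j.
    """
    gu = np.einsum("cid,ci->cd", grads, u[cells])
    gp = np.einsum("cid,ci->cd", grads, p[cells])
    per_cell = volumes * np.einsum("cd,cd->c", gu, gp)
    d1 = cells.shape[1]
    out = np.zeros(int(cells.max()) + 1)
    np.add.at(out, cells.ravel(), np.repeat(per_cell / d1, d1))
    return out


def boundary_facets(cells: np.ndarray) -> np.ndarray:
    """Facets ((d-1)-simplices) that belong to exactly one cell."""
    d1 = cells.shape[1]
    idx = [[j for j in range(d1) if j != i] for i in range(d1)]
    facets = np.concatenate([cells[:, ix] for ix in idx], axis=0)
    facets_sorted = np.sort(facets, axis=1)
    _, first, counts = np.unique(
        facets_sorted, axis=0, return_index=True, return_counts=True
    )
    return facets_sorted[first[counts == 1]]


def boundary_mass_matrix(vertices, facets, n=None) -> sp.csr_matrix:
    """Mass matrix of the boundary trace (edge/face mass), for Robin terms."""
    if n is None:
        n = len(vertices)
    if len(facets) == 0:
        return sp.csr_matrix((n, n))
    k = facets.shape[1]  # 2 in 2-D (edges), 3 in 3-D (triangles)
    x0 = vertices[facets[:, 0]]
    E = np.stack([vertices[facets[:, j + 1]] - x0 for j in range(k - 1)], axis=2)
    gram = np.einsum("nik,nil->nkl", E, E)
    meas = np.sqrt(np.abs(np.linalg.det(gram))) / math.factorial(k - 1)
    base = (np.ones((k, k)) + np.eye(k)) / (k * (k + 1))
    local = meas[:, None, None] * base[None, :, :]
    return _assemble(facets, local, n)
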