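"""Computational domain: simplicial tissue mesh and the voxel observation grid.

The domain is a disk (2-D, default) or ball (3-D) standing in for brain
anatomy, carrying a per-vertex gray/white tissue label.  Observations live on
an axis-aligned voxel grid; the mesh-to-voxel interpolation contract used by
the whole package is the P1 (barycentric) interpolation matrix built here.

Units: coordinates and spacings in millimetres.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import numpy as np
import scipy.sparse as sp
from scipy.spatial import Delaunay

from . import fem

GRAY, WHITE = 1, 0

MASKED_SENTINEL = np.nan


@dataclass
class TissueDomain:
    """Conforming simplicial mesh with gray/white labels.

    Attributes
    ----------
    vertices : (nv, dim) float array, mm
    cells : (nc, dim+1) int array, simplex connectivity
    tissue_label : (nv,) uint8, 1 = gray matter, 0 = white matter
    """

    dim: int
    vertices: np.ndarray
    cells: np.ndarray
    tissue_label: np.ndarray
    _tri: Delaunay | None = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        self.vertices = np.ascontiguousarray(self.vertices, dtype=float)
        self.cells = np.ascontiguousarray(self.cells, dtype=np.int64)
        self.tissue_label = np.ascontiguousarray(self.tissue_label, dtype=np.uint8)
        if self.vertices.shape[1] != self.dim:
            raise ValueError("vertex coordinates do not match dim")
        if len(self.tissue_label) != len(self.vertices):
            raise ValueError("every vertex needs exactly one tissue label")
        # geometry check happens here; raises on degenerate (zero-measure) cells
        self.cell_volumes, self.basis_grads = fem.simplex_geometry(
            self.vertices, self.cells
        )

    # -- FEM operators -----------------------------------------------------
    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @cached_property
    def mass(self) -> sp.csr_matrix:
        return fem.mass_matrix(self.vertices, self.cells, self.cell_volumes)

    @cached_property
    def lumped_mass(self) -> np.ndarray:
        return fem.lumped_mass(self.vertices, self.cells, self.cell_volumes)

    @cached_property
    def boundary_facets(self) -> np.ndarray:
        return fem.boundary_facets(self.cells)

    @cached_property
    def boundary_mass(self) -> sp.csr_matrix:
        return fem.boundary_mass_matrix(
            self.vertices, self.boundary_facets, self.n_vertices
        )

    @cached_property
    def boundary_vertices(self) -> np.ndarray:
        return np.unique(self.boundary_facets.ravel())

    def stiffness(self, coeff_nodal: np.ndarray | None = None) -> sp.csr_matrix:
        """Stiffness matrix; a nodal coefficient is averaged per cell."""
        ce = None if coeff_nodal is None else fem.cell_mean(self.cells, coeff_nodal)
        return fem.stiffness_matrix(
            self.cells, self.cell_volumes, self.basis_grads, ce
        )

    def grad_pairing(self, u: np.ndarray, p: np.ndarray) -> np.ndarray:
        return fem.grad_pairing_per_vertex(
            self.cells, self.cell_volumes, self.basis_grads, u, p
        )

    @property
    def volume(self) -> float:
        """Total measure of the domain (area in 2-D)."""
        return float(self.cell_volumes.sum())

    # -- point location / interpolation ------------------------------------
    @property
    def triangulation(self) -> Delaunay:
        if self._tri is None:
            self._tri = Delaunay(self.vertices)
        return self._tri

    def contains(self, points: np.ndarray) -> np.ndarray:
        return self.triangulation.find_simplex(points) >= 0

    def interpolation_matrix(self, points: np.ndarray) -> sp.csr_matrix:
        """Sparse (npts, nv) P1 interpolation matrix at arbitrary points.

        Points outside the mesh fall back to the nearest vertex (weight one);
        callers that must exclude outside points should mask beforehand.
        """
        tri = self.triangulation
        points = np.atleast_2d(np.asarray(points, dtype=float))
        simplex = tri.find_simplex(points)
        inside = simplex >= 0
        d = self.dim
        rows, cols, vals = [], [], []
        if np.any(inside):
            s = simplex[inside]
            X = tri.transform[s]
            bary_d = np.einsum(
                "nij,nj->ni", X[:, :d, :], points[inside] - X[:, d, :]
            )
            bary = np.concatenate([bary_d, 1.0 - bary_d.sum(axis=1, keepdims=True)], axis=1)
            simp_verts = tri.simplices[s]
            idx = np.where(inside)[0]
            rows.append(np.repeat(idx, d + 1))
            cols.append(simp_verts.ravel())
            vals.append(bary.ravel())
        if np.any(~inside):
            idx = np.where(~inside)[0]
            d2 = ((points[idx, None, :] - self.vertices[None, :, :]) ** 2).sum(axis=2)
            nearest = np.argmin(d2, axis=1)
            rows.append(idx)
            cols.append(nearest)
            vals.append(np.ones(len(idx)))
        rows = np.concatenate(rows)
        cols = np.concatenate(cols)
        vals = np.concatenate(vals)
        return sp.coo_matrix(
            (vals, (rows, cols)), shape=(len(points), self.n_vertices)
        ).tocsr()


@dataclass
class VoxelGrid:
    """Axis-aligned voxel grid covering the mesh bounding box.

    Voxel centers sit at ``origin + (index + 0.5) * spacing`` (0-based
    indices).  ``inside_mask`` is True where the center lies inside the mesh;
    the likelihood sees exactly the ``n_observed`` unmasked voxels.
    """

    origin: np.ndarray
    spacing: np.ndarray
    shape: tuple
    inside_mask: np.ndarray

    @property
    def n_observed(self) -> int:
        return int(self.inside_mask.sum())

    def centers(self) -> np.ndarray:
        """Centers of ALL voxels, shape (prod(shape), dim), C-order."""
        axes = [
            self.origin[a] + (np.arange(self.shape[a]) + 0.5) * self.spacing[a]
            for a in range(len(self.shape))
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    def observed_centers(self) -> np.ndarray:
        return self.centers()[self.inside_mask.ravel()]


def build_synthetic_brain(
    dim: int = 2,
    radius_mm: float = 50.0,
    h_mm: float = 2.0,
    tissue_spec: str = "annulus",
    seed: int = 0,
) -> TissueDomain:
    """Disk (2-D) or ball (3-D) domain with a deterministic tissue partition.

    ``tissue_spec`` options:

    - ``"annulus"`` (default): gray-matter rim for r >= 0.65 * radius, white
      core — a cartoon of cortical gray surrounding white matter;
      ``"annulus:<frac>"`` sets the rim start fraction.
    - ``"all_white"`` / ``"all_gray"``: uniform label.
    - ``"blobs:<n>"``: n seeded gray blobs on white background.

    Same inputs and seed give byte-identical vertex/label arrays.
    """
    if radius_mm <= 0 or h_mm <= 0:
        raise ValueError("radius_mm and h_mm must be positive")
    if not h_mm < radius_mm / 4:
        raise ValueError("h_mm must be smaller than radius_mm / 4")
    if dim == 2:
        pts = _disk_points(radius_mm, h_mm)
    elif dim == 3:
        pts = _ball_points(radius_mm, h_mm)
    else:
        raise ValueError("dim must be 2 or 3")
    tri = Delaunay(pts)
    labels = _tissue_labels(pts, radius_mm, tissue_spec, seed)
    return TissueDomain(
        dim=dim, vertices=pts, cells=tri.simplices, tissue_label=labels, _tri=tri
    )


def _disk_points(radius: float, h: float) -> np.ndarray:
    nring = max(4, int(round(radius / h)))
    pts = [np.zeros((1, 2))]
    for k in range(1, nring + 1):
        r = radius * k / nring
        n = max(6, int(round(2 * np.pi * r / h)))
        offset = (k % 2) * np.pi / n  # stagger alternate rings for quality
        theta = offset + 2 * np.pi * np.arange(n) / n
        pts.append(np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1))
    return np.concatenate(pts, axis=0)


def _fibonacci_sphere(n: int) -> np.ndarray:
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    golden = np.pi * (1 + 5**0.5)
    theta = golden * i
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def _ball_points(radius: float, h: float) -> np.ndarray:
    nshell = max(3, int(round(radius / h)))
    pts = [np.zeros((1, 3))]
    for k in range(1, nshell + 1):
        r = radius * k / nshell
        n = max(6, int(round(4 * np.pi * r**2 / h**2)))
        pts.append(r * _fibonacci_sphere(n))
    return np.concatenate(pts, axis=0)


def _tissue_labels(pts, radius, tissue_spec, seed) -> np.ndarray:
    r = np.linalg.norm(pts, axis=1)
    spec, _, arg = tissue_spec.partition(":")
    if spec == "annulus":
        frac = float(arg) if arg else 0.65
        return (r >= frac * radius).astype(np.uint8)
    if spec == "all_white":
        return np.zeros(len(pts), dtype=np.uint8)
    if spec == "all_gray":
        return np.ones(len(pts), dtype=np.uint8)
    if spec == "blobs":
        nblob = int(arg) if arg else 4
        rng = np.random.default_rng(seed)
        centers = rng.uniform(-0.7 * radius, 0.7 * radius, size=(nblob, pts.shape[1]))
        width = 0.25 * radius
        lab = np.zeros(len(pts), dtype=np.uint8)
        for c in centers:
            lab |= (np.linalg.norm(pts - c, axis=1) < width).astype(np.uint8)
        return lab
    raise ValueError(f"unknown tissue_spec {tissue_spec!r}")


def make_voxel_grid(domain: TissueDomain, spacing_mm) -> VoxelGrid:
    """Voxel grid whose bounding box covers the mesh, masked to the inside."""
    spacing = np.broadcast_to(
        np.atleast_1d(np.asarray(spacing_mm, dtype=float)), (domain.dim,)
    ).copy()
    if np.any(spacing <= 0):
        raise ValueError("spacing must be strictly positive")
    lo = domain.vertices.min(axis=0)
    hi = domain.vertices.max(axis=0)
    extent = hi - lo
    if np.any(spacing > extent):
        raise ValueError("spacing exceeds the domain extent")
    shape = tuple(np.ceil(extent / spacing).astype(int))
    origin = lo - (np.array(shape) * spacing - extent) / 2  # center the grid
    grid = VoxelGrid(
        origin=origin, spacing=spacing, shape=shape,
        inside_mask=np.zeros(shape, dtype=bool),
    )
    inside = domain.contains(grid.centers())
    grid.inside_mask = inside.reshape(shape)
    return grid


def observation_matrix(domain: TissueDomain, grid: VoxelGrid) -> sp.csr_matrix:
    """(n_observed, nv) P1 interpolation matrix at unmasked voxel centers."""
    return domain.interpolation_matrix(grid.observed_centers())


def voxels_to_fem(
    observed_values: np.ndarray, grid: VoxelGrid, domain: TissueDomain
) -> np.ndarray:
    """Nearest-voxel lookup of unmasked voxel values at mesh vertices.

    The inverse direction of the observation operator, used to initialize a
    prediction from measured data (voxels outside the mask contribute 0).
    Piecewise-constant by construction; adequate for initial conditions.
    """
    full = np.zeros(grid.shape)
    full[grid.inside_mask] = np.asarray(observed_values, dtype=float)
    idx = np.floor((domain.vertices - grid.origin[None, :]) / grid.spacing[None, :])
    idx = np.clip(idx, 0, np.asarray(grid.shape) - 1).astype(int)
    return full[tuple(idx.T)]


def fem_to_voxels(field: np.ndarray, domain: TissueDomain, grid: VoxelGrid) -> np.ndarray:
    """Interpolate a nodal field to the voxel grid.

    Returns the full-shape voxel array with NaN in masked (outside) voxels.
    Piecewise-linear, so linear functions are reproduced exactly.
    """
    field = np.asarray(field, dtype=float)
    if field.shape != (domain.n_vertices,):
        raise ValueError("field must be nodal on this domain's mesh")
    out = np.full(grid.shape, MASKED_SENTINEL)
    vals = observation_matrix(domain, grid) @ field
    out[grid.inside_mask] = vals
    return out
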