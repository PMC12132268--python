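"""Light-weight export of meshes, nodal fields and voxel arrays.

Meshes and nodal fields go to legacy ASCII VTK (readable by ParaView and
common mesh tools); voxel arrays optionally to NIfTI via nibabel for
interoperability with imaging pipelines; trajectories to a delimited table.
"""

from __future__ import annotations

import numpy as np

from .geometry import TissueDomain, VoxelGrid

_VTK_CELL = {2: 5, 3: 10}  # triangle, tetrahedron


def write_vtk(path, domain: TissueDomain, point_data: dict | None = None) -> None:
    """Write the mesh and named nodal fields as legacy ASCII VTK."""
    pts = domain.vertices
    nv, d = pts.shape
    xyz = np.zeros((nv, 3))
    xyz[:, :d] = pts
    cells = domain.cells
    nc, k = cells.shape
    with open(path, "w") as f:
        f.write("# vtk DataFile Version 3.0\ngliomatwin mesh\nASCII\n")
        f.write("DATASET UNSTRUCTURED_GRID\n")
        f.write(f"POINTS {nv} double\n")
        np.savetxt(f, xyz, fmt="%.10g")
        f.write(f"CELLS {nc} {nc * (k + 1)}\n")
        np.savetxt(f, np.column_stack([np.full(nc, k), cells]), fmt="%d")
        f.write(f"CELL_TYPES {nc}\n")
        np.savetxt(f, np.full(nc, _VTK_CELL[d]), fmt="%d")
        data = {"tissue_label": domain.tissue_label.astype(float)}
        data.update(point_data or {})
        f.write(f"POINT_DATA {nv}\n")
        for name, arr in data.items():
            f.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(f, np.asarray(arr, dtype=float), fmt="%.10g")


def write_trajectory_table(path, domain: TissueDomain, sol, threshold=0.1) -> None:
    """CSV of (time, total cellularity, tumor volume) along a trajectory."""
    from .qoi import total_tumor_cellularity, tumor_volume

    import pandas as pd

    rows = [
        {
            "time_days": t,
            "total_cellularity": total_tumor_cellularity(u, domain, threshold),
            "tumor_volume": tumor_volume(u, domain, threshold),
        }
        for t, u in zip(sol.times, sol.states)
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def save_voxels_nifti(path, voxels: np.ndarray, grid: VoxelGrid) -> None:
    """Write a voxel array as NIfTI with the grid's affine (requires nibabel)."""
    import nibabel as nib

    vol = np.asarray(voxels, dtype=np.float32)
    d = len(grid.shape)
    affine = np.eye(4)
    affine[:d, :d] = np.diag(grid.spacing)
    affine[:d, 3] = grid.origin + 0.5 * grid.spacing
    nib.save(nib.Nifti1Image(vol, affine), str(path))
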