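"""Voxelized ligand occupancy maps with fractional isosurface levels.

A :class:`DensityGrid` records, per voxel, the fraction of trajectory
frames in which the ligand visited that voxel — either its geometric
center (``centroid`` mode, exactly one voxel per frame) or any heavy atom
(``heavy-atoms`` mode).  Thresholding at 10/30/50% occupancy yields the
nested isolevel sets used to visualise a binding site.  Grids are written
as OpenDX scalar fields for molecular viewers.

The trajectory must be pre-aligned to a common reference (see
``structdev.superpose_trajectory``); a density accumulated over an
unaligned, freely tumbling system is meaningless, so the accumulator warns
unless told the frames are aligned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .trajmodel import Selection, Trajectory, centroid

__all__ = ["DensityGrid", "accumulate_density", "threshold_voxels", "write_dx"]


@dataclass
class DensityGrid:
    """Regular grid of per-voxel ligand occupancy fractions.

    origin : Å position of the (0,0,0) voxel corner.
    spacing : Å voxel edge length (cubic voxels).
    counts : int array (nx, ny, nz), frames in which the ligand visited
        the voxel (at most one count per frame per voxel).
    n_frames : total frames accumulated.
    """

    origin: np.ndarray
    spacing: float
    counts: np.ndarray
    n_frames: int
    mode: str

    @property
    def occupancy(self) -> np.ndarray:
        return self.counts / self.n_frames

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.counts.shape

    def voxel_of(self, point: np.ndarray) -> tuple[int, int, int]:
        ijk = np.floor((np.asarray(point) - self.origin) / self.spacing).astype(int)
        return tuple(ijk)

    def to_voxel_table(self):
        """CSV-friendly dump of non-empty voxels (for tests and audit)."""
        import pandas as pd

        idx = np.argwhere(self.counts > 0)
        occ = self.occupancy
        return pd.DataFrame(
            {
                "i": idx[:, 0],
                "j": idx[:, 1],
                "k": idx[:, 2],
                "count": self.counts[idx[:, 0], idx[:, 1], idx[:, 2]],
                "occupancy": occ[idx[:, 0], idx[:, 1], idx[:, 2]],
            }
        )


def _snap_down(x: np.ndarray, spacing: float) -> np.ndarray:
    return np.floor(x / spacing) * spacing


def accumulate_density(
    traj: Trajectory,
    ligand: Selection,
    mode: str = "heavy-atoms",
    spacing: float = 1.0,
    aligned: bool = True,
) -> DensityGrid:
    """Accumulate the per-voxel fraction of frames visited by the ligand.

    The grid origin is snapped down to a multiple of ``spacing`` from the
    ligand bounding box, padded by one voxel on every side, so the grid is
    reproducible for a given alignment and spacing.
    """
    if mode not in ("centroid", "heavy-atoms"):
        raise ValueError("mode must be 'centroid' or 'heavy-atoms'")
    if spacing <= 0:
        raise ValueError("spacing must be positive (Å)")
    if not aligned:
        warnings.warn(
            "trajectory not flagged as aligned; occupancy density of a "
            "mobile frame is not meaningful", stacklevel=2,
        )
    by_id = {a.atom_id: a for a in traj.topology.atoms}
    heavy = tuple(i for i in ligand.atom_ids if by_id[i].is_heavy)
    if not heavy:
        raise ValueError("ligand selection has no heavy atoms")
    xyz = traj.coordinates[:, traj.topology.indices_of(heavy), :]
    if mode == "centroid":
        points = centroid(xyz)[:, None, :]  # (F, 1, 3)
    else:
        points = xyz  # (F, n_heavy, 3)

    flat = points.reshape(-1, 3)
    origin = _snap_down(flat.min(axis=0), spacing) - spacing
    upper = _snap_down(flat.max(axis=0), spacing) + 2 * spacing
    shape = np.ceil((upper - origin) / spacing).astype(int) + 1
    counts = np.zeros(tuple(shape), dtype=np.int64)

    for f in range(points.shape[0]):
        ijk = np.floor((points[f] - origin) / spacing).astype(int)
        # a voxel counts at most once per frame, even if several ligand
        # atoms fall inside it
        for voxel in {tuple(v) for v in ijk}:
            counts[voxel] += 1
    return DensityGrid(
        origin=origin, spacing=spacing, counts=counts,
        n_frames=points.shape[0], mode=mode,
    )


def threshold_voxels(grid: DensityGrid, level: float) -> set[tuple[int, int, int]]:
    """Voxels with occupancy fraction >= ``level``.

    Isolevel sets are nested: the set at 0.5 is a subset of the set at 0.3,
    which is a subset of the set at 0.1.
    """
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    occ = grid.occupancy
    return {tuple(v) for v in np.argwhere(occ >= level)}


def write_dx(grid: DensityGrid, path: str | Path) -> None:
    """Write the occupancy grid as an OpenDX scalar field.

    Standard "gridpositions" layout with z varying fastest, as consumed by
    PyMOL/VMD/Chimera.
    """
    nx, ny, nz = grid.shape
    occ = grid.occupancy
    # voxel-center positions
    ox, oy, oz = grid.origin + 0.5 * grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {ox:.6f} {oy:.6f} {oz:.6f}",
        f"delta {grid.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = occ.ravel(order="C")  # x slowest, z fastest
    for i in range(0, len(flat), 3):
        lines.append(" ".join(f"{v:.6e}" for v in flat[i:i + 3]))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    Path(path).write_text("\n".join(lines) + "\n")
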