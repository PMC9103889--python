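"""Occupancy maps and the preferable protein surface.

Per run: probe heavy atoms from every snapshot are binned into 1 Å voxels,
values outside a 5 Å shell around the protein are discarded, and the rest is
scaled to unit total (the PMAP).  Across runs: the per-voxel maximum of all
PMAPs (max-PMAP) compensates the under-sampling of deep pockets, and the
voxels where it reaches a threshold (0.2 by default) form the preferable
surface that gates environment extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .grid import (
    GeometryMismatchError,
    Grid3D,
    VoxelMask,
    bin_points,
    mask_within_distance,
    normalize_masked,
    threshold_voxels,
    voxelwise_max,
)
from .trajectory import Trajectory

__all__ = [
    "PMAP",
    "MaxPMAP",
    "PreferableSurface",
    "grid_geometry_for",
    "compute_pmap",
    "compute_max_pmap",
    "preferable_surface",
]

DEFAULT_SHELL_CUTOFF = 5.0
DEFAULT_SURFACE_THETA = 0.2
DEFAULT_GRID_MARGIN = 8.0


@dataclass
class PMAP:
    """Normalized probe-occupancy map of one run, restricted to the shell."""

    grid: Grid3D
    mask: VoxelMask
    run_id: str
    probe_resname: str
    n_binned: int = 0
    n_out_of_bounds: int = 0

    def masked_sum(self) -> float:
        return float(self.grid.values[self.mask.member].sum())


@dataclass
class MaxPMAP:
    grid: Grid3D
    mask: VoxelMask
    n_runs: int

    def masked_sum(self) -> float:
        return float(self.grid.values[self.mask.member].sum())


@dataclass
class PreferableSurface:
    """Voxels whose max-PMAP value reaches the threshold."""

    member: np.ndarray  # boolean, same shape as the parent grid
    theta: float
    origin: np.ndarray
    spacing: float

    @property
    def n_voxels(self) -> int:
        return int(self.member.sum())

    def voxel_indices(self) -> np.ndarray:
        return np.argwhere(self.member)

    def contains_points(self, points: np.ndarray) -> np.ndarray:
        """Per-point membership test under the grid's half-open convention."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        idx = np.floor((pts - self.origin) / self.spacing).astype(np.int64)
        ok = np.all((idx >= 0) & (idx < np.array(self.member.shape)), axis=1)
        result = np.zeros(len(pts), dtype=bool)
        if ok.any():
            inside = idx[ok]
            result[ok] = self.member[inside[:, 0], inside[:, 1], inside[:, 2]]
        return result


def grid_geometry_for(
    traj: Trajectory,
    *,
    spacing: float = 1.0,
    margin: float = DEFAULT_GRID_MARGIN,
    align_point: np.ndarray | None = None,
) -> Grid3D:
    """Grid covering the reference snapshot's protein bounding box plus margin.

    If ``align_point`` is given, the origin is shifted (< one spacing) so
    that the point falls at a voxel center — useful when a location of
    interest should not straddle voxel faces.
    """
    coords = traj.snapshots[0].protein_heavy_coords()
    if coords.size == 0:
        raise ValueError("reference snapshot has no protein heavy atoms")
    lo = coords.min(axis=0) - margin
    hi = coords.max(axis=0) + margin
    if align_point is not None:
        p = np.asarray(align_point, dtype=float)
        # snap: choose origin so (p - origin)/spacing is k + 0.5
        k = np.floor((p - 0.5 * spacing - lo) / spacing)
        lo = p - (k + 0.5) * spacing
    shape = np.ceil((hi - lo) / spacing).astype(int)
    shape = np.maximum(shape, 1)
    return Grid3D(lo, spacing, np.zeros(tuple(shape)))


def compute_pmap(
    traj: Trajectory,
    geometry: Grid3D,
    probe_resname: str = "PRB",
    *,
    surface_cutoff: float = DEFAULT_SHELL_CUTOFF,
    mask: VoxelMask | None = None,
) -> PMAP:
    """Compute one run's PMAP on the given grid geometry.

    The trajectory must already be fitted to the frame the geometry was
    built in.  The shell mask is derived from the reference (first)
    snapshot's protein heavy atoms unless an explicit mask is supplied
    (runs sharing a mask is what makes the cross-run maximum well defined).
    """
    if not traj.snapshots:
        raise ValueError("empty trajectory")
    if mask is None:
        mask = mask_within_distance(
            geometry, traj.snapshots[0].protein_heavy_coords(), surface_cutoff
        )
    counts = geometry.zeros_like()
    n_binned = 0
    n_oob = 0
    blocks = []
    for snap in traj.snapshots:
        coords = snap.probe_heavy_coords()
        if coords.size:
            blocks.append(coords)
    if blocks:
        all_points = np.vstack(blocks)
        counts, n_oob = bin_points(counts, all_points)
        n_binned = len(all_points) - n_oob
    normalized = normalize_masked(counts, mask)
    return PMAP(
        grid=normalized,
        mask=mask,
        run_id=traj.run_id,
        probe_resname=probe_resname,
        n_binned=n_binned,
        n_out_of_bounds=n_oob,
    )


def compute_max_pmap(pmaps: list[PMAP]) -> MaxPMAP:
    """Per-voxel maximum over PMAPs sharing one grid geometry and mask."""
    if not pmaps:
        raise ValueError("need at least one PMAP")
    first = pmaps[0]
    for p in pmaps[1:]:
        if not first.grid.same_geometry(p.grid):
            raise GeometryMismatchError("PMAPs do not share grid geometry")
        if not np.array_equal(first.mask.member, p.mask.member):
            raise GeometryMismatchError("PMAPs do not share the shell mask")
    grid = voxelwise_max([p.grid for p in pmaps])
    return MaxPMAP(grid=grid, mask=first.mask, n_runs=len(pmaps))


def preferable_surface(
    max_pmap: MaxPMAP, theta: float = DEFAULT_SURFACE_THETA
) -> PreferableSurface:
    """Inclusive thresholding of the max-PMAP; an empty surface only warns."""
    idx = threshold_voxels(max_pmap.grid, theta)
    member = np.zeros(max_pmap.grid.shape, dtype=bool)
    if len(idx):
        member[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    else:
        warnings.warn(
            f"preferable surface is empty at theta={theta} "
            f"(max value {max_pmap.grid.values.max():.4g})",
            stacklevel=2,
        )
    return PreferableSurface(
        member=member,
        theta=theta,
        origin=max_pmap.grid.origin.copy(),
        spacing=max_pmap.grid.spacing,
    )
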