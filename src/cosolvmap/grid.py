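"""Axis-aligned voxel lattices and the generic grid operations shared by all maps.

The :class:`Grid3D` lattice is the common currency of every density map in this
package: occupancy maps, their per-voxel maxima, and the per-residue-type
interaction profiles.  Voxels are cubic (1 Å by default) and own their volume
under a half-open convention: voxel ``(i, j, k)`` covers
``[origin + idx*spacing, origin + (idx+1)*spacing)``, so a point lying exactly
on a shared face belongs to the higher-index voxel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "Grid3D",
    "VoxelMask",
    "BinResult",
    "GridError",
    "GeometryMismatchError",
    "DegenerateNormalizationError",
    "DXParseError",
    "create_grid",
    "bin_points",
    "mask_within_distance",
    "normalize_masked",
    "voxelwise_max",
    "threshold_voxels",
    "write_dx",
    "read_dx",
]

#: Relative tolerance for the masked-sum-equals-one postcondition.
NORMALIZATION_RTOL = 1e-9

#: Absolute tolerance of the text round trip through OpenDX files.
DX_ATOL = 1e-6


class GridError(ValueError):
    """Base class for grid-related failures."""


class GeometryMismatchError(GridError):
    """Grids that were required to share origin/shape/spacing do not."""


class DegenerateNormalizationError(GridError):
    """Every masked voxel is zero; there is no mass to scale to 1.0."""


class DXParseError(GridError):
    """An OpenDX file violated the expected scalar regular-grid layout."""


@dataclass
class Grid3D:
    """A cubic-voxel scalar field.

    Parameters
    ----------
    origin:
        Cartesian coordinate (Å) of the minimum corner of voxel ``(0, 0, 0)``.
    spacing:
        Edge length of every voxel in Å; must be positive.
    values:
        Array of shape ``(nx, ny, nz)`` holding one finite real per voxel.
    """

    origin: np.ndarray
    spacing: float
    values: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.origin.shape != (3,):
            raise GridError(f"origin must be a 3-vector, got shape {self.origin.shape}")
        if not np.all(np.isfinite(self.origin)):
            raise GridError("origin must be finite")
        if not (np.isfinite(self.spacing) and self.spacing > 0):
            raise GridError(f"spacing must be positive and finite, got {self.spacing}")
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise GridError(f"values must be a 3-D array with positive shape, got {self.values.shape}")
        if not np.all(np.isfinite(self.values)):
            raise GridError("grid values must be finite (no NaN/Inf)")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_voxels(self) -> int:
        return int(self.values.size)

    def same_geometry(self, other: "Grid3D | VoxelMask", atol: float = 1e-9) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= atol
            and bool(np.all(np.abs(self.origin - other.origin) <= atol))
        )

    def point_to_index(self, points: np.ndarray) -> np.ndarray:
        """Map Cartesian points to integer voxel indices (floor convention).

        Indices may fall outside ``shape``; pair with :meth:`in_bounds`.
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return np.floor((pts - self.origin) / self.spacing).astype(np.int64)

    def in_bounds(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(indices)
        return np.all((idx >= 0) & (idx < np.array(self.shape)), axis=1)

    def voxel_centers(self) -> np.ndarray:
        """Return an ``(nx, ny, nz, 3)`` array of voxel-center coordinates."""
        axes = [
            self.origin[d] + (np.arange(self.shape[d]) + 0.5) * self.spacing
            for d in range(3)
        ]
        gx, gy, gz = np.meshgrid(*axes, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1)

    def index_to_center(self, indices: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return self.origin + (idx + 0.5) * self.spacing

    def copy(self) -> "Grid3D":
        return Grid3D(self.origin.copy(), self.spacing, self.values.copy())

    def zeros_like(self) -> "Grid3D":
        return Grid3D(self.origin.copy(), self.spacing, np.zeros(self.shape))


@dataclass
class VoxelMask:
    """Boolean membership over the voxels of a companion :class:`Grid3D`."""

    origin: np.ndarray
    spacing: float
    member: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.member = np.asarray(self.member, dtype=bool)
        if self.member.ndim != 3:
            raise GridError("mask must be 3-D")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.member.shape  # type: ignore[return-value]

    @property
    def n_members(self) -> int:
        return int(self.member.sum())

    @classmethod
    def for_grid(cls, grid: Grid3D, member: np.ndarray) -> "VoxelMask":
        member = np.asarray(member, dtype=bool)
        if member.shape != grid.shape:
            raise GeometryMismatchError(
                f"mask shape {member.shape} does not match grid shape {grid.shape}"
            )
        return cls(grid.origin.copy(), grid.spacing, member)


class BinResult(NamedTuple):
    """Outcome of :func:`bin_points`: counts plus the out-of-bounds tally."""

    grid: Grid3D
    n_out_of_bounds: int


def create_grid(origin: Sequence[float], shape: Sequence[int], spacing: float) -> Grid3D:
    """Create an all-zero grid with the stated geometry."""
    shape_t = tuple(int(s) for s in shape)
    if len(shape_t) != 3 or min(shape_t) < 1:
        raise GridError(f"shape must be 3 positive integers, got {shape}")
    if not (np.isfinite(spacing) and spacing > 0):
        raise GridError(f"spacing must be positive, got {spacing}")
    return Grid3D(np.asarray(origin, dtype=float), float(spacing), np.zeros(shape_t))


def bin_points(grid: Grid3D, points: np.ndarray) -> BinResult:
    """Add one count per point to the voxel owning it.

    Out-of-bounds points are tallied in the result rather than raising:
    probes legitimately wander beyond the analysis region.
    """
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return BinResult(grid.copy(), 0)
    pts = np.atleast_2d(pts)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise GridError(f"points must be an (N, 3) array, got shape {pts.shape}")
    if not np.all(np.isfinite(pts)):
        raise GridError("points must be finite")
    out = grid.copy()
    idx = grid.point_to_index(pts)
    ok = grid.in_bounds(idx)
    inside = idx[ok]
    np.add.at(out.values, (inside[:, 0], inside[:, 1], inside[:, 2]), 1.0)
    return BinResult(out, int((~ok).sum()))


def mask_within_distance(
    grid: Grid3D, reference_points: np.ndarray, cutoff: float
) -> VoxelMask:
    """Mark voxels whose center lies within ``cutoff`` Å of any reference point."""
    ref = np.atleast_2d(np.asarray(reference_points, dtype=float))
    if ref.size == 0:
        raise GridError("reference point set is empty; mask is undefined")
    if not (np.isfinite(cutoff) and cutoff > 0):
        raise GridError(f"cutoff must be positive, got {cutoff}")
    centers = grid.voxel_centers().reshape(-1, 3)
    tree = cKDTree(ref)
    dist, _ = tree.query(centers, k=1)
    member = (dist <= cutoff).reshape(grid.shape)
    return VoxelMask.for_grid(grid, member)


def normalize_masked(grid: Grid3D, mask: VoxelMask) -> Grid3D:
    """Discard values outside the mask and scale the rest to unit total."""
    if not grid.same_geometry(mask):
        raise GeometryMismatchError("mask geometry does not match grid")
    if np.any(grid.values < 0):
        raise GridError("normalization requires non-negative values")
    masked = np.where(mask.member, grid.values, 0.0)
    total = masked.sum()
    if total <= 0:
        raise DegenerateNormalizationError(
            "all masked voxels are zero; no occupancy to normalize"
        )
    return Grid3D(grid.origin.copy(), grid.spacing, masked / total)


def voxelwise_max(grids: Iterable[Grid3D]) -> Grid3D:
    """Per-voxel maximum over a collection of geometry-identical grids."""
    grids = list(grids)
    if not grids:
        raise GridError("voxelwise_max requires at least one grid")
    first = grids[0]
    for g in grids[1:]:
        if not first.same_geometry(g):
            raise GeometryMismatchError("all grids must share origin/shape/spacing")
    stacked = np.stack([g.values for g in grids])
    return Grid3D(first.origin.copy(), first.spacing, stacked.max(axis=0))


def threshold_voxels(grid: Grid3D, theta: float) -> np.ndarray:
    """Indices of voxels with value >= theta (inclusive), as an (n, 3) array."""
    if not np.isfinite(theta):
        raise GridError("theta must be finite")
    return np.argwhere(grid.values >= theta)


# ---------------------------------------------------------------------------
# OpenDX scalar-field I/O
# ---------------------------------------------------------------------------

def write_dx(grid: Grid3D, path: str | Path, *, sidecar: bool = True) -> None:
    """Write ``grid`` as an OpenDX scalar regular-grid file.

    A JSON sidecar (``<path>.json``) echoes the geometry at full precision,
    since the DX text format itself is limited by its ``%g`` style fields.
    """
    path = Path(path)
    nx, ny, nz = grid.shape
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        "origin {:.6f} {:.6f} {:.6f}".format(*grid.origin),
        f"delta {grid.spacing:.6f} 0.000000 0.000000",
        f"delta 0.000000 {grid.spacing:.6f} 0.000000",
        f"delta 0.000000 0.000000 {grid.spacing:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {grid.n_voxels} data follows",
    ]
    flat = grid.values.ravel(order="C")  # z fastest, per DX convention
    for start in range(0, flat.size, 3):
        chunk = flat[start : start + 3]
        lines.append(" ".join(f"{v:.6e}" for v in chunk))
    lines.append('attribute "dep" string "positions"')
    lines.append('object "density" class field')
    lines.append('component "positions" value 1')
    lines.append('component "connections" value 2')
    lines.append('component "data" value 3')
    path.write_text("\n".join(lines) + "\n")
    if sidecar:
        meta = {
            "origin": grid.origin.tolist(),
            "spacing": grid.spacing,
            "shape": list(grid.shape),
        }
        Path(str(path) + ".json").write_text(json.dumps(meta, indent=1) + "\n")


def read_dx(path: str | Path) -> Grid3D:
    """Read an OpenDX scalar regular-grid file written by :func:`write_dx`.

    Also accepts the equivalent output of other tools as long as the deltas
    are diagonal and isotropic.
    """
    path = Path(path)
    origin: np.ndarray | None = None
    shape: tuple[int, int, int] | None = None
    deltas: list[np.ndarray] = []
    n_items: int | None = None
    data: list[float] = []
    reading_data = False

    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if reading_data:
            if line.startswith(("attribute", "object", "component")):
                reading_data = False
            else:
                try:
                    data.extend(float(tok) for tok in line.split())
                except ValueError as exc:
                    raise DXParseError(f"{path}:{lineno}: bad data token ({exc})") from exc
                continue
        if line.startswith("object 1 class gridpositions"):
            toks = line.split()
            try:
                shape = (int(toks[-3]), int(toks[-2]), int(toks[-1]))
            except ValueError as exc:
                raise DXParseError(f"{path}:{lineno}: bad counts line") from exc
        elif line.startswith("origin"):
            origin = np.array([float(t) for t in line.split()[1:4]])
        elif line.startswith("delta"):
            deltas.append(np.array([float(t) for t in line.split()[1:4]]))
        elif "class array" in line and "data follows" in line:
            toks = line.split()
            try:
                n_items = int(toks[toks.index("items") + 1])
            except (ValueError, IndexError) as exc:
                raise DXParseError(f"{path}:{lineno}: bad items count") from exc
            reading_data = True

    if shape is None or origin is None or n_items is None:
        raise DXParseError(f"{path}: missing gridpositions/origin/array header")
    if len(deltas) != 3:
        raise DXParseError(f"{path}: expected 3 delta lines, found {len(deltas)}")
    delta = np.array(deltas)
    diag = np.diag(delta)
    if not np.allclose(delta, np.diag(diag)) or not np.allclose(diag, diag[0]):
        raise DXParseError(f"{path}: only isotropic diagonal deltas are supported")
    expected = shape[0] * shape[1] * shape[2]
    if n_items != expected or len(data) != expected:
        raise DXParseError(
            f"{path}: declared {n_items} items for shape {shape} "
            f"({expected} voxels) but parsed {len(data)} values"
        )
    values = np.array(data).reshape(shape, order="C")
    return Grid3D(origin, float(diag[0]), values)
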