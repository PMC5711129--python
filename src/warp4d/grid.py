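"""Grid-aligned volumes, masks and vector fields.

All data live on axis-aligned regular 3D grids. Arrays are indexed ``[i, j, k]``
with the fixed anatomical axis order ``x = LR (left-right), y = AP
(anterior-posterior), z = SI (superior-inferior)``. The world coordinate of
voxel ``(i, j, k)`` is ``origin + (i, j, k) * spacing`` (mm); grids are never
rotated or oblique.

Vector fields use the pull-back convention throughout: the displacement
``u(x)`` stored at a voxel of the *target* (reference) grid points to the
corresponding location in the *source* image, i.e. ``x_source = x + u(x)``.
A field in this convention can be consumed directly by resampling.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "Grid3D",
    "ScalarVolume",
    "VectorField",
    "StructureMask",
    "sample_trilinear",
    "mask_boolean",
    "expand_margin",
    "centroid",
    "build_targets",
    "resample_to_grid",
]


class GridMismatchError(ValueError):
    """Two objects that must share a grid do not."""


@dataclass(frozen=True)
class Grid3D:
    """Regular axis-aligned 3D grid.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels per axis (x, y, z); each >= 1.
    spacing : tuple of float
        Voxel size in mm per axis; each > 0.
    origin : tuple of float
        World coordinate (mm) of voxel index (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        spacing = tuple(float(s) for s in self.spacing)
        origin = tuple(float(o) for o in self.origin)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"shape must be 3 positive integers, got {shape}")
        if len(spacing) != 3 or any(s <= 0 for s in spacing):
            raise ValueError(f"non-positive spacing: {spacing}")
        if len(origin) != 3 or not all(np.isfinite(origin)):
            raise ValueError(f"origin must be 3 finite floats, got {origin}")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "spacing", spacing)
        object.__setattr__(self, "origin", origin)

    @property
    def voxel_volume_cc(self) -> float:
        """Volume of one voxel in cm^3 (spacing is mm)."""
        return float(np.prod(self.spacing)) / 1000.0

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Convert (N, 3) world mm coordinates to fractional voxel indices."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, indices: np.ndarray) -> np.ndarray:
        """Convert (N, 3) (possibly fractional) voxel indices to world mm."""
        idx = np.atleast_2d(np.asarray(indices, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def coordinate_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World-coordinate arrays (each of grid shape) for x, y, z in mm."""
        axes = [
            self.origin[a] + np.arange(self.shape[a]) * self.spacing[a]
            for a in range(3)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))

    def same_geometry(self, other: "Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol)
            and np.allclose(self.origin, other.origin, atol=tol)
        )


def _require_same_grid(a, b, what: str = "operands"):
    if not a.grid.same_geometry(b.grid):
        raise GridMismatchError(
            f"{what} are on different grids: "
            f"{a.grid.shape}/{a.grid.spacing} vs {b.grid.shape}/{b.grid.spacing}"
        )


@dataclass
class ScalarVolume:
    """One scalar per voxel (CT intensities in HU or dose in Gy)."""

    grid: Grid3D
    values: np.ndarray
    unit: str = "dimensionless"  # one of HU | Gy | dimensionless

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} != grid shape {self.grid.shape}"
            )

    def require_nonnegative(self, what: str = "dose"):
        """Dose distributions are physically non-negative; difference maps
        (also carried as ScalarVolume) are exempt."""
        if np.any(self.values < -1e-9):
            raise ValueError(f"{what} volume has negative values")
        return self

    def copy(self) -> "ScalarVolume":
        return ScalarVolume(self.grid, self.values.copy(), self.unit)


@dataclass
class VectorField:
    """Per-voxel 3D displacement in mm, pull-back convention."""

    grid: Grid3D
    displacements: np.ndarray  # shape grid.shape + (3,)

    def __post_init__(self):
        self.displacements = np.asarray(self.displacements, dtype=np.float64)
        if self.displacements.shape != self.grid.shape + (3,):
            raise ValueError(
                f"displacement shape {self.displacements.shape} != "
                f"{self.grid.shape + (3,)}"
            )
        if not np.all(np.isfinite(self.displacements)):
            raise ValueError("displacement field contains non-finite values")

    @classmethod
    def zero(cls, grid: Grid3D) -> "VectorField":
        return cls(grid, np.zeros(grid.shape + (3,)))

    def magnitude(self) -> np.ndarray:
        return np.sqrt(np.sum(self.displacements**2, axis=-1))


@dataclass
class StructureMask:
    """Named boolean region on a grid (GTV, ITV, PTV, liver, ...)."""

    grid: Grid3D
    member: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.member = np.asarray(self.member).astype(bool)
        if self.member.shape != self.grid.shape:
            raise ValueError(
                f"mask shape {self.member.shape} != grid shape {self.grid.shape}"
            )

    @property
    def voxel_count(self) -> int:
        return int(np.count_nonzero(self.member))

    @property
    def volume_cc(self) -> float:
        return self.voxel_count * self.grid.voxel_volume_cc

    def is_empty(self) -> bool:
        return self.voxel_count == 0


def sample_trilinear(
    vol: ScalarVolume,
    points: np.ndarray,
    out_of_grid: float | str = 0.0,
) -> np.ndarray:
    """Trilinear interpolation of a volume at world-coordinate points.

    Parameters
    ----------
    vol : ScalarVolume
    points : (N, 3) array of mm world coordinates.
    out_of_grid : float or "nearest"
        Value returned outside the grid extent. A float (default 0, the
        physical choice for dose), or ``"nearest"`` to clamp to the edge
        value (the choice for CT, avoiding spurious air values).
    """
    pts = np.asarray(points, dtype=float)
    squeeze = pts.ndim == 1
    idx = vol.grid.world_to_index(pts)
    if not np.all(np.isfinite(idx)):
        raise ValueError("sample points must be finite")
    if out_of_grid == "nearest":
        out = ndimage.map_coordinates(
            vol.values, idx.T, order=1, mode="nearest"
        )
    else:
        out = ndimage.map_coordinates(
            vol.values, idx.T, order=1, mode="constant", cval=float(out_of_grid)
        )
    return out[0] if squeeze else out


def mask_boolean(a: StructureMask, b: StructureMask, op: str) -> StructureMask:
    """Voxel-wise boolean combination of two masks on the same grid.

    ``op`` is one of ``union``, ``intersection``, ``difference`` (a minus b),
    e.g. normal liver = difference(liver, target).
    """
    _require_same_grid(a, b, "masks")
    if op == "union":
        values, name = a.member | b.member, f"{a.name}|{b.name}"
    elif op == "intersection":
        values, name = a.member & b.member, f"{a.name}&{b.name}"
    elif op == "difference":
        values, name = a.member & ~b.member, f"{a.name}-{b.name}"
    else:
        raise ValueError(f"unknown boolean op {op!r}")
    return StructureMask(a.grid, values, name)


def expand_margin(mask: StructureMask, margin_mm: float) -> StructureMask:
    """Isotropic morphological dilation by a Euclidean margin in mm.

    A voxel belongs to the output iff its center lies within ``margin_mm``
    of some member voxel center of the input. Used for PTV = ITV + margin.
    """
    if margin_mm < 0:
        raise ValueError(f"margin must be non-negative, got {margin_mm}")
    if margin_mm == 0 or mask.is_empty():
        return StructureMask(mask.grid, mask.member.copy(), mask.name)
    dist = ndimage.distance_transform_edt(
        ~mask.member, sampling=mask.grid.spacing
    )
    return StructureMask(
        mask.grid, dist <= margin_mm + 1e-9, f"{mask.name}+{margin_mm:g}mm"
    )


def centroid(mask: StructureMask) -> np.ndarray:
    """Unweighted mean world coordinate (mm) of member voxel centers."""
    if mask.is_empty():
        raise ValueError(f"centroid of empty mask {mask.name!r}")
    idx = np.argwhere(mask.member)
    return mask.grid.index_to_world(idx).mean(axis=0)


def build_targets(
    gtv_exhale: StructureMask,
    gtv_inhale: StructureMask,
    margin_mm: float = 5.0,
    itv_mode: str = "union",
) -> dict[str, StructureMask]:
    """Construct ITV and PTV from the extreme-phase GTVs.

    The ITV combines the end-expiration and end-inspiration GTVs (default:
    union, i.e. the motion envelope; ``itv_mode="intersection"`` is also
    accepted). The PTV adds an isotropic setup margin (default 5 mm).
    """
    _require_same_grid(gtv_exhale, gtv_inhale, "extreme-phase GTVs")
    if itv_mode not in ("union", "intersection"):
        raise ValueError(f"itv_mode must be union or intersection, got {itv_mode!r}")
    itv = mask_boolean(gtv_exhale, gtv_inhale, itv_mode)
    itv.name = "ITV"
    ptv = expand_margin(itv, margin_mm)
    ptv.name = "PTV"
    return {"ITV": itv, "PTV": ptv}


def resample_to_grid(
    vol: ScalarVolume, grid: Grid3D, out_of_grid: float | str = 0.0
) -> ScalarVolume:
    """Trilinearly resample a volume onto another grid (world-aligned)."""
    if vol.grid.same_geometry(grid):
        return vol.copy()
    xs, ys, zs = grid.coordinate_arrays()
    pts = np.stack([xs.ravel(), ys.ravel(), zs.ravel()], axis=1)
    vals = sample_trilinear(vol, pts, out_of_grid=out_of_grid)
    return ScalarVolume(grid, vals.reshape(grid.shape), vol.unit)
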