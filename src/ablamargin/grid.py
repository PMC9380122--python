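"""Voxel-grid geometry and in-memory image/mask containers.

All geometry lives in world millimetres.  A :class:`Grid` is an axis-aligned
voxel lattice: array index ``(i, j, k)`` maps to the world point
``origin + index * spacing`` (the voxel *center*).  Axis directions are the
identity; oblique acquisitions are expected to be resampled upstream.  A voxel
belongs to a structure iff its center is inside (half-open convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Grid", "ImageVolume", "LabelMask", "GeometryError"]


class GeometryError(ValueError):
    """Raised when paired volumes/masks disagree on grid geometry."""


@dataclass(frozen=True)
class Grid:
    """Axis-aligned voxel lattice in world mm.

    Parameters
    ----------
    shape : tuple of int
        Number of voxels along (x, y, z).
    spacing : tuple of float
        Voxel size in mm along each axis (anisotropy supported).
    origin : tuple of float
        World coordinate (mm) of the center of voxel (0, 0, 0).
    """

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if len(self.shape) != 3 or any(n <= 0 for n in self.shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))
        object.__setattr__(self, "origin", tuple(float(o) for o in self.origin))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def voxel_to_world(self, idx: np.ndarray) -> np.ndarray:
        """Map fractional voxel indices (..., 3) to world mm."""
        idx = np.asarray(idx, dtype=float)
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        """Map world mm points (..., 3) to fractional voxel indices."""
        xyz = np.asarray(xyz, dtype=float)
        return (xyz - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a])
            for a in range(3)
        )

    def coordinate_grid(self) -> np.ndarray:
        """Dense (nx, ny, nz, 3) array of voxel-center world coordinates."""
        ax = self.axes()
        return np.stack(np.meshgrid(*ax, indexing="ij"), axis=-1)

    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world affine (diagonal, for NIfTI export)."""
        A = np.eye(4)
        A[:3, :3] = np.diag(self.spacing)
        A[:3, 3] = self.origin
        return A

    def isclose(self, other: "Grid", tol_mm: float = 1e-3) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing, atol=tol_mm)
            and np.allclose(self.origin, other.origin, atol=tol_mm)
        )


def _check_data(data: np.ndarray, grid: Grid) -> None:
    if tuple(data.shape) != grid.shape:
        raise GeometryError(
            f"data shape {data.shape} does not match grid shape {grid.shape}"
        )


@dataclass
class ImageVolume:
    """Scalar voxel image on a :class:`Grid` (intensities in arbitrary units)."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        _check_data(self.data, self.grid)


@dataclass
class LabelMask:
    """Binary voxel mask on a :class:`Grid`."""

    data: np.ndarray
    grid: Grid

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        _check_data(self.data, self.grid)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_cc(self) -> float:
        """Mask volume in cm^3."""
        return self.n_voxels * self.grid.voxel_volume_mm3 / 1000.0

    def centroid_mm(self) -> np.ndarray:
        """Unweighted mean of member-voxel center world coordinates."""
        if not self.data.any():
            raise ValueError("centroid of an empty mask is undefined")
        idx = np.argwhere(self.data)
        return self.grid.voxel_to_world(idx).mean(axis=0)


def require_same_grid(*items, tol_mm: float = 1e-3) -> Grid:
    """Assert all items share one grid geometry; return it."""
    grids = [it.grid for it in items]
    g0 = grids[0]
    for g in grids[1:]:
        if not g0.isclose(g, tol_mm):
            raise GeometryError(f"grid mismatch: {g0} vs {g}")
    return g0


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice similarity coefficient 2|A∩B| / (|A|+|B|) of two binary arrays."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)
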