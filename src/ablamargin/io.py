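"""NIfTI readers/writers and geometry checking.

Volumes, masks and displacement fields round-trip through NIfTI-1 with a
diagonal affine (axis-aligned grids; spacing and origin in mm).  Oblique
acquisitions must be resampled upstream — a non-diagonal affine is rejected
rather than silently reinterpreted.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np

from .grid import GeometryError, Grid, ImageVolume, LabelMask
from .transforms import DisplacementField

__all__ = [
    "read_volume",
    "read_mask",
    "write_volume",
    "read_dvf",
    "write_dvf",
    "check_paired_geometry",
]


def _grid_from_affine(affine: np.ndarray, shape: tuple[int, ...]) -> Grid:
    A = np.asarray(affine, dtype=float)
    off = A[:3, :3] - np.diag(np.diag(A[:3, :3]))
    if np.abs(off).max() > 1e-6:
        raise GeometryError(
            "non-diagonal NIfTI affine (oblique or flipped axes); resample first"
        )
    spacing = np.diag(A[:3, :3])
    if np.any(spacing <= 0):
        raise GeometryError(f"non-positive spacing in affine: {spacing}")
    return Grid(tuple(shape[:3]), tuple(spacing), tuple(A[:3, 3]))


def read_volume(path: str | Path) -> ImageVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D scalar volume, got shape {data.shape}")
    return ImageVolume(data, _grid_from_affine(img.affine, data.shape))


def read_mask(path: str | Path) -> LabelMask:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"expected a 3D mask, got shape {data.shape}")
    return LabelMask(data > 0.5, _grid_from_affine(img.affine, data.shape))


def write_volume(path: str | Path, vol: ImageVolume | LabelMask) -> None:
    data = vol.data.astype(np.uint8) if isinstance(vol, LabelMask) else vol.data
    nib.save(nib.Nifti1Image(data, vol.grid.affine()), str(path))


def write_dvf(path: str | Path, dvf: DisplacementField) -> None:
    nib.save(
        nib.Nifti1Image(dvf.data.astype(np.float32), dvf.grid.affine()), str(path)
    )


def read_dvf(path: str | Path, direction: str = "pre->post") -> DisplacementField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 3:
        raise GeometryError(f"expected a 3-component vector volume, got {data.shape}")
    return DisplacementField(data, _grid_from_affine(img.affine, data.shape), direction)


def check_paired_geometry(
    volume: ImageVolume, mask: LabelMask, tol_mm: float = 1e-3
) -> None:
    """Raise :class:`GeometryError` if a volume and its mask disagree."""
    if not volume.grid.isclose(mask.grid, tol_mm):
        raise GeometryError(
            f"volume grid {volume.grid} and mask grid {mask.grid} differ by more "
            f"than {tol_mm} mm"
        )
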