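"""3D minimum delivered ablation margin (distance to agreement).

The delivered margin at a point of the mapped tumor surface is its Euclidean
distance to the ablation-zone boundary when the ablation encompasses it, and
0 mm where tumor and ablation boundary overlap or the tumor pokes outside —
the margin has a closed lower limit of 0.  To avoid penalizing subcapsular
tumors, where no margin can exist beyond the liver capsule, the ablation
zone is first expanded (default 10 mm) everywhere *outside* the liver, so
the reported minimum is the minimum margin within the liver.

Distances use an exact Euclidean distance transform in physical spacing
(anisotropy respected); surfaces are boundary voxels under 6-connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grid import LabelMask, require_same_grid

__all__ = [
    "MarginParams",
    "MarginResult",
    "expand_outside_liver",
    "min_margin",
    "gtv_outside_ablation",
    "uncovered_margin_region",
    "surface_voxels",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class MarginParams:
    """extrahepatic_expansion: mm added to the ablation outside the liver;
    intended_margin: mm, the prescribed minimum margin (default 5)."""

    extrahepatic_expansion: float = 10.0
    intended_margin: float = 5.0

    def __post_init__(self) -> None:
        if self.extrahepatic_expansion < 0 or self.intended_margin < 0:
            raise ValueError("margin parameters must be non-negative")


@dataclass
class MarginResult:
    """min_margin_mm : minimum delivered margin over the tumor surface.
    margin_samples_mm : per-surface-voxel margins (0 where uncovered).
    pct_gtv_outside / cc_gtv_outside : mapped tumor volume outside ablation.
    uncovered_region : (GTV ⊕ intended margin) \\ ablation, within the liver.
    adjusted_ablation : ablation after extrahepatic expansion (for review).
    """

    min_margin_mm: float
    margin_samples_mm: np.ndarray
    pct_gtv_outside: float
    cc_gtv_outside: float
    uncovered_region: LabelMask
    adjusted_ablation: LabelMask


def surface_voxels(mask: np.ndarray) -> np.ndarray:
    """Boundary voxels of a binary mask under 6-connectivity."""
    return mask & ~ndimage.binary_erosion(mask, structure=_FACE_STRUCT)


def _dilate_mm(mask: np.ndarray, spacing, radius_mm: float) -> np.ndarray:
    """Morphological dilation by a Euclidean ball of radius_mm (exact EDT)."""
    if radius_mm == 0 or not mask.any():
        return mask.copy()
    d = ndimage.distance_transform_edt(~mask, sampling=spacing)
    return d <= radius_mm


def expand_outside_liver(
    ablation_mask: LabelMask, liver_mask: LabelMask, expansion_mm: float = 10.0
) -> LabelMask:
    """Ablation zone grown by ``expansion_mm`` strictly outside the liver.

    adjusted = ablation ∪ (dilate(ablation, expansion) ∩ ¬liver); no voxel
    inside the liver is ever added.
    """
    if expansion_mm < 0:
        raise ValueError("expansion must be non-negative")
    grid = require_same_grid(ablation_mask, liver_mask)
    dil = _dilate_mm(ablation_mask.data, grid.spacing, expansion_mm)
    adjusted = ablation_mask.data | (dil & ~liver_mask.data)
    return LabelMask(adjusted, grid)


def gtv_outside_ablation(
    gtv_mapped_mask: LabelMask, ablation_mask: LabelMask
) -> tuple[float, float]:
    """(% of mapped GTV volume outside the ablation zone, the same in cm³)."""
    grid = require_same_grid(gtv_mapped_mask, ablation_mask)
    n_gtv = gtv_mapped_mask.n_voxels
    if n_gtv == 0:
        raise ValueError("empty GTV mask")
    outside = gtv_mapped_mask.data & ~ablation_mask.data
    n_out = int(outside.sum())
    pct = 100.0 * n_out / n_gtv
    cc = n_out * grid.voxel_volume_mm3 / 1000.0
    return float(pct), float(cc)


def uncovered_margin_region(
    gtv_mapped_mask: LabelMask,
    ablation_mask: LabelMask,
    liver_mask: LabelMask,
    intended_margin_mm: float = 5.0,
) -> LabelMask:
    """Tissue that the intended margin required but the ablation missed:
    (GTV dilated by the intended margin) minus the ablation, inside the liver.
    This is the target set the recurrence cone is tested against."""
    grid = require_same_grid(gtv_mapped_mask, ablation_mask, liver_mask)
    dil = _dilate_mm(gtv_mapped_mask.data, grid.spacing, intended_margin_mm)
    return LabelMask(dil & ~ablation_mask.data & liver_mask.data, grid)


def min_margin(
    gtv_mapped_mask: LabelMask,
    ablation_mask: LabelMask,
    liver_mask: LabelMask,
    params: MarginParams = MarginParams(),
) -> MarginResult:
    """Minimum 3D distance to agreement between mapped GTV and ablation zone.

    For every GTV surface voxel: margin = distance to the nearest
    adjusted-ablation surface voxel if the ablation (after extrahepatic
    expansion) encompasses it, else 0.  ``min_margin_mm`` is the minimum over
    the surface; it is 0 iff some GTV voxel lies outside the adjusted
    ablation or on its boundary.
    """
    grid = require_same_grid(gtv_mapped_mask, ablation_mask, liver_mask)
    if not gtv_mapped_mask.data.any():
        raise ValueError("empty GTV mask")

    adjusted = expand_outside_liver(ablation_mask, liver_mask, params.extrahepatic_expansion)
    gtv_surf = surface_voxels(gtv_mapped_mask.data)
    adj_surf = surface_voxels(adjusted.data)

    if adj_surf.any():
        dist_to_surf = ndimage.distance_transform_edt(~adj_surf, sampling=grid.spacing)
    else:  # no ablation at all: every margin is 0
        dist_to_surf = np.zeros(grid.shape)

    covered = adjusted.data & ~adj_surf  # strictly interior to the adjusted zone
    samples = np.where(covered[gtv_surf], dist_to_surf[gtv_surf], 0.0)
    # a GTV strictly inside with no surface voxels can't happen (erosion of a
    # nonempty mask always leaves a boundary), so samples is nonempty
    min_m = float(samples.min()) if ablation_mask.data.any() else 0.0

    pct, cc = gtv_outside_ablation(gtv_mapped_mask, adjusted)
    uncovered = uncovered_margin_region(
        gtv_mapped_mask, ablation_mask, liver_mask, params.intended_margin
    )
    return MarginResult(
        min_margin_mm=min_m,
        margin_samples_mm=samples,
        pct_gtv_outside=round(pct, 2),
        cc_gtv_outside=round(cc, 2),
        uncovered_region=uncovered,
        adjusted_ablation=adjusted,
    )
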