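"""Cone tracing: does the recurrence point at the under-ablated region?

The recurrence, contoured on follow-up imaging, is expressed as the set of
directions (spherical coordinates) from the centroid of the recovered
ablation zone to every recurrence voxel — the union of per-voxel rays, an
arbitrary solid-angle set rather than a single fitted circular cone, so the
"cone" intersects every contoured recurrence point.  That direction set is
then carried to the post-treatment frame (directions rotate with the rigid
post->follow-up registration; translation cannot affect a direction) and
re-anchored at the post-treatment ablation centroid.  If any voxel of the
uncovered intended-margin region lies in an occupied direction bin, the
recurrence colocates with the region where the intended margin was missed.

Directions are binned on an equiangular (theta, phi) grid: polar theta in
[0°, 180°] from the world +z (superior) axis, azimuth phi in [-180°, 180°)
from +x in the axial plane, default bin width 2° (a 5 mm feature at 10 cm
subtends more than one bin).  Bin edges use the floor convention; at the
poles all phi bins are merged.  An optional angular dilation widens the set
isotropically on the bin grid, wrapping in phi.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .grid import LabelMask
from .transforms import RigidTransform

__all__ = ["DirectionSet", "ConeResult", "mask_centroid", "build_direction_set", "cone_overlap"]


def mask_centroid(mask: LabelMask) -> np.ndarray:
    """Unweighted mean of member-voxel center world coordinates (mm)."""
    return mask.centroid_mm()


@dataclass
class DirectionSet:
    """Binary occupancy over an equiangular (theta, phi) direction grid."""

    bins: np.ndarray  # (n_theta, n_phi) bool
    bin_deg: float
    angular_dilation_deg: float = 0.0
    n_skipped: int = 0  # voxels coincident with the centroid (no direction)

    @property
    def n_occupied(self) -> int:
        return int(self.bins.sum())

    def _indices(self, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        d = np.atleast_2d(directions)
        r = np.linalg.norm(d, axis=1)
        with np.errstate(invalid="ignore"):
            theta = np.degrees(np.arccos(np.clip(d[:, 2] / np.where(r > 0, r, 1), -1, 1)))
        phi = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        n_theta, n_phi = self.bins.shape
        it = np.minimum((theta // self.bin_deg).astype(int), n_theta - 1)
        ip = ((phi + 180.0) // self.bin_deg).astype(int) % n_phi
        return it, ip

    def contains(self, directions: np.ndarray) -> np.ndarray:
        """Membership of direction vectors (need not be unit length)."""
        it, ip = self._indices(directions)
        return self.bins[it, ip]

    def solid_angle_sr(self) -> float:
        """Total solid angle of the occupied bins (steradians)."""
        n_theta, n_phi = self.bins.shape
        edges = np.radians(np.arange(n_theta + 1) * self.bin_deg)
        band = (np.cos(edges[:-1]) - np.cos(edges[1:])) * np.radians(self.bin_deg)
        return float((self.bins * band[:, None]).sum())


@dataclass
class ConeResult:
    overlap: bool
    overlap_volume_cc: float
    overlap_mask: LabelMask


def build_direction_set(
    centroid_mm: np.ndarray,
    recurrence_mask: LabelMask,
    bin_deg: float = 2.0,
    dilation_deg: float = 0.0,
) -> DirectionSet:
    """Direction set from a centroid to every voxel of the recurrence.

    Recurrence voxels whose center coincides with the centroid have no
    defined direction; they are skipped and counted in ``n_skipped``.
    """
    if not recurrence_mask.data.any():
        raise ValueError("empty recurrence mask")
    if bin_deg <= 0 or 180.0 % bin_deg > 1e-9:
        raise ValueError("bin_deg must be positive and divide 180")
    n_theta = int(round(180.0 / bin_deg))
    n_phi = 2 * n_theta
    ds = DirectionSet(np.zeros((n_theta, n_phi), dtype=bool), bin_deg, dilation_deg)

    pts = recurrence_mask.grid.voxel_to_world(np.argwhere(recurrence_mask.data))
    d = pts - np.asarray(centroid_mm, dtype=float)
    r = np.linalg.norm(d, axis=1)
    ok = r > 1e-9
    ds.n_skipped = int((~ok).sum())
    it, ip = ds._indices(d[ok])
    ds.bins[it, ip] = True

    if dilation_deg > 0:
        w = int(np.ceil(dilation_deg / bin_deg))
        padded = np.pad(ds.bins, ((0, 0), (w, w)), mode="wrap")
        padded = ndimage.binary_dilation(padded, iterations=w)
        ds.bins = padded[:, w:-w]
    # pole merging: a hit at theta = 0 or 180 has no azimuth
    if ds.bins[0].any():
        ds.bins[0] = True
    if ds.bins[-1].any():
        ds.bins[-1] = True
    return ds


def cone_overlap(
    direction_set: DirectionSet,
    post_ablation_centroid_mm: np.ndarray,
    uncovered_region_mask: LabelMask,
    rigid_post_to_recur: RigidTransform | None = None,
) -> ConeResult:
    """Overlap of the mapped recurrence cone with the uncovered-margin region.

    ``direction_set`` lives in the follow-up frame; the uncovered region and
    centroid live in the post-treatment frame.  Each uncovered voxel's
    direction from the post-treatment ablation centroid is rotated into the
    follow-up frame by the rigid registration's rotation and tested against
    the occupied bins.  An empty uncovered region yields no overlap (0 cc),
    which is a valid outcome, not an error.
    """
    grid = uncovered_region_mask.grid
    if not uncovered_region_mask.data.any():
        return ConeResult(False, 0.0, LabelMask(np.zeros(grid.shape, bool), grid))
    idx = np.argwhere(uncovered_region_mask.data)
    d = grid.voxel_to_world(idx) - np.asarray(post_ablation_centroid_mm, dtype=float)
    if rigid_post_to_recur is not None:
        d = d @ rigid_post_to_recur.rotation.T
    hit = direction_set.contains(d)
    mask = np.zeros(grid.shape, dtype=bool)
    mask[tuple(idx[hit].T)] = True
    vol_cc = int(hit.sum()) * grid.voxel_volume_mm3 / 1000.0
    return ConeResult(bool(hit.any()), float(vol_cc), LabelMask(mask, grid))
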