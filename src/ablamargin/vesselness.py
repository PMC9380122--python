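"""Hepatic vessel segmentation and vessel-focused rigid registration.

Vessels are segmented with a multiscale Hessian tubularity (Frangi) filter
inside the liver mask; the response is taken as the maximum over scales,
thresholded relative to its own maximum (so the result is invariant to the
absolute intensity scale), and cleaned of small components.

Between the post-ablation scan and the later follow-up scan, registration is
rigid and driven solely by the segmented vasculature within a sphere of
interest centered on each ablation zone (default radius 75 mm, selectable
among 50/75/100 mm) — the ablation cavity itself shrinks between the two
time points and would mislead an intensity match.  When too few vessel
voxels are found inside the spheres the operation refuses to run and raises
:class:`InsufficientVasculatureError`; the clinical fallback is a manually
supplied transform, which downstream code accepts in its place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import frangi

from .grid import ImageVolume, LabelMask, require_same_grid
from .registration import rigid_register
from .transforms import RigidTransform

__all__ = [
    "VesselnessParams",
    "FocusedRegParams",
    "InsufficientVasculatureError",
    "segment_vessels",
    "focused_vessel_registration",
]


class InsufficientVasculatureError(RuntimeError):
    """Too few vessel voxels within the spheres of interest.

    Carries the counts found on both sides; the caller is expected to fall
    back to an externally supplied (manual) rigid transform.
    """

    def __init__(self, count_post: int, count_recur: int, required: int) -> None:
        super().__init__(
            f"insufficient vasculature for focused registration: "
            f"{count_post} (post) / {count_recur} (follow-up) voxels inside the "
            f"spheres of interest, {required} required — supply a manual transform"
        )
        self.count_post = count_post
        self.count_recur = count_recur
        self.required = required


@dataclass(frozen=True)
class VesselnessParams:
    """scales: tube radii probed (mm, ascending); response_threshold: fraction
    of the maximum in-liver response kept; min_component_voxels: size filter."""

    scales: tuple[float, ...] = (1.0, 2.0, 3.0)
    response_threshold: float = 0.25
    min_component_voxels: int = 50

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.scales) or list(self.scales) != sorted(self.scales):
            raise ValueError("scales must be positive and ascending")
        if not (0.0 < self.response_threshold < 1.0):
            raise ValueError("response_threshold must be in (0, 1)")


@dataclass(frozen=True)
class FocusedRegParams:
    """sphere_radius: mm (50 / 75 / 100 investigated; default 75);
    min_vessel_voxels: refusal threshold for the manual-fallback path."""

    sphere_radius: float = 75.0
    min_vessel_voxels: int = 200

    def __post_init__(self) -> None:
        if self.sphere_radius <= 0:
            raise ValueError("sphere_radius must be positive")


def segment_vessels(
    volume: ImageVolume,
    liver_mask: LabelMask,
    params: VesselnessParams = VesselnessParams(),
) -> LabelMask:
    """Multiscale Frangi tubularity segmentation inside the liver.

    Bright-on-dark polarity, alpha = beta = 0.5, gamma set per scale to half
    the maximum Hessian Frobenius norm (the filter's intensity-adaptive
    default).  Voxels outside the (slightly eroded) liver are excluded so the
    capsule edge does not respond.
    """
    require_same_grid(volume, liver_mask)
    if not liver_mask.data.any():
        raise ValueError("empty liver mask")
    spacing = np.asarray(volume.grid.spacing)
    mean_sp = float(spacing.mean())

    # flatten non-liver tissue to the liver median so the boundary is quiet
    data = volume.data.astype(np.float32).copy()
    fill = float(np.median(data[liver_mask.data]))
    data[~liver_mask.data] = fill

    sigmas = [s / mean_sp for s in params.scales]
    response = frangi(data, sigmas=sigmas, alpha=0.5, beta=0.5, gamma=None,
                      black_ridges=False)

    interior = ndimage.binary_erosion(liver_mask.data, iterations=2)
    response[~interior] = 0.0
    peak = float(response.max())
    if peak <= 0:
        return LabelMask(np.zeros(volume.grid.shape, dtype=bool), volume.grid)
    mask = response >= params.response_threshold * peak

    lab, n = ndimage.label(mask)
    if n:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        keep = counts >= params.min_component_voxels
        mask = keep[lab]
    return LabelMask(mask, volume.grid)


def _sphere_crop(mask: LabelMask, center_mm: np.ndarray, radius_mm: float) -> np.ndarray:
    pts = mask.grid.coordinate_grid()
    d2 = ((pts - center_mm) ** 2).sum(axis=-1)
    return mask.data & (d2 <= radius_mm**2)


def focused_vessel_registration(
    post_vessels: LabelMask,
    recur_vessels: LabelMask,
    post_ablation_mask: LabelMask,
    recur_ablation_mask: LabelMask,
    params: FocusedRegParams = FocusedRegParams(),
    smoothing_mm: float = 1.5,
) -> RigidTransform:
    """Rigid transform mapping post-frame points to follow-up-frame points.

    Crops both vessel masks to spheres of interest centered on the two
    ablation-zone centroids, Gaussian-smooths the cropped masks into
    continuous vessel-likelihood images, and maximizes their masked
    cross-correlation over a rigid transform (deterministic coarse search +
    Powell refinement, as in :func:`ablamargin.registration.rigid_register`).
    """
    require_same_grid(post_vessels, post_ablation_mask)
    require_same_grid(recur_vessels, recur_ablation_mask)
    c_post = post_ablation_mask.centroid_mm()
    c_recur = recur_ablation_mask.centroid_mm()
    v_post = _sphere_crop(post_vessels, c_post, params.sphere_radius)
    v_recur = _sphere_crop(recur_vessels, c_recur, params.sphere_radius)
    n_post, n_recur = int(v_post.sum()), int(v_recur.sum())
    if min(n_post, n_recur) < params.min_vessel_voxels:
        raise InsufficientVasculatureError(n_post, n_recur, params.min_vessel_voxels)

    sp_post = np.asarray(post_vessels.grid.spacing)
    sp_recur = np.asarray(recur_vessels.grid.spacing)
    img_post = ImageVolume(
        ndimage.gaussian_filter(v_post.astype(np.float32), smoothing_mm / sp_post) * 100,
        post_vessels.grid,
    )
    img_recur = ImageVolume(
        ndimage.gaussian_filter(v_recur.astype(np.float32), smoothing_mm / sp_recur) * 100,
        recur_vessels.grid,
    )
    roi_post = LabelMask(
        ndimage.binary_dilation(v_post, iterations=3), post_vessels.grid
    )
    roi_recur = LabelMask(
        ndimage.binary_dilation(v_recur, iterations=3), recur_vessels.grid
    )
    # resampling convention: recur(T(x)) ~ post(x), so T maps post->follow-up
    return rigid_register(
        img_post, img_recur, roi_post, roi_recur,
        coarse_range_mm=9.0, coarse_step_mm=1.5, max_rotation_deg=10.0,
    )
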