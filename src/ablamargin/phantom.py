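"""Synthetic liver ablation phantoms with known ground truth.

Generates the three imaging time points of a thermal-ablation episode —
pre-treatment (liver + tumor + vessels), immediately post-ablation (liver +
ablation cavity + vessels, nonrigidly deformed w.r.t. pre), and a later
follow-up at recurrence diagnosis (the post frame under a rigid offset, with
the ablation cavity shrunken and a recurrence nodule added) — on a common
voxel grid, together with the exact deformations that relate them.

Geometry is analytic (superellipsoid liver, spherical tumor/ablation/
recurrence, capsule-shaped vessels), so every mask can be re-rasterized
through any transform without accumulation of resampling error.  Intensities
are piecewise-constant tissue classes plus Gaussian noise: enough contrast
for cross-correlation registration and Hessian vesselness filters without
modelling CT physics.  The nonrigid pre->post warp is drawn from the
biomechanical model family itself — a smooth control-point field supplies a
normal-direction boundary displacement that a linear-elastic solve extends
through the organ (see :class:`WarpSpec`) — is verified diffeomorphic, and
its dense voxel-center values are the ground truth a registration must
recover.  The follow-up ablation cavity defaults to
63% of its post-treatment volume, matching the average 37% cavity shrinkage
observed between post-treatment and recurrence imaging.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .grid import Grid, ImageVolume, LabelMask
from .transforms import DisplacementField, RigidTransform

__all__ = [
    "Superellipsoid",
    "Sphere",
    "Tube",
    "WarpSpec",
    "RigidOffsetSpec",
    "PhantomSpec",
    "PhantomCase",
    "PhantomSpecError",
    "scaled_spec",
    "generate_phantom",
    "simulate_ablation_shrinkage",
]

# piecewise-constant tissue intensities (HU-like, arbitrary units)
INTENSITY = {
    "background": -1000.0,
    "liver": 100.0,
    "vessel": 200.0,
    "ablation": 40.0,
    "tumor": 60.0,
}


class PhantomSpecError(ValueError):
    """Invalid phantom specification (geometry or warp constraint violated)."""


# ---------------------------------------------------------------------------
# analytic shapes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Superellipsoid:
    """|x/a|^p + |y/b|^p + |z/c|^p <= 1 about ``center`` (world mm)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    exponent: float = 2.5

    def contains(self, pts: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        d = np.abs(np.atleast_2d(pts) - np.asarray(self.center))
        ax = np.asarray(self.semi_axes) - margin_mm
        return (d / ax) ** self.exponent @ np.ones(3) <= 1.0


@dataclass(frozen=True)
class Sphere:
    center: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        d = np.linalg.norm(np.atleast_2d(pts) - np.asarray(self.center), axis=-1)
        return d <= self.radius - margin_mm

    def surface_points(self, n: int = 200) -> np.ndarray:
        """Fibonacci-sphere sample of the surface (for containment checks)."""
        i = np.arange(n) + 0.5
        phi = np.arccos(1 - 2 * i / n)
        theta = np.pi * (1 + 5**0.5) * i
        u = np.stack(
            [np.cos(theta) * np.sin(phi), np.sin(theta) * np.sin(phi), np.cos(phi)],
            axis=1,
        )
        return np.asarray(self.center) + self.radius * u


@dataclass(frozen=True)
class Tube:
    """Capsule: all points within ``radius`` of segment p0-p1 (world mm)."""

    p0: tuple[float, float, float]
    p1: tuple[float, float, float]
    radius: float

    def contains(self, pts: np.ndarray, margin_mm: float = 0.0) -> np.ndarray:
        p = np.atleast_2d(pts)
        a, b = np.asarray(self.p0, float), np.asarray(self.p1, float)
        ab = b - a
        t = np.clip((p - a) @ ab / (ab @ ab), 0.0, 1.0)
        d = np.linalg.norm(p - (a + t[:, None] * ab), axis=-1)
        return d <= self.radius - margin_mm


# ---------------------------------------------------------------------------
# spec
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WarpSpec:
    """Smooth nonrigid pre->post deformation.

    amplitude_mm : peak displacement magnitude (0 disables the warp).
    scale_mm : control-point spacing of the driving field; larger values give
        smoother boundary displacement patterns.

    The driving field (random control-point displacements, cubic-interpolated)
    is sampled on the liver surface, projected onto the outward surface
    normals, and extended into the organ by a linear-elastic solve with the
    same material model the registration assumes.  The resulting truth
    deformation is therefore boundary-determined and normal-directed at the
    capsule — the deformation family a surface-driven biomechanical
    registration is built to recover.  Tangential capsule sliding is
    deliberately absent: no shape-driven correspondence can observe it, so it
    cannot serve as a recoverable ground truth.
    """

    amplitude_mm: float = 8.0
    scale_mm: float = 32.0


@dataclass(frozen=True)
class RigidOffsetSpec:
    """Rigid post->recurrence frame offset (translation mm, rotation deg about z)."""

    translation_mm: tuple[float, float, float] = (8 / 3, -8 / 3, 4 / 3)  # |t| = 4 mm
    rotation_z_deg: float = 3.0


@dataclass(frozen=True)
class PhantomSpec:
    seed: int = 0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    liver: Superellipsoid = Superellipsoid((48.0, 48.0, 48.0), (38.0, 32.0, 27.0))
    gtv: Sphere = Sphere((56.0, 52.0, 50.0), 7.0)
    ablation: Sphere = Sphere((57.0, 52.0, 51.0), 12.0)
    vessels: tuple[Tube, ...] = (
        Tube((18.0, 36.0, 48.0), (78.0, 40.0, 46.0), 2.0),
        Tube((48.0, 40.0, 47.0), (40.0, 62.0, 58.0), 1.8),
        Tube((60.0, 42.0, 46.5), (70.0, 60.0, 38.0), 1.6),
    )
    recurrence: Sphere | None = None  # auto-placed at the ablation rim if None
    deformation: WarpSpec = WarpSpec()
    rigid_offset: RigidOffsetSpec = RigidOffsetSpec()
    shrink_factor: float = 0.63  # cavity keeps 63% of its volume at follow-up
    noise_sd: float = 10.0

    @property
    def grid(self) -> Grid:
        return Grid(self.grid_shape, self.spacing)

    def validate(self) -> None:
        if not (0.0 < self.shrink_factor <= 1.0):
            raise PhantomSpecError(f"shrink_factor must be in (0, 1], got {self.shrink_factor}")
        if any(s <= 0 for s in self.spacing):
            raise PhantomSpecError("spacing must be positive")
        if not self.liver.contains(self.gtv.surface_points(200)).all():
            raise PhantomSpecError("gtv does not lie entirely inside the liver")
        for tube in self.vessels:
            a, b = np.asarray(tube.p0), np.asarray(tube.p1)
            t = np.linspace(0, 1, 25)[:, None]
            axis_pts = a + t * (b - a)
            # sample the capsule wall in two orthogonal directions
            u = b - a
            u = u / np.linalg.norm(u)
            w = np.cross(u, [0.0, 0.0, 1.0])
            if np.linalg.norm(w) < 1e-6:
                w = np.cross(u, [0.0, 1.0, 0.0])
            w = w / np.linalg.norm(w)
            w2 = np.cross(u, w)
            shell = np.vstack(
                [axis_pts + s * tube.radius * d for s in (-1, 1) for d in (w, w2)]
            )
            if not self.liver.contains(np.vstack([axis_pts, shell])).all():
                raise PhantomSpecError(f"vessel {tube} exits the liver")


def scaled_spec(
    seed: int = 0,
    shape: int = 96,
    shrink_factor: float = 0.63,
    warp_amplitude_mm: float | None = None,
    noise_sd: float = 10.0,
    spacing: float = 1.0,
) -> PhantomSpec:
    """Default phantom geometry scaled to a cubic grid of ``shape`` voxels.

    All anatomy (liver, tumor, ablation, vessels) scales linearly with the
    grid; the warp amplitude scales with it too unless given explicitly.
    """
    s = shape / 96.0
    base = PhantomSpec()

    def sc(t):
        return tuple(v * s for v in t)

    amp = warp_amplitude_mm if warp_amplitude_mm is not None else 8.0 * s
    return PhantomSpec(
        seed=seed,
        grid_shape=(shape,) * 3,
        spacing=(spacing,) * 3,
        liver=Superellipsoid(sc(base.liver.center), sc(base.liver.semi_axes)),
        gtv=Sphere(sc(base.gtv.center), base.gtv.radius * s),
        ablation=Sphere(sc(base.ablation.center), base.ablation.radius * s),
        vessels=tuple(
            Tube(sc(t.p0), sc(t.p1), max(t.radius * s, 1.2)) for t in base.vessels
        ),
        deformation=WarpSpec(amplitude_mm=amp, scale_mm=base.deformation.scale_mm * s),
        shrink_factor=shrink_factor,
        noise_sd=noise_sd,
    )


# ---------------------------------------------------------------------------
# case container
# ---------------------------------------------------------------------------


@dataclass
class PhantomCase:
    """All volumes, masks and ground-truth transforms for one synthetic case."""

    spec: PhantomSpec
    pre_volume: ImageVolume
    pre_masks: dict[str, LabelMask]
    post_volume: ImageVolume
    post_masks: dict[str, LabelMask]
    recur_volume: ImageVolume
    recur_masks: dict[str, LabelMask]
    truth_dvf: DisplacementField
    truth_rigid: RigidTransform

    def save(self, out_dir: str | Path) -> None:
        """Write all volumes/masks as NIfTI plus a JSON sidecar of the spec."""
        from . import io as _io

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for stem, vol in [
            ("pre_volume", self.pre_volume),
            ("post_volume", self.post_volume),
            ("recur_volume", self.recur_volume),
        ]:
            _io.write_volume(out / f"{stem}.nii.gz", vol)
        for prefix, masks in [
            ("pre", self.pre_masks),
            ("post", self.post_masks),
            ("recur", self.recur_masks),
        ]:
            for name, m in masks.items():
                _io.write_volume(out / f"{prefix}_{name}.nii.gz", m)
        _io.write_dvf(out / "truth_dvf.nii.gz", self.truth_dvf)
        self.truth_rigid.save(out / "truth_rigid.json")
        sidecar = asdict(self.spec)
        sidecar["rigid_matrix"] = self.truth_rigid.as_matrix().tolist()
        (out / "phantom_spec.json").write_text(json.dumps(sidecar, indent=2, default=list))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def _control_point_warp(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Dense (nx, ny, nz, 3) displacement sampled from a smooth control grid."""
    grid = spec.grid
    if spec.deformation.amplitude_mm == 0:
        return np.zeros((*grid.shape, 3))
    extent = np.asarray(grid.shape) * np.asarray(grid.spacing)
    n_ctrl = np.maximum((extent / spec.deformation.scale_mm).astype(int) + 2, 4)
    ctrl = rng.standard_normal((*n_ctrl, 3))
    ctrl[0, :, :] = ctrl[-1, :, :] = 0.0  # pin the image border so the
    ctrl[:, 0, :] = ctrl[:, -1, :] = 0.0  # warp decays to zero outside
    ctrl[:, :, 0] = ctrl[:, :, -1] = 0.0  # the field of view
    dense = np.stack(
        [
            ndimage.zoom(
                ctrl[..., c],
                np.asarray(grid.shape) / n_ctrl,
                order=3,
                mode="nearest",
                grid_mode=True,
            )
            for c in range(3)
        ],
        axis=-1,
    )
    peak = np.linalg.norm(dense, axis=-1).max()
    if peak > 0:
        dense *= spec.deformation.amplitude_mm / peak
    return dense


def _paint(
    grid: Grid,
    pts: np.ndarray,
    layers: list[tuple[np.ndarray, float]],
    noise_sd: float,
    rng: np.random.Generator,
) -> ImageVolume:
    """Compose intensity classes back-to-front; later layers override."""
    intensity = np.full(len(pts), INTENSITY["background"], dtype=np.float32)
    for mask_flat, value in layers:
        intensity[mask_flat] = value
    if noise_sd > 0:
        intensity += rng.normal(0.0, noise_sd, size=intensity.shape).astype(np.float32)
    return ImageVolume(intensity.reshape(grid.shape), grid)


def _elastic_truth_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Ground-truth deformation in the biomechanical model family.

    The control-grid driving field is sampled on the liver surface and
    projected onto the outward normals; a linear-elastic solve (default
    material) extends that boundary displacement through the organ.  Outside
    the liver the field continues by normalized-convolution smoothing and
    tapers to zero within 15 mm, so the background stays still and the field
    is continuous everywhere.  The peak magnitude is normalized to the
    requested amplitude.
    """
    from .elastic import BoundaryConditions, ElasticParams, solve_linear_elastic
    from .meshing import MeshingParams, build_tet_mesh, extract_surface_mesh
    from .registration import _interpolate_node_field

    grid = spec.grid
    if spec.deformation.amplitude_mm == 0:
        return np.zeros((*grid.shape, 3))
    driving = DisplacementField(_control_point_warp(spec, rng), grid)

    pts = grid.coordinate_grid().reshape(-1, 3)
    liver = LabelMask(spec.liver.contains(pts).reshape(grid.shape), grid)
    surf = extract_surface_mesh(liver, MeshingParams(smoothing_radius=1.0, edge_length=5.0))
    tet = build_tet_mesh(surf)
    normals = np.asarray(surf.vertex_normals)
    verts = np.asarray(surf.vertices)
    v_surf = driving.evaluate(verts)
    amp = np.einsum("ij,ij->i", v_surf, normals)
    # remove the component a rigid motion could mimic: small translations and
    # rotations move the surface normally by n·t and n·(w x (p-c)); a warp
    # containing those modes makes the pose/deformation split ill-posed, so
    # the truth deformation is made orthogonal to all six of them
    c = verts.mean(axis=0)
    basis = np.column_stack(
        [normals[:, k] for k in range(3)]
        + [
            np.einsum("ij,ij->i", normals, np.cross(np.eye(3)[k], verts - c))
            for k in range(3)
        ]
    )
    coef, *_ = np.linalg.lstsq(basis, amp, rcond=None)
    amp = amp - basis @ coef
    bc = normals * amp[:, None]
    u = solve_linear_elastic(tet, BoundaryConditions(bc), ElasticParams())

    # dense field inside the liver, then a smooth tapered continuation outside
    inside = liver.data
    field = np.zeros((*grid.shape, 3))
    field[inside] = _interpolate_node_field(
        tet.nodes, u, grid.voxel_to_world(np.argwhere(inside))
    )
    sigma_vox = 3.0 / np.asarray(grid.spacing)
    w = ndimage.gaussian_filter(inside.astype(np.float64), sigma_vox)
    ext = np.stack(
        [
            ndimage.gaussian_filter(field[..., c] * inside, sigma_vox)
            / np.maximum(w, 1e-9)
            for c in range(3)
        ],
        axis=-1,
    )
    dist_out = ndimage.distance_transform_edt(~inside, sampling=grid.spacing)
    taper = np.clip(1.0 - dist_out / 15.0, 0.0, 1.0)
    # the normalized-convolution field is used everywhere (inside it is the
    # elastic solution up to a 3 mm smoothing), keeping the truth field
    # C^1-smooth across the capsule instead of jumping to the extension
    field = ext * taper[..., None]

    peak = np.linalg.norm(field, axis=-1).max()
    if peak > 0:
        field *= spec.deformation.amplitude_mm / peak
    return field


def generate_phantom(spec: PhantomSpec) -> PhantomCase:
    """Generate one fully ground-truthed synthetic case (deterministic per seed)."""
    spec.validate()
    grid = spec.grid
    rng = np.random.default_rng(spec.seed)

    dense = _elastic_truth_field(spec, rng)
    truth_dvf = DisplacementField(dense, grid, direction="pre->post")
    jac = truth_dvf.jacobian_determinant()
    if jac.min() <= 0:
        raise PhantomSpecError(
            f"warp amplitude {spec.deformation.amplitude_mm} mm folds the grid "
            f"(min Jacobian determinant {jac.min():.3f})"
        )

    pts = grid.coordinate_grid().reshape(-1, 3)

    # --- pre frame: analytic shapes at rest -------------------------------
    liver_pre = spec.liver.contains(pts)
    gtv_pre = spec.gtv.contains(pts)
    vessels_pre = np.zeros(len(pts), dtype=bool)
    for tube in spec.vessels:
        vessels_pre |= tube.contains(pts)
    pre_volume = _paint(
        grid,
        pts,
        [
            (liver_pre, INTENSITY["liver"]),
            (gtv_pre, INTENSITY["tumor"]),
            (vessels_pre, INTENSITY["vessel"]),
        ],
        spec.noise_sd,
        rng,
    )
    pre_masks = {
        "liver": LabelMask(liver_pre.reshape(grid.shape), grid),
        "gtv": LabelMask(gtv_pre.reshape(grid.shape), grid),
        "vessels": LabelMask(vessels_pre.reshape(grid.shape), grid),
    }

    # --- post frame: pre shapes pushed through the warp -------------------
    # A post voxel y belongs to a warped structure iff the inverse-warped
    # point x (x + v(x) = y) lies inside the analytic pre shape.
    if spec.deformation.amplitude_mm == 0:
        x_inv = pts
    else:
        x_inv = truth_dvf.invert_points(pts, max_iter=200, tol_mm=0.02)
    liver_post = spec.liver.contains(x_inv)
    vessels_post = np.zeros(len(pts), dtype=bool)
    for tube in spec.vessels:
        vessels_post |= tube.contains(x_inv)
    ablation_post = spec.ablation.contains(pts)  # the cavity lives in the post frame
    post_volume = _paint(
        grid,
        pts,
        [
            (liver_post, INTENSITY["liver"]),
            (ablation_post, INTENSITY["ablation"]),
            (vessels_post, INTENSITY["vessel"]),
        ],
        spec.noise_sd,
        rng,
    )
    post_masks = {
        "liver": LabelMask(liver_post.reshape(grid.shape), grid),
        "ablation": LabelMask(ablation_post.reshape(grid.shape), grid),
        "vessels": LabelMask(vessels_post.reshape(grid.shape), grid),
    }

    # --- recurrence frame: post frame under a rigid offset ----------------
    abl_centroid = post_masks["ablation"].centroid_mm()
    truth_rigid = RigidTransform.from_params(
        (0.0, 0.0, spec.rigid_offset.rotation_z_deg),
        spec.rigid_offset.translation_mm,
        tuple(abl_centroid),
    )
    shrunk = Sphere(
        spec.ablation.center, spec.ablation.radius * spec.shrink_factor ** (1 / 3)
    )
    recurrence = spec.recurrence
    if recurrence is None:
        u = np.asarray(spec.gtv.center) - np.asarray(spec.ablation.center)
        nu = np.linalg.norm(u)
        u = u / nu if nu > 1e-6 else np.array([0.0, 0.0, 1.0])
        recurrence = Sphere(
            tuple(np.asarray(spec.ablation.center) + u * (shrunk.radius + 3.0)), 5.0
        )

    # recur voxel y corresponds to post point p = T^-1(y); nonrigid content
    # additionally pulls back to x = warp^-1(p)
    p_post = truth_rigid.inverse().apply(pts)
    if spec.deformation.amplitude_mm == 0:
        x_recur = p_post
    else:
        x_recur = truth_dvf.invert_points(p_post, max_iter=200, tol_mm=0.02)
    liver_recur = spec.liver.contains(x_recur)
    vessels_recur = np.zeros(len(pts), dtype=bool)
    for tube in spec.vessels:
        vessels_recur |= tube.contains(x_recur)
    ablation_recur = shrunk.contains(p_post)
    recur_mask = recurrence.contains(p_post)
    recur_volume = _paint(
        grid,
        pts,
        [
            (liver_recur, INTENSITY["liver"]),
            (ablation_recur, INTENSITY["ablation"]),
            (recur_mask, INTENSITY["tumor"]),
            (vessels_recur, INTENSITY["vessel"]),
        ],
        spec.noise_sd,
        rng,
    )
    recur_masks = {
        "liver": LabelMask(liver_recur.reshape(grid.shape), grid),
        "ablation_shrunk": LabelMask(ablation_recur.reshape(grid.shape), grid),
        "recurrence": LabelMask(recur_mask.reshape(grid.shape), grid),
        "vessels": LabelMask(vessels_recur.reshape(grid.shape), grid),
    }

    return PhantomCase(
        spec=spec,
        pre_volume=pre_volume,
        pre_masks=pre_masks,
        post_volume=post_volume,
        post_masks=post_masks,
        recur_volume=recur_volume,
        recur_masks=recur_masks,
        truth_dvf=truth_dvf,
        truth_rigid=truth_rigid,
    )


def simulate_ablation_shrinkage(mask: LabelMask, shrink_factor: float) -> LabelMask:
    """Centroid-preserving isotropic contraction of a mask.

    The linear scale is ``shrink_factor ** (1/3)`` so the volume ratio of the
    result is ``shrink_factor`` (up to voxelization).  Factor 1 returns the
    mask unchanged.
    """
    if shrink_factor <= 0 or shrink_factor > 1:
        raise ValueError(f"shrink_factor must be in (0, 1], got {shrink_factor}")
    if shrink_factor == 1.0:
        return LabelMask(mask.data.copy(), mask.grid)
    c = mask.centroid_mm()
    pts = mask.grid.coordinate_grid().reshape(-1, 3)
    data = mask.data.astype(np.float32)
    n_src = mask.n_voxels

    def contract(scale: float) -> np.ndarray:
        # voxel y is kept iff its scaled-up preimage was inside the mask
        idx = mask.grid.world_to_voxel(c + (pts - c) / scale)
        vals = ndimage.map_coordinates(
            data, idx.T, order=1, mode="constant", cval=0.0
        )
        return (vals >= 0.5).reshape(mask.grid.shape)

    # the half-voxel surface convention of resampling biases the delivered
    # volume; two corrective iterations pin the voxel-count ratio to the
    # requested factor within surface-shell quantization
    s = shrink_factor ** (1.0 / 3.0)
    out = contract(s)
    for _ in range(2):
        achieved = out.sum() / n_src
        if achieved <= 0:
            break
        s *= (shrink_factor / achieved) ** (1.0 / 3.0)
        out = contract(s)
    return LabelMask(out, mask.grid)
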