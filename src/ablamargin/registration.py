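"""Rigid and biomechanical deformable registration of liver volumes.

The deformable pipeline mirrors the Morfeus-style biomechanical approach:

1. automated gray-level cross-correlation rigid registration of the liver
   regions of interest;
2. triangular surface meshes of both livers (see :mod:`ablamargin.meshing`);
3. surface correspondence between the rigidly aligned pre-treatment mesh and
   the post-treatment mesh, which supplies Dirichlet boundary conditions;
4. a linear-elastic finite-element solve over the liver interior
   (:mod:`ablamargin.elastic`);
5. rasterization of the node displacements to a dense displacement field on
   the pre-treatment liver ROI grid, composed with the rigid stage so the
   field maps pre-treatment points directly into the post-treatment frame.

Contours are propagated through transforms via their surface vertices and
re-voxelized — labels are never intensity-interpolated.
"""

from __future__ import annotations

import numpy as np
import trimesh
from scipy import ndimage
from scipy.interpolate import LinearNDInterpolator, NearestNDInterpolator
from scipy.optimize import minimize
from skimage.measure import marching_cubes

from .elastic import BoundaryConditions, ElasticParams, solve_linear_elastic
from .grid import Grid, ImageVolume, LabelMask, require_same_grid
from .meshing import (
    MeshingError,
    MeshingParams,
    TetMesh,
    build_tet_mesh,
    closest_point_on_surface,
    extract_surface_mesh,
    voxelize_surface,
)
from .transforms import DisplacementField, RigidTransform

__all__ = [
    "RegistrationError",
    "rigid_register",
    "surface_correspondence",
    "rasterize_dvf",
    "propagate_contour",
    "biomech_register",
    "mask_to_surface",
]


class RegistrationError(RuntimeError):
    """A registration stage failed; the message names the stage."""


# ---------------------------------------------------------------------------
# rigid gray-level registration
# ---------------------------------------------------------------------------


def _downsample(data: np.ndarray, grid: Grid, factor: int) -> tuple[np.ndarray, Grid]:
    if factor == 1:
        return data.astype(np.float32), grid
    out = ndimage.zoom(data.astype(np.float32), 1.0 / factor, order=1)
    g = Grid(
        out.shape,
        tuple(s * factor for s in grid.spacing),
        grid.origin,
    )
    return out, g


def _sample_at(data: np.ndarray, grid: Grid, pts: np.ndarray, cval: float) -> np.ndarray:
    idx = grid.world_to_voxel(pts)
    return ndimage.map_coordinates(data, idx.T, order=1, mode="constant", cval=cval)


def _masked_ncc(a: np.ndarray, b: np.ndarray, w: np.ndarray) -> float:
    wsum = w.sum()
    if wsum <= 0:
        return 0.0
    am = (w * a).sum() / wsum
    bm = (w * b).sum() / wsum
    da, db = a - am, b - bm
    num = (w * da * db).sum()
    den = np.sqrt((w * da * da).sum() * (w * db * db).sum())
    if den <= 1e-12:
        return 0.0
    return float(num / den)


def rigid_register(
    fixed_volume: ImageVolume,
    moving_volume: ImageVolume,
    fixed_mask: LabelMask,
    moving_mask: LabelMask,
    coarse_range_mm: float = 12.0,
    coarse_step_mm: float = 3.0,
    max_rotation_deg: float = 10.0,
) -> RigidTransform:
    """Gray-level cross-correlation rigid registration of the liver ROIs.

    Returns the resampling transform ``T`` (fixed-frame points to moving-frame
    points): ``moving(T(x)) ≈ fixed(x)``.  Equivalently, a structure sitting
    at ``p`` in the fixed frame sits at ``T(p)`` in the moving frame.  The
    optimization is deterministic: mask-centroid initialization, an
    exhaustive coarse translation search on 4x-downsampled volumes, then
    local derivative-free (Powell) refinement of all six parameters on
    2x-downsampled volumes.
    """
    require_same_grid(fixed_volume, fixed_mask)
    require_same_grid(moving_volume, moving_mask)
    if not fixed_mask.data.any() or not moving_mask.data.any():
        raise RegistrationError("rigid: empty liver mask")
    if fixed_volume.data.std() < 1e-6 or moving_volume.data.std() < 1e-6:
        raise RegistrationError("rigid: constant image, correlation undefined")

    center = fixed_mask.centroid_mm()
    t0 = moving_mask.centroid_mm() - center
    mov_min = float(moving_volume.data.min())

    weights_full = ndimage.binary_dilation(fixed_mask.data, iterations=3).astype(np.float32)

    def stage_data(factor: int):
        f, g = _downsample(fixed_volume.data, fixed_volume.grid, factor)
        w, _ = _downsample(weights_full, fixed_volume.grid, factor)
        m, mg = _downsample(moving_volume.data, moving_volume.grid, factor)
        sel = w.ravel() > 0  # NCC only needs the masked neighborhood
        pts = g.coordinate_grid().reshape(-1, 3)[sel]
        return f.ravel()[sel], w.ravel()[sel], pts, m, mg

    def objective(params: np.ndarray, f_sel, w_sel, pts, m_data, m_grid) -> float:
        T = RigidTransform.from_params(tuple(params[3:]), tuple(params[:3]), tuple(center))
        sampled = _sample_at(m_data, m_grid, T.apply(pts), mov_min)
        return -_masked_ncc(f_sel, sampled, w_sel)

    # stage 1: exhaustive coarse translation scan at 4x downsampling
    d4 = stage_data(4)
    offsets = np.arange(-coarse_range_mm, coarse_range_mm + 1e-9, coarse_step_mm)
    best, best_t = np.inf, t0
    for dx in offsets:
        for dy in offsets:
            for dz in offsets:
                t = t0 + np.array([dx, dy, dz])
                val = objective(np.r_[t, 0, 0, 0], *d4)
                if val < best:
                    best, best_t = val, t

    # stage 2: Powell refinement of all six parameters at 2x downsampling
    d2 = stage_data(2)
    x0 = np.r_[best_t, 0.0, 0.0, 0.0]
    bounds = [(bt - 2 * coarse_step_mm, bt + 2 * coarse_step_mm) for bt in best_t]
    bounds += [(-max_rotation_deg, max_rotation_deg)] * 3
    res = minimize(
        objective, x0, args=d2, method="Powell",
        bounds=bounds, options={"xtol": 1e-3, "ftol": 1e-7, "maxiter": 60},
    )

    # stage 3: full-resolution polish in a tight window.  The downsampled
    # landscape can drag the rotation several degrees off the full-resolution
    # optimum, so the polish is multi-started from the stage-2 result and
    # from a zero-rotation restart, keeping whichever scores better.
    d1 = stage_data(1)
    candidates = [res.x, np.r_[res.x[:3], 0.0, 0.0, 0.0]]
    best_val, best_x = np.inf, res.x
    for x1 in candidates:
        # re-center the trust window whenever the optimum lands on its edge,
        # so a poor 2x starting point cannot cap the polished solution
        for _ in range(4):
            bounds = [(v - 2.0, v + 2.0) for v in x1[:3]]
            bounds += [
                (max(v - 2.0, -max_rotation_deg), min(v + 2.0, max_rotation_deg))
                for v in x1[3:]
            ]
            r = minimize(
                objective, x1, args=d1, method="Powell",
                bounds=bounds, options={"xtol": 1e-3, "ftol": 1e-8, "maxiter": 20},
            )
            at_edge = any(
                min(abs(v - lo), abs(v - hi)) < 1e-3
                for v, (lo, hi) in zip(r.x, bounds)
            )
            x1 = r.x
            if not at_edge:
                break
        if r.fun < best_val:
            best_val, best_x = r.fun, r.x
    p = best_x
    return RigidTransform.from_params(tuple(p[3:]), tuple(p[:3]), tuple(center))


# ---------------------------------------------------------------------------
# surface correspondence -> boundary conditions
# ---------------------------------------------------------------------------


def _ray_hits(
    origins: np.ndarray, dirs: np.ndarray, tri: np.ndarray, max_range_mm: float
) -> np.ndarray:
    """Smallest non-negative ray parameter per ray (inf on miss).

    Möller-Trumbore against the full triangle soup, chunked over rays; at the
    mesh sizes this package produces (a few thousand triangles) exhaustive
    testing is faster than building spatial indices.
    """
    v0, e1, e2 = tri[:, 0], tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]
    best = np.full(len(origins), np.inf)
    for s in range(0, len(origins), 256):
        o = origins[s : s + 256, None, :]
        d = dirs[s : s + 256, None, :]
        p = np.cross(d, e2[None])
        det = np.einsum("rtk,tk->rt", p, e1)
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = 1.0 / det
            tvec = o - v0[None]
            u = np.einsum("rtk,rtk->rt", tvec, p) * inv
            q = np.cross(tvec, e1[None])
            v = np.einsum("rtk,rtk->rt", q, d) * inv
            t = np.einsum("rtk,tk->rt", q, e2) * inv
            ok = (
                (np.abs(det) > 1e-12)
                & (u >= -1e-9)
                & (v >= -1e-9)
                & (u + v <= 1 + 1e-9)
                & (t >= 0)
                & (t <= max_range_mm)
            )
        t = np.where(ok, t, np.inf)
        best[s : s + 256] = t.min(axis=1)
    return best


def _normal_shoot(
    source: trimesh.Trimesh, target: trimesh.Trimesh, max_range_mm: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest target intersection along each source vertex normal (±).

    Returns (displacements, hit_mask); vertices whose normal ray misses the
    target within ``max_range_mm`` have hit_mask False.
    """
    verts = np.asarray(source.vertices, dtype=float)
    normals = np.asarray(source.vertex_normals, dtype=float)
    tri = np.asarray(target.triangles, dtype=float)
    t_fwd = _ray_hits(verts, normals, tri, max_range_mm)
    t_bwd = _ray_hits(verts, -normals, tri, max_range_mm)
    t_signed = np.where(t_fwd <= t_bwd, t_fwd, -t_bwd)
    hit = np.isfinite(t_signed)
    disp = np.zeros_like(verts)
    disp[hit] = normals[hit] * t_signed[hit, None]
    return disp, hit


def surface_correspondence(
    source: trimesh.Trimesh,
    target: trimesh.Trimesh,
    smoothing_iterations: int = 3,
    smoothing_weight: float = 0.5,
    max_shoot_range_mm: float = 25.0,
) -> BoundaryConditions:
    """Boundary displacements carrying each source vertex onto the target.

    Projection of every source vertex onto the target surface along the
    source vertex normal (the nearer of the two intersections, either side),
    falling back to the Euclidean closest point where the normal ray misses;
    then Laplacian smoothing of the displacement field over the source mesh
    graph (default 3 iterations, weight 0.5) and re-projection so the
    smoothed displacements still land on the target surface.
    """
    s_lo, s_hi = source.bounds
    t_lo, t_hi = target.bounds
    if np.any(s_hi < t_lo) or np.any(t_hi < s_lo):
        raise RegistrationError(
            "correspondence: disjoint bounding boxes — run rigid alignment first"
        )
    verts = np.asarray(source.vertices, dtype=float)
    disp, hit = _normal_shoot(source, target, max_shoot_range_mm)
    if not hit.all():
        proj, _ = closest_point_on_surface(target, verts[~hit])
        disp[~hit] = proj - verts[~hit]

    if smoothing_iterations > 0:
        n = len(verts)
        e = source.edges_unique
        for _ in range(smoothing_iterations):
            acc = np.zeros_like(disp)
            cnt = np.zeros(n)
            np.add.at(acc, e[:, 0], disp[e[:, 1]])
            np.add.at(acc, e[:, 1], disp[e[:, 0]])
            np.add.at(cnt, e[:, 0], 1)
            np.add.at(cnt, e[:, 1], 1)
            has = cnt > 0
            disp[has] = (1 - smoothing_weight) * disp[has] + smoothing_weight * (
                acc[has] / cnt[has, None]
            )
        proj, _ = closest_point_on_surface(target, verts + disp)
        disp = proj - verts
    return BoundaryConditions(disp)


# ---------------------------------------------------------------------------
# dense field rasterization
# ---------------------------------------------------------------------------


def _interpolate_node_field(
    nodes: np.ndarray, values: np.ndarray, points: np.ndarray
) -> np.ndarray:
    """Piecewise-linear interpolation of per-node vectors, nearest outside."""
    lin = LinearNDInterpolator(nodes, values)
    out = lin(points)
    bad = np.isnan(out).any(axis=1)
    if bad.any():
        nearest = NearestNDInterpolator(nodes, values)
        out[bad] = nearest(points[bad])
    return out


def rasterize_dvf(
    mesh: TetMesh,
    node_displacements: np.ndarray,
    roi: LabelMask,
    direction: str = "pre->post",
) -> DisplacementField:
    """Resample FEM node displacements onto the voxels of the liver ROI.

    Piecewise-linear (barycentric) interpolation at every ROI voxel center,
    nearest-node extrapolation for support voxels just outside the mesh; the
    field is zero outside the ROI dilated by one voxel layer.
    """
    support = ndimage.binary_dilation(roi.data, iterations=1)
    if not support.any():
        raise RegistrationError("rasterize: empty ROI")
    pts = roi.grid.voxel_to_world(np.argwhere(support))
    lo, hi = mesh.nodes.min(0), mesh.nodes.max(0)
    if np.all(pts.max(0) < lo) or np.all(pts.min(0) > hi):
        raise RegistrationError("rasterize: ROI grid disjoint from mesh")
    vals = _interpolate_node_field(mesh.nodes, np.asarray(node_displacements, float), pts)
    field = np.zeros((*roi.grid.shape, 3))
    field[support] = vals
    return DisplacementField(field, roi.grid, direction=direction)


# ---------------------------------------------------------------------------
# contour propagation (surface-vertex pathway)
# ---------------------------------------------------------------------------


def mask_to_surface(mask: LabelMask) -> trimesh.Trimesh:
    """Watertight 0.5 iso-surface of a binary mask at native resolution.

    Vertices sit halfway between inside and outside voxel centers, so
    re-voxelizing the untransformed surface reproduces the mask exactly.
    """
    if not mask.data.any():
        raise ValueError("cannot extract a surface from an empty mask")
    padded = np.pad(mask.data.astype(np.float32), 1)
    verts, faces, _, _ = marching_cubes(padded, level=0.5, spacing=mask.grid.spacing)
    verts = verts + np.asarray(mask.grid.origin) - np.asarray(mask.grid.spacing)
    mesh = trimesh.Trimesh(vertices=verts, faces=faces, process=True)
    mesh.fix_normals()
    return mesh


def propagate_contour(
    mask: LabelMask,
    transform: RigidTransform | DisplacementField,
    direction: str = "forward",
    target_grid: Grid | None = None,
) -> LabelMask:
    """Map a label mask through a rigid transform or displacement field.

    The mask's surface vertices are moved through the transform and the moved
    surface is re-voxelized on ``target_grid`` (default: the source grid) —
    no intensity interpolation of labels.  ``direction="forward"`` moves
    pre-frame structures into the post frame for a ``pre->post`` field (or
    applies a rigid transform as-is); ``"inverse"`` goes the other way, using
    fixed-point inversion for displacement fields.
    """
    if direction not in ("forward", "inverse"):
        raise ValueError(f"direction must be 'forward' or 'inverse', got {direction!r}")
    grid = target_grid or mask.grid
    surf = mask_to_surface(mask)
    verts = np.asarray(surf.vertices, dtype=float)
    if isinstance(transform, RigidTransform):
        T = transform if direction == "forward" else transform.inverse()
        moved = T.apply(verts)
    else:
        if direction == "forward":
            moved = transform.transform_points(verts)
        else:
            moved = transform.invert_points(verts)
    out = voxelize_surface(
        trimesh.Trimesh(vertices=moved, faces=surf.faces, process=False), grid
    )
    return LabelMask(out, grid)


def _fit_rigid(points: np.ndarray, targets: np.ndarray) -> RigidTransform:
    """Least-squares rigid transform carrying ``points`` onto ``targets`` (Kabsch)."""
    pc, tc = points.mean(0), targets.mean(0)
    H = (points - pc).T @ (targets - tc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    return RigidTransform(R, tc - R @ pc)


# ---------------------------------------------------------------------------
# full biomechanical pipeline
# ---------------------------------------------------------------------------


def biomech_register(
    pre_volume: ImageVolume,
    pre_liver: LabelMask,
    post_volume: ImageVolume,
    post_liver: LabelMask,
    meshing: MeshingParams = MeshingParams(),
    elastic: ElasticParams = ElasticParams(),
) -> tuple[RigidTransform, DisplacementField]:
    """Rigid + biomechanical deformable registration, pre -> post.

    Returns ``(rigid, dvf)`` where ``rigid`` maps pre-treatment world points
    to their rigidly aligned post-frame positions and ``dvf`` is the *total*
    displacement field on the pre-treatment liver ROI grid: a pre-frame point
    ``x`` corresponds to ``x + dvf(x)`` in the post-treatment frame (rigid
    and elastic composed).
    """

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None and not isinstance(exc, RegistrationError):
                    raise RegistrationError(f"{name}: {exc}") from exc
                return False

        return _Ctx()

    with stage("rigid registration"):
        # resampling transform post->pre; its inverse carries pre points to post
        t_post2pre = rigid_register(post_volume, pre_volume, post_liver, pre_liver)
        t_pre2post = t_post2pre.inverse()

    with stage("surface meshing"):
        pre_mesh = extract_surface_mesh(pre_liver, meshing)
        post_mesh = extract_surface_mesh(post_liver, meshing)
        aligned = trimesh.Trimesh(
            vertices=t_pre2post.apply(np.asarray(pre_mesh.vertices)),
            faces=pre_mesh.faces,
            process=False,
        )

    with stage("surface correspondence"):
        # minimal-deformation pose: any net rigid component left in the
        # correspondence field is tangential motion the normal-projection
        # cannot represent, so it is absorbed into the rigid stage (surface
        # ICP) until the residual field is purely deformational
        for _ in range(4):
            bc = surface_correspondence(aligned, post_mesh)
            verts = np.asarray(aligned.vertices)
            t_fit = _fit_rigid(verts, verts + bc.displacements)
            dt = np.linalg.norm(t_fit.translation)
            dr = np.linalg.norm(t_fit.angles_deg())
            if dt < 0.05 and dr < 0.05:
                break
            t_pre2post = t_fit.compose(t_pre2post)
            aligned = trimesh.Trimesh(
                vertices=t_fit.apply(verts), faces=aligned.faces, process=False
            )
        bc = surface_correspondence(aligned, post_mesh)

    with stage("tetrahedralization"):
        tet = build_tet_mesh(aligned)

    with stage("elastic solve"):
        node_u = solve_linear_elastic(tet, bc, elastic)

    with stage("DVF rasterization"):
        support = ndimage.binary_dilation(pre_liver.data, iterations=1)
        pts_pre = pre_liver.grid.voxel_to_world(np.argwhere(support))
        pts_aligned = t_pre2post.apply(pts_pre)
        u_el = _interpolate_node_field(tet.nodes, node_u, pts_aligned)
        total = pts_aligned + u_el - pts_pre
        field = np.zeros((*pre_liver.grid.shape, 3))
        field[support] = total
        dvf = DisplacementField(field, pre_liver.grid, direction="pre->post")

    return t_pre2post, dvf
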