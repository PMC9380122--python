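# Methods

`ablamargin` quantifies whether a percutaneous thermal ablation of a liver
tumor delivered the intended minimum margin, and whether a later local tumor
progression (LTP) points back at the region where that margin was missed.
This note documents the models, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Biomechanical deformable registration

The liver deforms between the pre-treatment scan and the post-ablation scan
(breathing phase, patient position, ablation-induced change), so the tumor
contour cannot simply be overlaid on the ablation zone. The registration
pipeline is:

1. **Rigid stage.** Gray-level normalized cross-correlation of the liver
   regions of interest. The optimizer is deterministic: mask-centroid
   initialization, an exhaustive translation scan on 4×-downsampled volumes
   (±12 mm, 3 mm steps), Powell refinement of all six parameters at 2×
   downsampling, then a full-resolution Powell polish multi-started from the
   2× optimum and from a zero-rotation restart (the coarse landscape can
   strand the rotation several degrees from the full-resolution optimum;
   keeping the better of the two restarts removes that failure mode).
2. **Surface meshing.** Triangular liver surfaces from both masks
   (see below), with the pre-treatment mesh carried through the rigid
   transform.
3. **Surface correspondence → boundary conditions.** Each aligned
   pre-treatment vertex is projected onto the post-treatment surface along
   its vertex normal (nearer of the two intersections; Euclidean closest
   point where the ray misses within 25 mm), the displacement field is
   Laplacian-smoothed on the mesh graph (3 iterations, weight 0.5) and
   re-projected. A surface-ICP loop absorbs any net rigid component of the
   correspondence field back into the rigid stage, so the elastic stage only
   sees genuine deformation. Tangential surface motion is fundamentally
   unobservable from shapes alone; the correspondence is therefore
   normal-directed by construction.
4. **Elastic solve.** The liver interior is a homogeneous isotropic
   linear-elastic solid — Young's modulus 1000 Pa, Poisson's ratio 0.45 — with
   the surface displacement prescribed everywhere (pure Dirichlet, no body
   force). Under pure Dirichlet conditions the displacement solution is
   independent of the Young's modulus; only the Poisson ratio shapes how
   boundary motion diffuses inward. Both facts are exploited as exactness
   tests, together with machine-precision reproduction of rigid-body and
   affine boundary data (guaranteed for linear tetrahedra on a conforming
   mesh).
5. **Rasterization.** Node displacements are interpolated piecewise-linearly
   at every voxel of the pre-treatment liver ROI (nearest-node continuation
   for the one-voxel support layer) and composed with the rigid stage, giving
   a total displacement field: a pre-treatment point `x` corresponds to
   `x + v(x)` post-treatment.

Contours always travel through transforms via their surface vertices
(marching-cubes surface at the 0.5 level of the binary mask, vertices moved,
interior re-voxelized); labels are never intensity-interpolated. The
re-voxelizer is a scanline parity fill, exact for watertight surfaces.

### Meshing

The two tunable mesh-creation parameters are the mask smoothing radius
(Gaussian, σ = radius/2; default 1 mm) and the target triangle edge length
(default 6 mm; the investigated grid is edges {3, 6, 9, 12} × radii
{1, 3, 5} mm, selectable per case by Dice against the source mask).
Extraction computes a signed Euclidean distance field of the smoothed mask
and runs marching cubes on that field resampled to a lattice of pitch
edge/1.35: linear interpolation of an SDF places iso-surface vertices on the
true boundary even on a coarse lattice, where a resampled sharp occupancy
systematically erodes convex shapes. Delivered mean edge ≈ 0.73× the
requested edge (within the ±30% contract); enclosed volume is conserved to
≤ 3% at default parameters for organ-scale shapes.

Tetrahedralization is Delaunay over the surface vertices plus an interior
Steiner lattice at the surface edge spacing, jittered with a fixed-seed
perturbation (a regular lattice is maximally degenerate for Delaunay).
Tetrahedra whose centroid falls outside the surface (signed-distance test
with a half-voxel-permissive band) are discarded, carving hull tets that
span concave regions. Interior nodes touching a degenerate sliver or left
exposed on the kept-tet union boundary are deleted and the rest
re-triangulated — every free node keeps a complete star, which is what makes
the affine patch test exact.

## Margin (minimum distance to agreement)

The delivered margin at a mapped-tumor surface point is its Euclidean
distance to the ablation-zone boundary when the ablation encompasses it, and
0 mm where the surfaces overlap or the tumor pokes outside — the margin has a
closed lower limit of 0. Surfaces are boundary voxels under 6-connectivity;
distances use the exact Euclidean distance transform in physical spacing
(anisotropy respected), sampled at tumor surface voxels, which makes the
computation equal to the brute-force surface-pair minimum by construction
(asserted within one voxel diagonal in the tests).

For subcapsular tumors no margin can exist beyond the liver capsule, so the
ablation mask is first expanded by 10 mm strictly *outside* the liver; the
reported minimum is then the minimum margin within the liver. The
"uncovered region" — (tumor ⊕ 5 mm) \ ablation, inside the liver — is the
tissue the intended margin required but the ablation missed, and the target
set for cone tracing. Voxelized dilations measured from voxel centers
under-reach by about half a voxel per surface; at 1 mm spacing this biases
thin-shell volumes low by ~15%, falling to ~3% at 0.25 mm (the spacing the
shell test uses).

## Cone tracing

The recurrence is expressed as the set of directions from the centroid of
the recovered (follow-up) ablation zone to every recurrence voxel — a union
of per-voxel rays binned on an equiangular (θ, φ) grid: θ ∈ [0°, 180°] from
the world +z axis, φ ∈ [−180°, 180°) from +x, default bin 2°, floor
convention at bin edges, poles merged over φ. The direction set is carried
into the post-treatment frame by the rotation of the rigid post→follow-up
registration (translation cannot affect a direction) and re-anchored at the
post-treatment ablation centroid; overlap is the set of uncovered-region
voxels whose direction falls in an occupied bin.

Because rays are infinitely thin, a voxelized recurrence near the centroid
cannot populate bins finer than its voxels' angular footprint; an optional
angular dilation (bins, wrapping in φ) restores solid coverage. Overlap
volume is monotone non-decreasing in that dilation.

Frame registration between post-ablation and follow-up scans is rigid only
(the cavity shrinks — by 37% on average — and no validated deformable model
exists for that) and driven solely by vasculature within spheres of interest
(default radius 75 mm, selectable 50/100) centered on the two ablation-zone
centroids. Vessels come from a multiscale Hessian tubularity (Frangi) filter
inside the liver: maximum response over scales {1, 2, 3} mm, α = β = 0.5,
intensity-adaptive γ (half the maximum Hessian Frobenius norm), bright-on-
dark polarity, thresholded at 25% of the in-liver maximum, components under
50 voxels removed — the result is invariant to the absolute intensity scale.
When fewer than 200 vessel voxels fall inside the spheres the registration
refuses and raises an insufficient-vasculature signal; the pipeline then
accepts an externally supplied (manual) transform and flags the case.

## Cohort statistics

The packaged 30-patient table (14 LTP, 16 LTP-free) stores the published
per-patient outcomes verbatim: minimum DTA, and % / cc of tumor volume
mapped outside the ablation zone, under rigid-only and deformable
registration. Group comparison uses the two-sided Mann–Whitney U test
(midranks for ties; exact enumeration when n·m ≤ 400 and tie-free, else the
tie-corrected normal approximation with continuity correction) — the data
are unpaired and the DTA is censored at 0. Discrimination is the ROC AUC via
the rank-sum identity AUC = U/(n·m) with ties counted ½ (LTP-free scored
higher). Summary rows use the population standard deviation (ddof = 0), the
convention under which the published pooled values reproduce exactly. Two
printed summary cells of the source table are internally inconsistent with
their own rows (the LTP-free DTA means); summaries here are always computed
from the rows.

## Synthetic phantom

The generator emulates the three imaging time points on a common grid
(default (96 mm)³ at 1 mm; anisotropy supported): a superellipsoid liver, a
spherical tumor, an ablation cavity overlapping it, capsule-shaped vessels,
piecewise-constant tissue intensities (background −1000, liver 100, vessels
200, cavity 40, tumor 60) with Gaussian noise (σ = 10). The follow-up frame
is the post frame under a rigid offset (4 mm translation + 3° rotation by
default) with the cavity contracted to 63% of its volume (centroid-preserving
isotropic scaling by 0.63^(1/3), with two corrective iterations that pin the
delivered voxel-count ratio to the requested factor) and a recurrence nodule
placed
at the cavity rim on the least-covered side. All shapes are analytic, so
masks re-rasterize through any transform without accumulating resampling
error; generation is bit-reproducible per seed.

**Ground-truth deformation.** A smooth random control-grid field supplies a
boundary displacement pattern on the liver surface; it is projected onto the
outward surface normals, orthogonalized against the six rigid-motion normal
traces `n·t` and `n·(ω × (p − c))`, and extended through the organ by the
same linear-elastic model the registration assumes (then continued outside
the liver by normalized-convolution smoothing with a 15 mm taper, and peak-
normalized to the requested amplitude, default 8 mm). Diffeomorphism is
verified numerically (Jacobian determinant positive everywhere); a random
draw that would fold is rejected with an invalid-specification error rather
than silently attenuated.

This construction is deliberate, and it defines what the registration tests
mean. A surface-driven biomechanical registration can only ever recover
deformations that are (a) determined by their boundary values through the
elastic model and (b) normal-directed at the capsule — tangential sliding
and sub-organ-scale interior deformation are invisible to it in principle
(with oracle boundary conditions, a free-form smooth warp still leaves
1.5–2 mm mean interior error). The phantom therefore draws its ground truth
from exactly the recoverable family, and the rigid-trace orthogonalization
makes the pose/deformation split well-posed. Passing the recovery tests
(mean dense-field error ≤ 1 voxel, mean surface TRE ≤ 1.5 mm, propagated-
tumor Dice ≥ 0.85 under an 8 mm warp) demonstrates that the implementation
realizes its model correctly — it does *not* demonstrate accuracy on real
livers, where sliding, heterogeneity and segmentation error all violate the
model. The same caveat applies to the piecewise-constant intensities: they
exercise cross-correlation and tubularity filters but carry none of the
texture, partial-volume or contrast-timing effects of real CT.

## Problem sizes and runtime choices

Tests run phantoms at (64 mm)³–(96 mm)³ with the anatomy scaled to the grid;
the full-size case is generated once per session and shared. The end-to-end
pipeline on a (96 mm)³ case takes on the order of a minute on one CPU
(registration ≈ 30 s, vessel filtering ≈ 10 s per time point). The
acceptance script runs one full-size workflow plus four (64 mm)³ colocation
cases. Thin-shell volume checks use 0.25 mm grids over small windows.

## Known limitations

- Tangential surface motion is not recoverable by design; real inter-scan
  liver deformation contains some.
- The rigid/deformable split is ambiguous for smooth, feature-poor organs;
  the multi-start polish and ICP absorption control but do not eliminate it.
- Vesselness assumes near-isotropic voxels (scales are converted with the
  mean spacing); strongly anisotropic scans should be resampled first.
- Voxel-center distance transforms bias thin-structure volumes low by about
  half a voxel per bounding surface.
- The cone's per-voxel rays under-cover fine angular bins near the centroid
  unless an angular dilation comparable to the voxel footprint is applied.
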