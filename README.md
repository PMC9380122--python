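# ablamargin

Tools for assessing the outcome of percutaneous thermal ablation (PTA) of
colorectal liver metastases. After an ablation, the clinically decisive
question is whether the treated zone covered the gross tumor volume (GTV)
with the intended minimum margin (5 mm) in all three dimensions — a question
2D distance measurements and rigid image overlay answer badly, because the
liver deforms between the pre-treatment and post-ablation scans.

`ablamargin` implements the complete workflow for interventional-radiology
physicists and image-analysis researchers:

- **Biomechanical deformable registration** of the pre-treatment onto the
  post-ablation CT: gray-level cross-correlation rigid alignment of the liver
  ROIs, triangular surface meshing of both liver segmentations, surface
  correspondence supplying Dirichlet boundary conditions, and a linear-elastic
  finite-element solve over the organ interior (Young's modulus *E* = 1000 Pa,
  Poisson's ratio *ν* = 0.45; under pure Dirichlet conditions the solution is
  independent of *E*). The result is a dense displacement field `x ↦ x + v(x)`
  that carries the tumor contour into the post-ablation frame.
- **3D minimum delivered margin** (minimum distance to agreement): for every
  mapped-tumor surface voxel, the Euclidean distance to the ablation-zone
  boundary where the ablation encompasses it, 0 mm where it does not; the
  ablation is expanded 10 mm outside the liver first so subcapsular tumors are
  scored by their in-liver margin. Also reported: % and cm³ of GTV outside the
  ablation, and the *uncovered region* (GTV ⊕ 5 mm) \ ablation within the liver.
- **Cone tracing of recurrences**: the recurrence on follow-up imaging is
  expressed as spherical-coordinate directions (θ, φ) from the ablation-zone
  centroid, mapped to the post-treatment frame through a vessel-focused rigid
  registration (Frangi vesselness inside spheres of interest, default radius
  75 mm), and intersected with the uncovered region — did the progression occur
  where the intended margin was missed?
- **A fully ground-truthed synthetic phantom generator** (liver, tumor,
  ablation cavity with 37% follow-up shrinkage, vessels, diffeomorphic
  deformation, rigid frame offset) so every stage is testable without patient
  data, plus the published 30-patient outcome table (14 with local tumor
  progression, 16 without) and its statistics (Mann–Whitney U, ROC AUC).

## Worked example

Run the whole workflow on a synthetic case:

```bash
ablamargin pipeline --phantom-seed 7 --out results/case7
```

which prints (stage log omitted):

```json
{
  "min_margin_mm": 2.0,
  "pct_gtv_outside": 0.0,
  "cc_gtv_outside": 0.0,
  "uncovered_region_cc": 1.09,
  "insufficient_vasculature": false,
  "used_manual_rigid": false,
  "cone_overlap": true,
  "cone_overlap_cc": 0.093
}
```

Reading: the mapped tumor is entirely inside the ablation zone (0% outside)
but the minimum delivered margin is only 2.0 mm — 1.09 cm³ of the intended
5 mm margin shell was not ablated — and the recurrence on the follow-up scan
points at exactly that region (`cone_overlap: true`, 0.093 cm³ of the
uncovered shell inside the recurrence cone). That is the signature finding
the workflow is built to surface. All intermediate artifacts (displacement
field, mapped GTV, uncovered-region mask, transforms) are written beside the
report as NIfTI/JSON.

The same stages are available individually (`ablamargin phantom`,
`register`, `margin`, `cone`, `stats`) and as library functions
(`ablamargin.biomech_register`, `ablamargin.min_margin`,
`ablamargin.cone_overlap`, ...).

Cohort statistics from the packaged outcome table:

```bash
$ ablamargin stats --json
{
  "pct_rigid_pooled_mean": 19.51,
  "pct_rigid_pooled_std": 28.26,
  "pct_deformed_pooled_mean": 1.39,
  "pct_deformed_pooled_std": 3.8,
  ...
  "auc_deformed": 0.87,
  "auc_rigid": 0.58,
  "mwu_p_deformed": 0.0005434317234923551
}
```

Deformable registration collapses the spurious tumor-outside-ablation volume
(19.5% → 1.4% on average), and the deformably-measured minimum margin
separates patients who later progressed from those who did not (AUC 0.87
vs 0.58 for rigid; two-sided Mann–Whitney p ≈ 5·10⁻⁴).

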