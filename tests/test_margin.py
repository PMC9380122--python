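"""Minimum-margin computation against brute-force and analytic oracles."""

import numpy as np
import pytest
from scipy import ndimage

from ablamargin.grid import Grid, LabelMask
from ablamargin.margin import (
    MarginParams,
    expand_outside_liver,
    gtv_outside_ablation,
    min_margin,
    surface_voxels,
    uncovered_margin_region,
)


def brute_force_min_margin(gtv: LabelMask, abl: LabelMask, liver: LabelMask,
                           expansion: float = 10.0) -> float:
    """Independent oracle: explicit min over (GTV surface voxel, adjusted
    ablation surface voxel) pairs, 0 for uncovered/boundary surface voxels."""
    g = gtv.grid
    adj = expand_outside_liver(abl, liver, expansion)
    gs = surface_voxels(gtv.data)
    asf = surface_voxels(adj.data)
    inside = adj.data & ~asf
    gp = g.voxel_to_world(np.argwhere(gs))
    ap = g.voxel_to_world(np.argwhere(asf))
    vals = []
    for p, iv in zip(gp, np.argwhere(gs)):
        if inside[tuple(iv)]:
            vals.append(np.sqrt(((ap - p) ** 2).sum(axis=1)).min())
        else:
            vals.append(0.0)
    return min(vals)


@pytest.fixture(scope="module")
def full_liver(sphere_masks_64):
    g = sphere_masks_64["grid"]
    return LabelMask(np.ones(g.shape, bool), g)


class TestExpandOutsideLiver:
    def test_interior_ablation_unchanged(self, sphere_masks_64, full_liver):
        abl = sphere_masks_64["ball"](9.0)
        out = expand_outside_liver(abl, full_liver, 10.0)
        assert np.array_equal(out.data, abl.data)

    def test_zero_expansion_identity(self, sphere_masks_64):
        g = sphere_masks_64["grid"]
        liver = LabelMask(g.coordinate_grid()[..., 2] <= 32.0, g)
        abl = sphere_masks_64["ball"](9.0, center=(32.0, 32.0, 28.0))
        out = expand_outside_liver(abl, liver, 0.0)
        assert np.array_equal(out.data, abl.data)

    def test_added_voxels_outside_liver_within_reach(self, sphere_masks_64):
        g = sphere_masks_64["grid"]
        pts = g.coordinate_grid()
        liver = LabelMask(pts[..., 2] <= 32.0, g)
        abl = sphere_masks_64["ball"](8.0, center=(32.0, 32.0, 30.0))
        out = expand_outside_liver(abl, liver, 10.0)
        added = out.data & ~abl.data
        assert added.any()
        assert not (added & liver.data).any()  # never inside the liver
        d_to_abl = ndimage.distance_transform_edt(~abl.data, sampling=g.spacing)
        assert d_to_abl[added].max() <= 10.0 + 1e-9

    def test_negative_expansion_rejected(self, sphere_masks_64, full_liver):
        with pytest.raises(ValueError):
            expand_outside_liver(sphere_masks_64["ball"](5.0), full_liver, -1.0)


class TestGtvOutsideAblation:
    def test_fully_covered(self, sphere_masks_64):
        pct, cc = gtv_outside_ablation(sphere_masks_64["ball"](5.0), sphere_masks_64["ball"](9.0))
        assert (pct, cc) == (0.0, 0.0)

    def test_disjoint(self, sphere_masks_64):
        gtv = sphere_masks_64["ball"](6.0, center=(16.0, 16.0, 16.0))
        abl = sphere_masks_64["ball"](6.0, center=(48.0, 48.0, 48.0))
        pct, cc = gtv_outside_ablation(gtv, abl)
        assert pct == 100.0
        assert cc == pytest.approx(gtv.volume_cc)

    def test_half_cube(self, sphere_masks_64):
        g = sphere_masks_64["grid"]
        pts = g.coordinate_grid()
        cube = LabelMask(np.all(np.abs(pts - 31.5) <= 9.5, axis=-1), g)  # 20x20x20
        half = LabelMask(cube.data & (pts[..., 0] <= 31.5), g)
        pct, cc = gtv_outside_ablation(cube, half)
        assert pct == pytest.approx(50.0, abs=1.0)
        assert cc == pytest.approx(4.0, abs=0.1)

    def test_empty_gtv_rejected(self, sphere_masks_64):
        g = sphere_masks_64["grid"]
        with pytest.raises(ValueError):
            gtv_outside_ablation(LabelMask(np.zeros(g.shape, bool), g), sphere_masks_64["ball"](5.0))


class TestMinMargin:
    def test_concentric_spheres_within_one_voxel(self, sphere_masks_64, full_liver):
        res = min_margin(sphere_masks_64["ball"](5.0), sphere_masks_64["ball"](9.0), full_liver)
        assert res.min_margin_mm == pytest.approx(4.0, abs=1.0)
        assert res.pct_gtv_outside == 0.0

    def test_poking_gtv_has_zero_margin(self, sphere_masks_64, full_liver):
        gtv = sphere_masks_64["ball"](5.0, center=(38.0, 32.0, 32.0))
        res = min_margin(gtv, sphere_masks_64["ball"](9.0), full_liver)
        assert res.min_margin_mm == 0.0
        assert res.pct_gtv_outside > 0.0

    def test_matches_brute_force_on_random_blobs(self, sphere_masks_64, full_liver):
        g = sphere_masks_64["grid"]
        rng = np.random.default_rng(13)
        blob = rng.random(g.shape) > 0.995
        gtv = LabelMask(
            ndimage.binary_dilation(blob, iterations=3)
            & (np.linalg.norm(g.coordinate_grid() - 32.0, axis=-1) < 12),
            g,
        )
        abl = sphere_masks_64["ball"](16.0)
        res = min_margin(gtv, abl, full_liver)
        oracle = brute_force_min_margin(gtv, abl, full_liver)
        diag = np.linalg.norm(g.spacing)
        assert abs(res.min_margin_mm - oracle) <= diag

    def test_subcapsular_expansion_matches_oracle(self, sphere_masks_64):
        """Tumor and cavity both touch the capsule: the raw margin is 0 at
        the capsule, but the extrahepatic expansion restores the in-liver
        (lateral) minimum; implementation must equal the brute-force oracle."""
        g = sphere_masks_64["grid"]
        pts = g.coordinate_grid()
        liver = LabelMask(pts[..., 2] <= 32.0, g)
        gtv = sphere_masks_64["ball"](3.0, center=(32.0, 32.0, 28.5))
        abl = sphere_masks_64["ball"](6.0, center=(32.0, 32.0, 27.0))
        res = min_margin(gtv, abl, liver)
        oracle = brute_force_min_margin(gtv, abl, liver)
        assert abs(res.min_margin_mm - oracle) <= np.linalg.norm(g.spacing)
        res0 = min_margin(gtv, abl, liver, MarginParams(extrahepatic_expansion=0.0))
        assert res0.min_margin_mm <= res.min_margin_mm  # expansion only helps

    def test_monotone_under_ablation_dilation(self, sphere_masks_64, full_liver):
        gtv = sphere_masks_64["ball"](5.0, center=(34.0, 32.0, 32.0))
        abl = sphere_masks_64["ball"](8.0).data
        prev_margin, prev_pct, prev_unc = -np.inf, np.inf, np.inf
        g = sphere_masks_64["grid"]
        for _ in range(3):
            res = min_margin(gtv, LabelMask(abl, g), full_liver)
            assert res.min_margin_mm >= prev_margin
            assert res.pct_gtv_outside <= prev_pct
            assert res.uncovered_region.n_voxels <= prev_unc
            prev_margin, prev_pct = res.min_margin_mm, res.pct_gtv_outside
            prev_unc = res.uncovered_region.n_voxels
            abl = ndimage.binary_dilation(abl, iterations=2)

    def test_pct_cc_consistency(self, sphere_masks_64, full_liver):
        gtv = sphere_masks_64["ball"](5.0, center=(38.0, 32.0, 32.0))
        res = min_margin(gtv, sphere_masks_64["ball"](9.0), full_liver)
        expect_cc = res.pct_gtv_outside * gtv.volume_cc / 100.0
        assert res.cc_gtv_outside == pytest.approx(expect_cc, abs=0.02)


class TestUncoveredRegion:
    def test_sufficient_margin_empty(self, sphere_masks_64, full_liver):
        unc = uncovered_margin_region(
            sphere_masks_64["ball"](5.0), sphere_masks_64["ball"](11.0), full_liver, 5.0
        )
        assert unc.n_voxels == 0

    def test_spherical_shell_volume(self):
        """GTV r=5 dilated by 5 minus ablation r=8 is the 8-10 mm shell; a
        0.25 mm grid keeps voxelization bias under the 5% tolerance."""
        sp = 0.25
        n = int(36 / sp)
        g = Grid((n, n, n), (sp, sp, sp))
        r = np.linalg.norm(g.coordinate_grid() - 18.0, axis=-1)
        liver = LabelMask(np.ones(g.shape, bool), g)
        unc = uncovered_margin_region(
            LabelMask(r <= 5.0, g), LabelMask(r <= 8.0, g), liver, 5.0
        )
        assert unc.volume_cc == pytest.approx(4 / 3 * np.pi * (10**3 - 8**3) / 1000, rel=0.05)

    def test_subcapsular_fully_covered_in_liver(self, sphere_masks_64):
        g = sphere_masks_64["grid"]
        pts = g.coordinate_grid()
        liver = LabelMask(pts[..., 2] <= 32.0, g)
        gtv = sphere_masks_64["ball"](3.0, center=(32.0, 32.0, 30.0))
        abl = sphere_masks_64["ball"](11.0, center=(32.0, 32.0, 28.0))
        unc = uncovered_margin_region(gtv, abl, liver, 5.0)
        assert unc.n_voxels == 0
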