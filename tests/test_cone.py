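"""Spherical-coordinate cone tracing of recurrences."""

import numpy as np
import pytest
from scipy import ndimage

from ablamargin.cone import DirectionSet, build_direction_set, cone_overlap, mask_centroid
from ablamargin.grid import Grid, LabelMask
from ablamargin.transforms import RigidTransform


@pytest.fixture(scope="module")
def grid80():
    g = Grid((80, 80, 80))
    pts = g.coordinate_grid()
    c = np.full(3, 40.0)
    d = pts - c
    r = np.linalg.norm(d, axis=-1)
    with np.errstate(invalid="ignore"):
        theta = np.degrees(np.arccos(np.clip(d[..., 2] / np.maximum(r, 1e-9), -1, 1)))
    return {"g": g, "c": c, "r": r, "theta": theta}


def single_voxel_mask(g: Grid, idx) -> LabelMask:
    m = np.zeros(g.shape, bool)
    m[idx] = True
    return LabelMask(m, g)


class TestCentroid:
    def test_two_voxel_midpoint(self):
        g = Grid((16, 16, 16))
        m = np.zeros(g.shape, bool)
        m[0, 0, 0] = m[10, 0, 0] = True
        assert np.allclose(mask_centroid(LabelMask(m, g)), [5.0, 0.0, 0.0])

    def test_random_blob_matches_direct_mean(self):
        g = Grid((20, 20, 20), (0.8, 0.8, 2.0))
        data = np.random.default_rng(17).random(g.shape) > 0.8
        m = LabelMask(data, g)
        direct = g.voxel_to_world(np.argwhere(data)).mean(axis=0)
        assert np.allclose(mask_centroid(m), direct, atol=1e-9)

    def test_empty_rejected(self):
        g = Grid((8, 8, 8))
        with pytest.raises(ValueError):
            mask_centroid(LabelMask(np.zeros(g.shape, bool), g))


class TestBuildDirectionSet:
    def test_pole_occupies_all_azimuths(self, grid80):
        g, c = grid80["g"], grid80["c"]
        ds = build_direction_set(c, single_voxel_mask(g, (40, 40, 50)), 2.0)
        assert ds.bins[0].all()  # +z pole: every phi at theta bin 0
        assert ds.bins[1:].sum() == 0

    def test_equatorial_axis_bin(self, grid80):
        g, c = grid80["g"], grid80["c"]
        ds = build_direction_set(c, single_voxel_mask(g, (50, 40, 40)), 2.0)
        it, ip = np.nonzero(ds.bins)
        assert list(it * 2.0) == [90.0]  # theta = 90 falls in the [90, 92) bin
        assert list(ip * 2.0 - 180.0) == [0.0]  # phi = 0

    def test_full_shell_occupies_everything(self, grid80):
        g, c, r = grid80["g"], grid80["c"], grid80["r"]
        shell = LabelMask((r >= 20) & (r <= 30), g)
        ds = build_direction_set(c, shell, 10.0)  # coarse bins -> dense coverage
        assert ds.bins.all()

    def test_centroid_coincident_voxel_skipped(self, grid80):
        g, c = grid80["g"], grid80["c"]
        m = np.zeros(g.shape, bool)
        m[40, 40, 40] = True  # exactly the centroid: direction undefined
        m[40, 40, 50] = True
        ds = build_direction_set(c, m_ := LabelMask(m, g), 2.0)
        assert ds.n_skipped == 1
        assert ds.bins[0].all()

    def test_empty_recurrence_rejected(self, grid80):
        g, c = grid80["g"], grid80["c"]
        with pytest.raises(ValueError):
            build_direction_set(c, LabelMask(np.zeros(g.shape, bool), g), 2.0)


class TestConeOverlap:
    def _cap(self, grid80, lo_cos, hi_cos=1.0):
        g, r, theta = grid80["g"], grid80["r"], grid80["theta"]
        cosz = np.cos(np.radians(theta))
        return LabelMask((r >= 12) & (r <= 18) & (cosz > lo_cos) & (cosz <= hi_cos), g)

    def test_aligned_cap_fully_covered(self, grid80):
        """Recurrence subtending the +z cap; the uncovered cap in the same
        directions is covered in full."""
        g, c, r, theta = grid80["g"], grid80["c"], grid80["r"], grid80["theta"]
        rec = LabelMask((r >= 20) & (r <= 26) & (theta <= 40), g)
        unc = self._cap(grid80, np.cos(np.radians(25)))  # theta <= 25 < 40
        ds = build_direction_set(c, rec, 2.0, dilation_deg=4.0)
        res = cone_overlap(ds, c, unc, RigidTransform.identity())
        assert res.overlap
        assert res.overlap_volume_cc == pytest.approx(unc.volume_cc, rel=0.02)

    def test_opposed_cap_no_overlap(self, grid80):
        g, c, r, theta = grid80["g"], grid80["c"], grid80["r"], grid80["theta"]
        rec = LabelMask((r >= 20) & (r <= 26) & (theta <= 40), g)
        unc = self._cap(grid80, -1.0, np.cos(np.radians(140)))  # theta >= 140
        ds = build_direction_set(c, rec, 2.0, dilation_deg=4.0)
        res = cone_overlap(ds, c, unc, RigidTransform.identity())
        assert not res.overlap
        assert res.overlap_volume_cc == 0.0

    def test_sector_volume_against_voxel_oracle(self, grid80):
        """Direction set covering theta <= 30 deg (all phi) intersected with a
        45 deg uncovered sector: the overlap equals the per-voxel angle test
        and the analytic solid-angle fraction within 5%."""
        g, c, r, theta = grid80["g"], grid80["c"], grid80["r"], grid80["theta"]
        unc = LabelMask((r >= 16) & (r <= 22) & (theta <= 45), g)
        bins = np.zeros((90, 180), bool)
        bins[:15] = True  # theta in [0, 30)
        ds = DirectionSet(bins, 2.0)
        res = cone_overlap(ds, c, unc, RigidTransform.identity())
        brute = (unc.data & (theta < 30.0)).sum() * g.voxel_volume_mm3 / 1000
        assert res.overlap_volume_cc == pytest.approx(brute, rel=0.01)
        frac = (1 - np.cos(np.radians(30))) / (1 - np.cos(np.radians(45)))
        assert res.overlap_volume_cc == pytest.approx(unc.volume_cc * frac, rel=0.05)

    def test_empty_uncovered_region_is_no_overlap(self, grid80):
        g, c = grid80["g"], grid80["c"]
        ds = build_direction_set(c, single_voxel_mask(g, (40, 40, 50)), 2.0)
        res = cone_overlap(ds, c, LabelMask(np.zeros(g.shape, bool), g))
        assert not res.overlap and res.overlap_volume_cc == 0.0

    def test_rigid_rotation_maps_directions(self, grid80):
        """Recurrence due +x in the follow-up frame; with a 90 deg z-rotation
        mapping post to follow-up, the post-frame direction that lands on the
        recurrence is -y (R(-y) = +x), while +x itself must miss."""
        g, c = grid80["g"], grid80["c"]
        rec = single_voxel_mask(g, (50, 40, 40))  # +x in follow-up frame
        ds = build_direction_set(c, rec, 2.0, dilation_deg=4.0)
        T = RigidTransform.from_params((0, 0, 90.0), (0, 0, 0), tuple(c))
        unc_neg_y = single_voxel_mask(g, (40, 30, 40))
        unc_x = single_voxel_mask(g, (50, 40, 40))
        assert cone_overlap(ds, c, unc_neg_y, T).overlap
        assert not cone_overlap(ds, c, unc_x, T).overlap

    def test_rotation_equivariance_within_bin_band(self, grid80):
        """Rotating recurrence and uncovered region together changes the
        overlap only within the one-bin-wide band at the cone's angular edge
        (recurrence placed far from the centroid so ray coverage is solid)."""
        g, c, r, theta = grid80["g"], grid80["c"], grid80["r"], grid80["theta"]
        pts = g.coordinate_grid()
        rec = LabelMask((r >= 20) & (r <= 26) & (theta <= 25), g)
        unc = LabelMask((r >= 16) & (r <= 22) & (theta <= 30), g)
        ds = build_direction_set(c, rec, 2.0, dilation_deg=4.0)
        base = cone_overlap(ds, c, unc, RigidTransform.identity())

        R = RigidTransform.from_params((30.0, 0, 0), (0, 0, 0), tuple(c))

        def rotated(m):
            idx = g.world_to_voxel(R.inverse().apply(pts.reshape(-1, 3)))
            v = ndimage.map_coordinates(m.data.astype(np.float32), idx.T, order=1) >= 0.5
            return LabelMask(v.reshape(g.shape), g)

        rec_r, unc_r = rotated(rec), rotated(unc)
        ds_r = build_direction_set(c, rec_r, 2.0, dilation_deg=4.0)
        got = cone_overlap(ds_r, c, unc_r, RigidTransform.identity())
        # tolerance: uncovered voxels within one bin width of the 25 deg cone
        # edge, plus whatever the mask resampling itself changed
        band = (unc.data & (np.abs(theta - 25.0) <= 2.0)).sum() * g.voxel_volume_mm3 / 1000
        dv = abs(unc_r.volume_cc - unc.volume_cc)
        assert abs(got.overlap_volume_cc - base.overlap_volume_cc) <= band + dv + 0.05

    def test_angular_dilation_monotone(self, grid80):
        g, c, r, theta = grid80["g"], grid80["c"], grid80["r"], grid80["theta"]
        rec = LabelMask((r >= 8) & (r <= 14) & (theta <= 30), g)
        unc = LabelMask((r >= 16) & (r <= 22) & (theta <= 45), g)
        prev = -1.0
        for dil in (0.0, 2.0, 4.0, 8.0):
            ds = build_direction_set(c, rec, 2.0, dilation_deg=dil)
            v = cone_overlap(ds, c, unc, RigidTransform.identity()).overlap_volume_cc
            assert v >= prev
            prev = v

    def test_bin_refinement_stability(self, grid80):
        """Halving the bin width changes the overlap volume by <= 10% on a
        smooth cap construction (with the voxel footprint filled by dilation)."""
        g, c, r, theta = grid80["g"], grid80["c"], grid80["r"], grid80["theta"]
        rec = LabelMask((r >= 6) & (r <= 12) & (theta <= 40), g)
        unc = LabelMask((r >= 16) & (r <= 22) & (theta <= 30), g)
        vols = {}
        for bin_deg in (2.0, 1.0):
            ds = build_direction_set(c, rec, bin_deg, dilation_deg=4.0)
            vols[bin_deg] = cone_overlap(ds, c, unc, RigidTransform.identity()).overlap_volume_cc
        assert vols[1.0] == pytest.approx(vols[2.0], rel=0.10)
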