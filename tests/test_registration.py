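"""Rigid fit, thin-plate-spline warp and sector transfer."""

import numpy as np
import pytest

from iplconcord import (RigidTransform2D, build_sector_map, fit_deformation,
                        fit_rigid, transfer_sectors)
from iplconcord.registration import DeformationWarp, angle_sorted_outline
from iplconcord.volumes import Region


def _circle(n=64, r=20.0, center=(0.0, 0.0)):
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return np.column_stack([center[0] + r * np.cos(t), center[1] + r * np.sin(t)])


def _blob(rng, n=64, r=20.0):
    """Smooth prostate-like outline: circle plus low-order harmonics."""
    t = np.linspace(0, 2 * np.pi, n, endpoint=False)
    rr = r * (1.0 + 0.08 * rng.standard_normal() * np.cos(2 * t + rng.uniform(0, np.pi))
              + 0.05 * rng.standard_normal() * np.cos(3 * t + rng.uniform(0, np.pi)))
    return np.column_stack([rr * np.cos(t), rr * np.sin(t)])


class TestRigidFit:
    def test_translation_recovered_exactly(self):
        src = _blob(np.random.default_rng(0))
        rigid = fit_rigid(src, src + (5.0, -3.0))
        assert rigid.tx == pytest.approx(5.0, abs=1e-6)
        assert rigid.ty == pytest.approx(-3.0, abs=1e-6)
        assert rigid.theta == pytest.approx(0.0, abs=1e-6)

    def test_rotation_about_centroid_recovered(self):
        src = _blob(np.random.default_rng(1))
        ang = np.deg2rad(30.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        c = src.mean(axis=0)
        tgt = (src - c) @ R.T + c
        rigid = fit_rigid(src, tgt)
        assert rigid.theta == pytest.approx(ang, abs=1e-6)

    def test_scale_recovered(self):
        src = _blob(np.random.default_rng(2))
        rigid = fit_rigid(src, 1.3 * src, with_scale=True)
        assert rigid.scale == pytest.approx(1.3, abs=1e-6)

    def test_noisy_correspondence_unbiased(self):
        """50-seed Monte Carlo: parameter bias < 0.1 mm / 0.5 deg."""
        true_t, true_ang = np.array([4.0, -2.0]), np.deg2rad(12.0)
        R = np.array([[np.cos(true_ang), -np.sin(true_ang)],
                      [np.sin(true_ang), np.cos(true_ang)]])
        errs_t, errs_a = [], []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            src = _blob(rng, n=100)
            tgt = src @ R.T + true_t + rng.normal(0, 0.5, src.shape)
            rigid = fit_rigid(src, tgt, assume_matched=True)
            errs_t.append([rigid.tx - true_t[0], rigid.ty - true_t[1]])
            errs_a.append(rigid.theta - true_ang)
        assert np.abs(np.mean(errs_t, axis=0)).max() < 0.1
        assert abs(np.degrees(np.mean(errs_a))) < 0.5

    def test_rotation_equivariance(self):
        src = _blob(np.random.default_rng(3))
        tgt = _blob(np.random.default_rng(4))
        base = fit_rigid(src, tgt)
        ang = np.deg2rad(25.0)
        R = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        rot = fit_rigid(src @ R.T, tgt @ R.T)
        delta = (rot.theta - base.theta + np.pi) % (2 * np.pi) - np.pi
        assert delta == pytest.approx(0.0, abs=1e-6)

    def test_collinear_points_rejected(self):
        line = np.column_stack([np.arange(10.0), 2.0 * np.arange(10.0)])
        with pytest.raises(ValueError, match="collinear"):
            fit_rigid(line, line + 1.0)

    def test_inverse_composes_to_identity(self):
        rigid = RigidTransform2D(tx=3.0, ty=-7.0, theta=0.6, scale=1.2)
        pts = _blob(np.random.default_rng(5))
        back = rigid.inverse().apply(rigid.apply(pts))
        assert np.abs(back - pts).max() < 1e-9


class TestDeformation:
    def test_identity_when_outlines_coincide(self):
        c = _circle()
        warp = fit_deformation(c, c, n_control_points=16)
        disp = warp.apply(c) - c
        assert np.abs(disp).max() < 1e-9

    def test_interpolates_control_points_exactly(self):
        rng = np.random.default_rng(7)
        warp = fit_deformation(_blob(rng), _blob(rng), n_control_points=16)
        assert warp.control_point_residual() < 1e-9

    def test_circle_to_ellipse(self):
        import shapely
        from shapely.geometry import Polygon

        circle = _circle(n=128, r=10.0)
        ellipse = circle * np.array([1.2, 0.8])
        warp = fit_deformation(circle, ellipse, n_control_points=16)
        warped = warp.apply(circle)
        boundary = Polygon(_circle(n=720, r=10.0) * np.array([1.2, 0.8])).exterior
        d = [boundary.distance(shapely.points(p)) for p in warped]
        assert np.mean(d) < 0.2

    def test_warp_dominates_rigid_alone(self):
        """Post-warp boundary residual <= rigid-only residual, 100 shapes."""
        from shapely.geometry import Polygon

        for seed in range(100):
            rng = np.random.default_rng(seed)
            src = angle_sorted_outline(_blob(rng), 48)
            tgt = angle_sorted_outline(_blob(rng) + rng.normal(0, 2, 2), 48)
            rigid = fit_rigid(src, tgt, assume_matched=True)
            aligned = rigid.apply(src)
            warp = fit_deformation(aligned, tgt, n_control_points=16)
            boundary = Polygon(tgt).exterior
            d_rigid = np.mean([boundary.distance(__import__('shapely').points(p))
                               for p in aligned])
            d_warp = np.mean([boundary.distance(__import__('shapely').points(p))
                              for p in warp.apply(aligned)])
            assert d_warp <= d_rigid + 1e-9

    def test_self_intersecting_outline_rejected(self):
        bow = np.array([[0, 0], [10, 10], [10, 0], [0, 10]], float)
        with pytest.raises(ValueError, match="self-intersecting"):
            fit_deformation(bow, _circle())


class TestTransfer:
    def test_identity_transfer_reproduces_polygons(self, anatomy, sector_map):
        """Near-identity mapping assigns voxels consistently per region."""
        rigid = RigidTransform2D(tx=0, ty=0, theta=0.0)
        c = _circle(n=48, r=25.0)
        warp = DeformationWarp(c, c)
        k = int(anatomy.region_slab_slices(Region.MID)[1])
        # schematic coordinates == patient mm coordinates shifted to centroid
        ii, jj = np.nonzero(anatomy.prostate_mask[:, :, k])
        cx, cy = ii.mean() * anatomy.spacing[0], jj.mean() * anatomy.spacing[1]
        shifted = RigidTransform2D(tx=cx, ty=cy, theta=0.0)
        out = transfer_sectors(sector_map, Region.MID, warp, shifted, anatomy, k)
        assert ((out > 0) == anatomy.prostate_mask[:, :, k]).all()
        uids = set(np.unique(out)) - {0}
        assert uids <= {s.uid for s in sector_map.sectors if s.region == Region.MID}

    def test_pure_translation_moves_boundaries_rigidly(self, anatomy, sector_map):
        k = int(anatomy.region_slab_slices(Region.MID)[1])
        ii, jj = np.nonzero(anatomy.prostate_mask[:, :, k])
        cx, cy = ii.mean() * anatomy.spacing[0], jj.mean() * anatomy.spacing[1]
        c = _circle(n=48, r=25.0)
        warp = DeformationWarp(c, c)
        base = transfer_sectors(sector_map, Region.MID, warp,
                                RigidTransform2D(cx, cy, 0.0), anatomy, k)
        dx_vox = 2  # shift by an integer number of voxels
        shifted = transfer_sectors(
            sector_map, Region.MID, warp,
            RigidTransform2D(cx + dx_vox * anatomy.spacing[0], cy, 0.0), anatomy, k)
        ov = (base[:-dx_vox] > 0) & (shifted[dx_vox:] > 0)
        agree = (base[:-dx_vox][ov] == shifted[dx_vox:][ov]).mean()
        assert agree > 0.95

    def test_random_warps_cover_all_prostate_voxels(self, anatomy, sector_map):
        from iplconcord.pipeline import register_case
        from iplconcord.phantom import CohortSpec, generate_case

        for seed in (0, 1, 2):
            case = generate_case(CohortSpec(n_patients=3, seed=seed), seed)
            smap = build_sector_map(case.anatomy)
            reg = register_case(case, smap)
            assert ((reg > 0) == case.anatomy.prostate_mask).all()

    def test_wrong_region_slice_rejected(self, anatomy, sector_map):
        c = _circle(n=48, r=25.0)
        warp = DeformationWarp(c, c)
        k_base = int(anatomy.region_slab_slices(Region.BASE)[0])
        with pytest.raises(ValueError):
            transfer_sectors(sector_map, Region.APEX, warp,
                             RigidTransform2D(0, 0, 0.0), anatomy, k_base)
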