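"""Sector schematic and biopsy simulation: partition, detection, round trip."""

import numpy as np
import pandas as pd
import pytest

from iplconcord import BiopsyScheme, build_sector_map, generate_case, simulate_biopsy
from iplconcord.phantom import GroundTruthLesion, build_anatomy
from iplconcord.sectors import _core_traversal, _systematic_core_positions
from iplconcord.volumes import ProstateAnatomy, Region, Zone


class TestSectorGeometry:
    def test_36_sectors_12_per_region(self, sector_map):
        assert len(sector_map.sectors) == 36
        for region in Region:
            assert sum(s.region == region for s in sector_map.sectors) == 12

    def test_sector_uids_bijective(self, sector_map):
        assert sorted(s.uid for s in sector_map.sectors) == list(range(1, 37))

    def test_voxel_partition_of_prostate(self, anatomy, sector_map):
        assert ((sector_map.assignment > 0) == anatomy.prostate_mask).all()
        total = sum(int(sector_map.voxels_of(u).sum()) for u in range(1, 37))
        assert total == int(anatomy.prostate_mask.sum())

    def test_left_right_symmetry(self, anatomy, sector_map):
        # the phantom prostate is mirror-symmetric in x; so must be the split
        left = sum(sector_map.voxels_of(s.uid).sum()
                   for s in sector_map.sectors if s.side == "left")
        right = sum(sector_map.voxels_of(s.uid).sum()
                    for s in sector_map.sectors if s.side == "right")
        assert abs(left - right) / (left + right) < 0.01

    def test_schematic_polygons_tile_disc(self, sector_map):
        import shapely.ops

        for region in Region:
            polys = [s.polygon for s in sector_map.sectors if s.region == region]
            union = shapely.ops.unary_union(polys)
            disc_area = np.pi * 25.0 ** 2
            assert union.area == pytest.approx(disc_area, rel=0.01)
            pair_overlap = sum(p.intersection(q).area
                               for i, p in enumerate(polys) for q in polys[i + 1:])
            assert pair_overlap < 1e-6 * disc_area

    def test_degenerate_anatomy_rejected(self):
        a = build_anatomy((48, 48, 26), (2.0, 2.0, 3.0), 31.0)
        squashed = ProstateAnatomy(a.prostate_mask, a.region_labels,
                                   a.zone_labels, a.spacing)
        squashed.region_labels = np.where(a.region_labels == int(Region.APEX),
                                          int(Region.MID), a.region_labels)
        with pytest.raises(ValueError, match="APEX"):
            build_sector_map(squashed)


def _single_sector_lesion(anatomy, sector_map, uid):
    mask = sector_map.voxels_of(uid)
    ii, jj, kk = np.nonzero(mask)
    center = np.array([ii.mean() * anatomy.spacing[0],
                       jj.mean() * anatomy.spacing[1],
                       kk.mean() * anatomy.spacing[2]])
    return GroundTruthLesion(
        id=0, center_mm=center, semi_axes_mm=np.ones(3), mask=mask,
        relative_volume_fraction=mask.sum() / anatomy.prostate_mask.sum(),
        gleason_score="7b", assigned_suvmax=8.0,
        region=Region((uid - 1) // 12 + 1), zone=Zone.PERIPHERAL)


class TestBiopsy:
    def test_certain_detection_hits_exactly_the_lesion_sector(self, anatomy, sector_map):
        # lesion occupying exactly one sector + a targeted core through it
        uid = 17  # a mid-region sector
        les = _single_sector_lesion(anatomy, sector_map, uid)
        scheme = BiopsyScheme(detection_scale_mm=None)
        lab = simulate_biopsy(anatomy, [les], scheme, sector_map,
                              targeted_lesions=[les], seed=0)
        assert lab.positive_uids == {uid}
        assert lab.sector(uid).gleason_score == "7b"

    def test_zero_detection_probability_all_negative(self, anatomy, sector_map):
        uid = 17
        les = _single_sector_lesion(anatomy, sector_map, uid)
        scheme = BiopsyScheme(detection_scale_mm=np.inf)
        lab = simulate_biopsy(anatomy, [les], scheme, sector_map,
                              targeted_lesions=[les], seed=0)
        assert lab.positive_uids == set()
        assert len(lab.sampled_uids) > 0

    def test_unsampled_sectors_exist_and_are_labelled(self, anatomy, sector_map):
        les = _single_sector_lesion(anatomy, sector_map, 17)
        lab = simulate_biopsy(anatomy, [les], BiopsyScheme(), sector_map,
                              targeted_lesions=[], seed=3)
        statuses = {s.biopsy_status for s in lab.sectors}
        assert statuses <= {"positive", "negative", "unsampled"}
        assert any(s.biopsy_status == "unsampled" for s in lab.sectors)

    def test_positivity_rate_matches_closed_form(self, anatomy, sector_map):
        """Monte-Carlo per-lesion detection vs 1 - prod(1 - p_core)."""
        les = _single_sector_lesion(anatomy, sector_map, 17)
        scheme = BiopsyScheme(detection_scale_mm=3.0, targeted=False)
        # independent expected probability from an explicit needle march
        p_miss = 1.0
        for x_mm, z_mm in _systematic_core_positions(anatomy, scheme):
            i = int(round(x_mm / anatomy.spacing[0]))
            k = int(round(z_mm / anatomy.spacing[2]))
            step = scheme.core_step_mm
            y = np.arange(0.0, anatomy.prostate_mask.shape[1] * anatomy.spacing[1], step)
            j = np.clip(np.round(y / anatomy.spacing[1]).astype(int), 0,
                        anatomy.prostate_mask.shape[1] - 1)
            path = les.mask[i, j, k].sum() * step
            p_miss *= np.exp(-path / scheme.detection_scale_mm) if path > 0 else 1.0
        p_expected = 1.0 - p_miss
        n = 1000
        hits = sum(bool(simulate_biopsy(anatomy, [les], scheme, sector_map,
                                        seed=s).positive_uids)
                   for s in range(n))
        se = np.sqrt(max(p_expected * (1 - p_expected), 1e-6) / n)
        assert abs(hits / n - p_expected) <= 3 * se + 1e-9

    def test_targeted_cores_never_reduce_detection(self, small_spec):
        """Stochastic dominance of systematic+targeted over systematic alone."""
        case = generate_case(small_spec, 0)
        smap = build_sector_map(case.anatomy)
        lesions = case.lesions
        scheme = BiopsyScheme(detection_scale_mm=6.0)

        def n_detected(targeted, seed):
            lab = simulate_biopsy(case.anatomy, lesions, scheme, smap,
                                  targeted_lesions=lesions if targeted else [],
                                  seed=seed)
            pos = lab.positive_uids
            return sum(bool({int(u) for u in
                             np.unique(smap.assignment[l.mask]) if u > 0} & pos)
                       for l in lesions)

        with_t = [n_detected(True, s) for s in range(200)]
        without = [n_detected(False, s) for s in range(200)]
        assert np.mean(with_t) >= np.mean(without)

    def test_core_count_guideline_bounds(self):
        with pytest.raises(ValueError):
            BiopsyScheme(n_systematic_cores=6)
        for n in (10, 11, 12):
            BiopsyScheme(n_systematic_cores=n)


class TestSerialization:
    def test_csv_round_trip_lossless(self, anatomy, sector_map, tmp_path):
        les = _single_sector_lesion(anatomy, sector_map, 17)
        lab = simulate_biopsy(anatomy, [les], BiopsyScheme(detection_scale_mm=None),
                              sector_map, targeted_lesions=[les], seed=0)
        path = tmp_path / "sectors.csv"
        lab.to_csv(path)
        back = lab.with_labels_from(pd.read_csv(path, keep_default_na=False))
        for a, b in zip(lab.sectors, back.sectors):
            assert (a.uid, a.biopsy_status, a.gleason_score) == \
                   (b.uid, b.biopsy_status, b.gleason_score)

    def test_geojson_has_36_features(self, sector_map):
        gj = sector_map.schematic_geojson()
        assert len(gj["features"]) == 36
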