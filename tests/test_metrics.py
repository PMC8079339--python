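"""Sector-level scoring: confusion oracle, aggregation, threshold selection."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from iplconcord import (ConfusionCounts, aggregate, best_threshold, score,
                        score_sets, sectorize_contour)
from iplconcord.metrics import records_to_frame
from iplconcord.reference import (TRACER_F18_CT, TRACER_GA68_CT,
                                  manual_method_rows, per_threshold_rows)


def brute_force_metrics(predicted: set, positive: set, universe: set):
    """Independent elementwise oracle for DSC/YI/sensitivity/specificity."""
    tp = fp = fn = tn = 0
    for s in universe:
        p, q = s in predicted, s in positive
        tp += p and q
        fp += p and not q
        fn += q and not p
        tn += (not p) and (not q)
    dsc = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    return dsc, sens, spec, sens + spec - 1


class TestConfusionFormulas:
    def test_worked_example(self):
        c = ConfusionCounts(tp=3, fp=1, fn=2, tn=30)
        assert c.dice == pytest.approx(6 / 9)
        assert c.sensitivity == pytest.approx(0.600)
        assert c.specificity == pytest.approx(30 / 31)
        assert c.youden == pytest.approx(0.600 + 30 / 31 - 1)

    def test_perfect_and_disjoint_cases(self):
        perfect = score_sets({1, 2, 3}, {1, 2, 3}, set(range(1, 37)))
        assert perfect.dice == 1.0 and perfect.youden == 1.0
        disjoint = score_sets({1, 2}, {3, 4}, set(range(1, 37)))
        assert disjoint.dice == 0.0 and disjoint.sensitivity == 0.0

    def test_youden_identity(self):
        c = ConfusionCounts(tp=5, fp=2, fn=3, tn=20)
        assert abs(c.youden - (c.sensitivity + c.specificity - 1)) < 1e-12

    def test_exhaustive_small_confusion_tables_match_brute_force(self):
        """All (TP,FP,FN,TN) with total <= 20 vs an elementwise oracle."""
        for tp, fp, fn in itertools.product(range(8), repeat=3):
            for tn in range(0, 21 - tp - fp - fn):
                universe = set(range(tp + fp + fn + tn))
                items = sorted(universe)
                positive = set(items[:tp + fn])
                predicted = set(items[:tp]) | set(items[tp + fn:tp + fn + fp])
                counts = score_sets(predicted, positive, universe)
                assert (counts.tp, counts.fp, counts.fn, counts.tn) == \
                       (tp, fp, fn, tn)
                dsc, sens, spec, yi = brute_force_metrics(predicted, positive,
                                                          universe)
                for ours, ref in [(counts.dice, dsc), (counts.sensitivity, sens),
                                  (counts.specificity, spec), (counts.youden, yi)]:
                    if math.isnan(ref):
                        assert math.isnan(ours)
                    else:
                        assert abs(ours - ref) < 1e-12


class TestSectorize:
    def test_contour_filling_one_sector(self, anatomy, sector_map):
        mask = sector_map.voxels_of(17)
        pred = sectorize_contour(mask, sector_map.assignment, anatomy.spacing,
                                 margin_mm=0.0)
        assert pred == {17}

    def test_empty_contour(self, anatomy, sector_map):
        empty = np.zeros_like(sector_map.assignment, bool)
        assert sectorize_contour(empty, sector_map.assignment,
                                 anatomy.spacing) == set()

    def test_overlap_fraction_threshold_semantics(self, anatomy, sector_map):
        sector_vox = sector_map.voxels_of(17)
        ii, jj, kk = np.nonzero(sector_vox)
        half = np.zeros_like(sector_vox)
        keep = len(ii) // 2
        half[ii[:keep], jj[:keep], kk[:keep]] = True
        pred = sectorize_contour(half, sector_map.assignment, anatomy.spacing,
                                 margin_mm=0.0, overlap_fraction=0.6)
        assert 17 not in pred
        pred0 = sectorize_contour(half, sector_map.assignment, anatomy.spacing,
                                  margin_mm=0.0)
        assert 17 in pred0

    def test_margin_grows_prediction(self, anatomy, sector_map):
        mask = sector_map.voxels_of(17)
        p0 = sectorize_contour(mask, sector_map.assignment, anatomy.spacing, 0.0)
        p5 = sectorize_contour(mask, sector_map.assignment, anatomy.spacing, 5.0)
        assert p0 <= p5 and len(p5) > len(p0)


class TestScore:
    def _labelled(self, sector_map, positives):
        from dataclasses import replace

        sectors = [replace(s, biopsy_status="positive", gleason_score="7a")
                   if s.uid in positives else replace(s, biopsy_status="negative")
                   for s in sector_map.sectors]
        return replace(sector_map, sectors=sectors)

    def test_no_positive_sectors_flags_undefined_sensitivity(self, sector_map):
        lab = self._labelled(sector_map, set())
        rec = score({1, 2}, lab)
        assert "no_positive_sectors" in rec.flags
        assert math.isnan(rec.sensitivity)

    def test_counts_over_36_sectors(self, sector_map):
        lab = self._labelled(sector_map, {1, 2, 3})
        rec = score({2, 3, 4}, lab)
        assert (rec.counts.tp, rec.counts.fp, rec.counts.fn, rec.counts.tn) == \
               (2, 1, 1, 32)
        assert rec.counts.total == 36


class TestAggregate:
    def _rec(self, dsc_pair, method="m", case=0):
        # build counts giving the wanted DSC via tp/fp with fn=0
        tp, fp = dsc_pair
        from iplconcord import MetricsRecord
        return MetricsRecord(case_id=case, lesion_id=0, method=method,
                             counts=ConfusionCounts(tp=tp, fp=fp, fn=0, tn=10))

    def test_single_record_flagged(self):
        recs = [self._rec((1, 0))]
        out = aggregate(recs)
        assert out.loc[0, "n"] == 1 and out.loc[0, "dsc_sd"] == 0.0
        assert out.loc[0, "flag"] == "n=1"

    def test_two_values_hand_arithmetic(self):
        # DSC 0.4 = 2*1/(2*1+3), DSC 0.8 = 2*2/(2*2+1)
        recs = [self._rec((1, 3)), self._rec((2, 1))]
        out = aggregate(recs)
        assert out.loc[0, "dsc_mean"] == pytest.approx(0.6)
        assert out.loc[0, "dsc_sd"] == pytest.approx(0.28284271, abs=1e-6)

    def test_permutation_invariant(self):
        recs = [self._rec((1, 3)), self._rec((2, 1)), self._rec((5, 2))]
        a = aggregate(recs)
        b = aggregate(list(reversed(recs)))
        pd.testing.assert_frame_equal(a, b)

    def test_nan_excluded_pairwise(self):
        from iplconcord import MetricsRecord
        recs = [self._rec((1, 0)),
                MetricsRecord(case_id=1, lesion_id=0, method="m",
                              counts=ConfusionCounts(tp=0, fp=2, fn=0, tn=10))]
        out = aggregate(recs)
        assert out.loc[0, "n_sensitivity"] == 1  # second record has no positives


class TestBestThreshold:
    def test_published_rows_select_70_percent(self):
        for method in (TRACER_GA68_CT, TRACER_F18_CT):
            rows = per_threshold_rows(method)
            frac = rows[rows["kind"] == "frac"]
            best, info = best_threshold(frac)
            assert best == 0.7
            assert not info["discordant"]

    def test_strictly_increasing_returns_last(self):
        df = pd.DataFrame({"threshold": [0.4, 0.5, 0.6],
                           "dsc_mean": [0.1, 0.2, 0.3],
                           "yi_mean": [0.1, 0.2, 0.3],
                           "specificity_mean": [0.5, 0.6, 0.7]})
        best, _ = best_threshold(df)
        assert best == 0.6

    def test_tie_broken_by_yi_then_specificity(self):
        df = pd.DataFrame({"threshold": [0.4, 0.5],
                           "dsc_mean": [0.5, 0.5],
                           "yi_mean": [0.2, 0.3],
                           "specificity_mean": [0.9, 0.8]})
        best, info = best_threshold(df)
        assert best == 0.5 and info["tie"]

    def test_discordance_flagged(self):
        df = pd.DataFrame({"threshold": [0.4, 0.5],
                           "dsc_mean": [0.6, 0.5],
                           "yi_mean": [0.2, 0.3],
                           "specificity_mean": [0.9, 0.8]})
        best, info = best_threshold(df)
        assert best == 0.4 and info["discordant"]

    def test_manual_specificity_ranking(self):
        rows = manual_method_rows()
        top = rows.loc[rows["specificity_mean"].idxmax()]
        assert top["method"] == "68Ga-PSMA-PET/MRI_man"
        assert top["specificity_mean"] == 97
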