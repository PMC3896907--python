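from collections import deque

import numpy as np
import pytest

from nightglow.change import (
    CLASS_DECREASE,
    CLASS_INCREASE,
    CLASS_MASKED,
    CLASS_NODATA,
    CLASS_NONE,
    ChangeDetector,
    ChangeParams,
    classify_change,
    epoch_mean,
    extract_patches,
    saturation_mask,
    summarize_region,
)
from nightglow.composites import RegionMask
from nightglow.errors import ValidationError

from conftest import make_composite


def series_of(grids, years, calibrated=True):
    return [
        make_composite(np.asarray(g, dtype=float if calibrated else np.int16),
                       year=y, calibrated=calibrated)
        for g, y in zip(grids, years)
    ]


def flood_fill_count(binary, connectivity=8):
    """Independent BFS flood-fill enumeration of connected components."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    if connectivity == 8:
        nbrs = [(a, b) for a in (-1, 0, 1) for b in (-1, 0, 1) if (a, b) != (0, 0)]
    else:
        nbrs = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    count = 0
    for r0, c0 in zip(*np.nonzero(binary)):
        if seen[r0, c0]:
            continue
        count += 1
        q = deque([(r0, c0)])
        seen[r0, c0] = True
        while q:
            r, c = q.popleft()
            for a, b in nbrs:
                rr, cc = r + a, c + b
                if (0 <= rr < binary.shape[0] and 0 <= cc < binary.shape[1]
                        and binary[rr, cc] and not seen[rr, cc]):
                    seen[rr, cc] = True
                    q.append((rr, cc))
    return count


class TestEpochMean:
    def test_constant_pixel(self):
        series = series_of([np.full((4, 4), 12.0)] * 3, [2005, 2006, 2007])
        np.testing.assert_allclose(epoch_mean(series, (2005, 2006, 2007)), 12.0)

    def test_arithmetic(self):
        vals = [10, 20, 30, 40, 50, 60]
        series = series_of([np.full((2, 2), float(v)) for v in vals], range(1995, 2001))
        np.testing.assert_allclose(epoch_mean(series, tuple(range(1995, 2001))), 35.0)

    def test_matches_per_pixel_loop(self, rng):
        grids = rng.uniform(0, 63, (5, 16, 16))
        series = series_of(grids, range(2000, 2005))
        mean = epoch_mean(series, tuple(range(2000, 2005)))
        for i in range(16):
            for j in range(16):
                assert mean[i, j] == pytest.approx(sum(g[i, j] for g in grids) / 5)

    def test_nodata_propagates(self):
        nod = np.zeros((4, 4), dtype=bool)
        nod[1, 1] = True
        series = [
            make_composite(np.full((4, 4), 5.0), year=2005, calibrated=True, nodata=nod),
            make_composite(np.full((4, 4), 7.0), year=2006, calibrated=True),
        ]
        mean = epoch_mean(series, (2005, 2006))
        assert np.isnan(mean[1, 1]) and mean[0, 0] == 6.0

    def test_missing_year_rejected(self):
        series = series_of([np.zeros((2, 2))], [2005])
        with pytest.raises(ValidationError):
            epoch_mean(series, (2005, 2006))


class TestSaturationMask:
    def params(self):
        return ChangeParams(epoch1=(1995, 1996), epoch2=(2005, 2006))

    def _series(self, pixel_by_year):
        grids = []
        for y in (1995, 1996, 2005, 2006):
            g = np.zeros((2, 2))
            g[0, 0] = pixel_by_year[y]
            grids.append(g)
        return series_of(grids, (1995, 1996, 2005, 2006))

    def test_saturated_throughout_is_masked(self):
        series = self._series({1995: 63, 1996: 63, 2005: 63, 2006: 63})
        assert saturation_mask(series, self.params())[0, 0]

    def test_one_unsaturated_year_unmasks(self):
        series = self._series({1995: 63, 1996: 60, 2005: 63, 2006: 63})
        assert not saturation_mask(series, self.params())[0, 0]

    def test_dark_pixel_not_masked(self):
        series = self._series({1995: 0, 1996: 0, 2005: 0, 2006: 0})
        assert not saturation_mask(series, self.params())[0, 0]


class TestClassify:
    def test_strict_threshold_rules(self):
        diff = np.array([[3.5, 3.0], [-7.0, -3.0]])
        sat = np.zeros((2, 2), dtype=bool)
        cmap = classify_change(diff, sat, 3.0)
        assert cmap.classes[0, 0] == CLASS_INCREASE  # diff > +3
        assert cmap.classes[0, 1] == CLASS_NONE      # exactly +3: no change
        assert cmap.classes[1, 0] == CLASS_DECREASE  # diff < −3
        assert cmap.classes[1, 1] == CLASS_NONE      # exactly −3: no change

    def test_mask_precedence_over_threshold(self):
        diff = np.full((2, 2), -7.0)
        sat = np.zeros((2, 2), dtype=bool)
        sat[0, 0] = True
        cmap = classify_change(diff, sat, 3.0)
        assert cmap.classes[0, 0] == CLASS_MASKED
        assert cmap.classes[1, 1] == CLASS_DECREASE

    def test_nodata_precedence(self):
        diff = np.array([[np.nan, 10.0]])
        cmap = classify_change(diff, np.array([[True, False]]), 3.0)
        assert cmap.classes[0, 0] == CLASS_NODATA
        assert cmap.classes[0, 1] == CLASS_INCREASE


class TestPatches:
    def _map_from_classes(self, classes):
        classes = np.asarray(classes, dtype=np.uint8)
        diff = np.zeros(classes.shape)
        diff[classes == CLASS_INCREASE] = 5.0
        diff[classes == CLASS_DECREASE] = -5.0
        from nightglow.change import ChangeMap

        return ChangeMap(diff, np.zeros(classes.shape, bool), classes, 3.0)

    def test_single_pixel_patch(self):
        classes = np.zeros((5, 5))
        classes[2, 2] = CLASS_INCREASE
        patches = extract_patches(self._map_from_classes(classes))
        assert len(patches) == 1 and patches[0].area_px == 1
        assert patches[0].change_class == "increase"

    def test_diagonal_connectivity(self):
        classes = np.zeros((5, 5))
        classes[1, 1] = classes[2, 2] = CLASS_INCREASE
        assert len(extract_patches(self._map_from_classes(classes), connectivity=8)) == 1
        assert len(extract_patches(self._map_from_classes(classes), connectivity=4)) == 2

    @pytest.mark.parametrize("connectivity", [4, 8])
    def test_patch_count_matches_flood_fill(self, rng, connectivity):
        classes = rng.choice(
            [CLASS_NONE, CLASS_INCREASE, CLASS_DECREASE], (32, 32), p=[0.6, 0.2, 0.2]
        )
        patches = extract_patches(self._map_from_classes(classes), connectivity)
        expected = flood_fill_count(classes == CLASS_INCREASE, connectivity) + flood_fill_count(
            classes == CLASS_DECREASE, connectivity
        )
        assert len(patches) == expected

    def test_patch_areas_sum_to_class_counts(self, rng):
        classes = rng.choice(
            [CLASS_NONE, CLASS_INCREASE, CLASS_DECREASE], (32, 32), p=[0.7, 0.15, 0.15]
        )
        patches = extract_patches(self._map_from_classes(classes))
        for code, name in ((CLASS_INCREASE, "increase"), (CLASS_DECREASE, "decrease")):
            total = sum(p.area_px for p in patches if p.change_class == name)
            assert total == int((classes == code).sum())

    def test_deterministic_ordering_by_top_left(self):
        classes = np.zeros((6, 6))
        classes[4, 1] = CLASS_DECREASE
        classes[0, 3] = CLASS_INCREASE
        patches = extract_patches(self._map_from_classes(classes))
        assert [p.patch_id for p in patches] == [1, 2]
        assert patches[0].change_class == "increase"  # row 0 precedes row 4


class TestAntisymmetry:
    def test_swapping_epochs_negates_diff_and_swaps_classes(self, rng):
        grids = rng.uniform(0, 50, (4, 12, 12))
        series = series_of(grids, (1995, 1996, 2005, 2006))
        det_fwd = ChangeDetector(epoch1=(1995, 1996), epoch2=(2005, 2006)).fit(series)
        det_rev = ChangeDetector(epoch1=(2005, 2006), epoch2=(1995, 1996)).fit(series)
        np.testing.assert_allclose(det_fwd.change_map_.diff, -det_rev.change_map_.diff)
        f, r = det_fwd.change_map_.classes, det_rev.change_map_.classes
        np.testing.assert_array_equal(f == CLASS_INCREASE, r == CLASS_DECREASE)
        np.testing.assert_array_equal(f == CLASS_DECREASE, r == CLASS_INCREASE)
        fwd_areas = sorted((p.change_class, p.area_px) for p in det_fwd.patches_)
        swap = {"increase": "decrease", "decrease": "increase"}
        rev_areas = sorted((swap[p.change_class], p.area_px) for p in det_rev.patches_)
        assert fwd_areas == rev_areas


class TestRegionSummary:
    def test_proportions(self):
        classes = np.full((10, 10), CLASS_NONE, dtype=np.uint8)
        classes[:5, :5] = CLASS_INCREASE  # 25 of 100 pixels
        cmap = TestPatches()._map_from_classes(classes)
        series = series_of([np.full((10, 10), 9.0)], [2000])
        region = RegionMask("r", np.ones((10, 10), bool))
        s = summarize_region(cmap, series, region)
        assert s.prop_increase == pytest.approx(0.25)
        assert s.prop_decrease == 0.0
        assert s.annual_means[2000] == pytest.approx(9.0)

    def test_partition_of_land(self, rng):
        classes = rng.choice(
            [CLASS_NONE, CLASS_INCREASE, CLASS_DECREASE, CLASS_MASKED, CLASS_NODATA],
            (20, 20), p=[0.4, 0.2, 0.2, 0.1, 0.1],
        ).astype(np.uint8)
        cmap = TestPatches()._map_from_classes(classes)
        cmap.classes = classes
        region = RegionMask("r", np.ones((20, 20), bool))
        series = series_of([np.zeros((20, 20))], [2000])
        s = summarize_region(cmap, series, region)
        land = classes != CLASS_NODATA
        prop_none = int(((classes == CLASS_NONE) & land).sum()) / land.sum()
        prop_masked = int(((classes == CLASS_MASKED) & land).sum()) / land.sum()
        assert s.prop_increase + s.prop_decrease + prop_none + prop_masked == pytest.approx(1.0)

    def test_empty_region_rejected(self):
        cmap = TestPatches()._map_from_classes(np.zeros((5, 5)))
        region = RegionMask("empty", np.zeros((5, 5), bool))
        with pytest.raises(ValidationError):
            summarize_region(cmap, [], region)
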