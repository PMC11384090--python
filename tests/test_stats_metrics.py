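"""Statistics, confusion-matrix metrics, Bland-Altman, group tests."""

import numpy as np
import pytest

from vertemap import (bland_altman, build_standardized_maps, compare_groups,
                      confusion_metrics, map_stats, map_stats_per_plane,
                      volumetric_stats)
from vertemap.inclination import VertebraROI

from conftest import make_roi


def _roi_from_values(values):
    vals = np.asarray(values, dtype=float).reshape(1, 1, -1)
    mask = np.ones_like(vals, dtype=bool)
    return VertebraROI(vals, mask, (1.0, 1.0, 1.0),
                       com=np.array([0.0, 0.0, (vals.size - 1) / 2]))


class TestVolumetricStats:
    def test_hand_computed_example(self):
        s = volumetric_stats(_roi_from_values([10, 20, 30]))
        assert (s.mean, s.min, s.max) == (20, 10, 30)
        assert s.sd == pytest.approx(10.0)  # sample SD, n-1 denominator
        assert s.n == 3

    def test_uniform_phantom(self, uniform_roi):
        s = volumetric_stats(uniform_roi)
        assert s.mean == 40.0 and s.sd == 0.0

    def test_agrees_with_bruteforce_loop(self):
        roi, _ = make_roi(noise=5.0, seed=4)
        s = volumetric_stats(roi)
        acc = [roi.scalar[z, y, x]
               for z, y, x in zip(*np.nonzero(roi.mask))]
        assert s.n == len(acc)
        assert s.mean == np.mean(acc)
        assert s.min == np.min(acc) and s.max == np.max(acc)
        assert s.sd == pytest.approx(np.std(acc, ddof=1), rel=1e-12)


class TestMapStats:
    def test_pooled_n_is_sum_of_planes(self, uniform_roi):
        maps = build_standardized_maps(uniform_roi)
        pooled = map_stats(maps)
        per = map_stats_per_plane(maps)
        assert pooled.n == sum(p.n for p in per.values())
        assert pooled.sd == 0.0 and pooled.mean == 40.0


class TestConfusionMetrics:
    def test_perfect_and_disjoint(self):
        m = np.zeros((6, 6, 6), dtype=bool)
        m[1:4, 1:4, 1:4] = True
        perfect = confusion_metrics(m, m, 0.001)
        assert perfect.dsc == 1.0 and perfect.jaccard == 1.0
        assert perfect.fdr == 0.0 and perfect.abs_vol_error_ml == 0.0
        other = np.zeros_like(m)
        other[4:6, 4:6, 4:6] = True
        assert confusion_metrics(m, other, 0.001).dsc == 0.0

    def test_shifted_cube_closed_form(self):
        """3x3x3 cube vs itself shifted by one voxel: overlap 18."""
        truth = np.zeros((8, 8, 8), dtype=bool)
        truth[2:5, 2:5, 2:5] = True
        pred = np.roll(truth, 1, axis=2)
        cm = confusion_metrics(pred, truth, 0.001)
        assert (cm.tp, cm.fp, cm.fn) == (18, 9, 9)
        assert cm.dsc == pytest.approx(36 / 54)
        assert cm.jaccard == pytest.approx(0.5)
        assert cm.abs_vol_error_ml == 0.0

    def test_identities_against_bruteforce_on_random_pairs(self):
        """Complementary-rate identities and DSC/Jaccard relation."""
        rng = np.random.default_rng(12)
        for _ in range(50):
            pred = rng.random((12, 12, 12)) < rng.uniform(0.2, 0.8)
            truth = rng.random((12, 12, 12)) < rng.uniform(0.2, 0.8)
            cm = confusion_metrics(pred, truth, 0.00432)
            # brute-force voxel enumeration as the oracle
            tp = sum(p and t for p, t in zip(pred.ravel(), truth.ravel()))
            fp = sum(p and not t
                     for p, t in zip(pred.ravel(), truth.ravel()))
            fn = sum(t and not p
                     for p, t in zip(pred.ravel(), truth.ravel()))
            assert (cm.tp, cm.fp, cm.fn) == (tp, fp, fn)
            assert cm.precision + cm.fdr == pytest.approx(1.0)
            assert cm.recall + cm.fnr == pytest.approx(1.0)
            assert cm.tnr + cm.fpr == pytest.approx(1.0)
            assert cm.npv + cm.forate == pytest.approx(1.0)
            assert cm.dsc == pytest.approx(2 * cm.jaccard / (1 + cm.jaccard))

    def test_empty_truth_flags_relative_error(self):
        pred = np.ones((3, 3, 3), dtype=bool)
        truth = np.zeros((3, 3, 3), dtype=bool)
        cm = confusion_metrics(pred, truth, 0.001)
        assert np.isnan(cm.rel_vol_error_percent)


class TestBlandAltman:
    def test_constant_difference(self):
        vol = np.array([10.0, 20.0, 30.0])
        res = bland_altman(vol, vol - 1.5)
        assert res.bias == pytest.approx(-1.5)
        assert res.sd_diff == 0.0
        assert res.loa_low == res.loa_high == pytest.approx(-1.5)

    def test_two_pair_closed_form(self):
        res = bland_altman([0.0, 10.0], [0.0, 8.0])
        assert res.bias == pytest.approx(-1.0)
        assert res.sd_diff == pytest.approx(np.sqrt(2.0))
        assert res.loa_low == pytest.approx(-1 - 1.96 * np.sqrt(2))
        assert res.loa_high == pytest.approx(-1 + 1.96 * np.sqrt(2))

    def test_identical_methods(self):
        res = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.bias == 0.0 and res.loa_high - res.loa_low == 0.0

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])


class TestCompareGroups:
    def test_identical_samples_not_significant(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1, 30)
        res = compare_groups(a, a.copy())
        assert not res.significant
        assert res.p_value > 0.9

    def test_separated_normals_detected_with_welch(self):
        rng = np.random.default_rng(1)
        res = compare_groups(rng.normal(0, 1, 50), rng.normal(5, 1, 50))
        assert res.test_name == "welch_t"
        assert res.significant

    def test_skewed_samples_fall_back_to_mann_whitney(self):
        rng = np.random.default_rng(2)
        res = compare_groups(rng.exponential(1.0, 40) ** 2,
                             rng.exponential(1.0, 40) ** 2)
        assert res.test_name == "mann_whitney_u"

    def test_constant_sample_falls_back_to_mann_whitney(self):
        res = compare_groups([5.0] * 10, [5.0, 5.0, 5.0, 5.0, 6.0])
        assert res.test_name == "mann_whitney_u"

    def test_tiny_samples_rejected(self):
        with pytest.raises(ValueError):
            compare_groups([1.0, 2.0], [1.0, 2.0, 3.0])
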