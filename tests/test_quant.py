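"""Counting rule, EdU index, domain fractions, intensity ratios."""

import numpy as np
import pytest

from pllptools import LabelVolume, Mask, Volume
from pllptools.quant import (CountParams, CountRecord, RegionSplit,
                             count_cells, edu_index,
                             expression_domain_fraction, mean_intensity_ratio)

SP = (1.0, 1.0, 1.0)


def _labels(arr):
    return LabelVolume(np.asarray(arr, dtype=np.int32), SP)


def _mask(arr):
    return Mask(np.asarray(arr, dtype=bool), SP)


class TestCountCells:
    def test_segment_fully_inside_is_counted(self):
        lab = np.zeros((4, 4, 4), dtype=np.int32)
        lab[1:3, 1:3, 1:3] = 1
        res = count_cells(_labels(lab), _mask(np.ones((4, 4, 4))))
        assert res.count == 1
        assert res.inside_fraction[0] == 1.0

    def test_exactly_three_quarters_inside_is_not_counted(self):
        """The in-mask rule is a strict inequality: a segment with exactly
        75% of its volume inside the mask is excluded."""
        lab = np.zeros((1, 1, 4), dtype=np.int32)
        lab[0, 0, :] = 1
        mask = np.zeros((1, 1, 4), dtype=bool)
        mask[0, 0, :3] = True  # 3 of 4 voxels inside
        res = count_cells(_labels(lab), _mask(mask))
        assert res.inside_fraction[0] == pytest.approx(0.75)
        assert res.count == 0

    def test_just_above_three_quarters_is_counted(self):
        lab = np.zeros((1, 1, 8), dtype=np.int32)
        lab[0, 0, :] = 1
        mask = np.zeros((1, 1, 8), dtype=bool)
        mask[0, 0, :7] = True  # 7/8 = 0.875
        assert count_cells(_labels(lab), _mask(mask)).count == 1

    def test_empty_mask_counts_zero(self):
        lab = np.ones((3, 3, 3), dtype=np.int32)
        assert count_cells(_labels(lab), _mask(np.zeros((3, 3, 3)))).count == 0

    def test_grid_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            count_cells(_labels(np.ones((3, 3, 3), dtype=np.int32)),
                        _mask(np.ones((4, 4, 4))))

    def test_count_monotone_in_mask(self, pipeline_result):
        """Enlarging the mask never decreases the count."""
        from scipy import ndimage as ndi
        labels, mask = pipeline_result.labels, pipeline_result.mask
        base = count_cells(labels, mask).count
        grown = mask.mask
        for _ in range(3):
            grown = ndi.binary_dilation(grown)
            c = count_cells(labels, Mask(grown, mask.spacing)).count
            assert c >= base
            base = c


class TestEdUIndex:
    def _two_row_cells(self, n=6, bright=()):
        """n unit-cube cells along x; selected ones carry bright voxels."""
        lab = np.zeros((2, 2, 2 * n), dtype=np.int32)
        chan = np.zeros((2, 2, 2 * n))
        for i in range(n):
            lab[:, :, 2 * i:2 * i + 2] = i + 1
            if (i + 1) in bright:
                chan[:, :, 2 * i:2 * i + 2] = 100.0
        return _labels(lab), Volume(chan, SP), _mask(np.ones_like(lab))

    def test_all_positive_gives_index_one(self):
        lab, chan, mask = self._two_row_cells(bright=range(1, 7))
        res = edu_index(lab, chan, mask)
        assert res.whole.index == 1.0

    def test_none_positive_gives_index_zero(self):
        lab, chan, mask = self._two_row_cells(bright=())
        res = edu_index(lab, chan, mask)
        assert res.whole.index == 0.0

    def test_positives_only_in_trailing_region(self):
        """Bright cells at the low-x (trailing) end leave the leading index
        at zero."""
        lab, chan, mask = self._two_row_cells(n=9, bright=(1, 2))
        res = edu_index(lab, chan, mask, RegionSplit(leading_fraction=1 / 3))
        assert res.leading.index == 0.0
        assert res.trailing.n_pos == 2

    def test_whole_equals_weighted_regional_mean(self, edu_acquisition):
        vol, edu, gt, _spec = edu_acquisition
        from pllptools.pipeline import count_pipeline
        res = count_pipeline(vol)
        r = edu_index(res.labels, edu, res.mask)
        assert r.whole.n_total == r.leading.n_total + r.trailing.n_total
        assert r.whole.n_pos == r.leading.n_pos + r.trailing.n_pos
        lead_w = r.leading.n_total / r.whole.n_total
        trail_w = r.trailing.n_total / r.whole.n_total
        assert r.whole.index == pytest.approx(
            lead_w * r.leading.index + trail_w * r.trailing.index, abs=1e-12)

    def test_recovers_generated_positives(self, edu_acquisition):
        """Against ground-truth labels, positivity calls match the generated
        EdU-positive set exactly on a clean acquisition."""
        vol, edu, gt, _spec = edu_acquisition
        from pllptools.mask import primordium_mask
        m = primordium_mask(vol)
        r = edu_index(gt.labels, edu, m)
        recovered = r.positive_labels
        truth = gt.edu_positive
        sym_diff = len(recovered ^ truth)
        assert sym_diff <= 0.05 * len(truth) + 2

    def test_fewer_than_two_cells_rejected(self):
        lab = np.zeros((2, 2, 2), dtype=np.int32)
        lab[0, 0, 0] = 1
        with pytest.raises(ValueError, match="2"):
            edu_index(_labels(lab), Volume(np.zeros((2, 2, 2)), SP),
                      _mask(np.ones((2, 2, 2))))


class TestExpressionDomain:
    def _mask_box(self):
        m = np.zeros((4, 4, 20), dtype=bool)
        m[1:3, 1:3, :] = True
        return _mask(m)

    def test_anterior_half_length_fraction(self):
        m = self._mask_box()
        sig = np.zeros((4, 4, 20))
        sig[:, :, :10] = 50.0
        frac = expression_domain_fraction(m, Volume(sig, SP), mode="length")
        assert frac == pytest.approx(0.5, abs=0.06)

    def test_no_signal_gives_zero(self):
        m = self._mask_box()
        frac = expression_domain_fraction(m, Volume(np.zeros((4, 4, 20)), SP))
        assert frac == 0.0

    def test_signal_everywhere_gives_one(self):
        m = self._mask_box()
        sig = np.where(m.mask, 80.0, 0.0)
        assert expression_domain_fraction(m, Volume(sig, SP), "length") == 1.0
        assert expression_domain_fraction(m, Volume(sig, SP), "area") == 1.0

    def test_area_mode_counts_voxels(self):
        m = self._mask_box()
        sig = np.zeros((4, 4, 20))
        sig[1:3, 1:3, :5] = 60.0  # quarter of the mask along x
        frac = expression_domain_fraction(m, Volume(sig, SP), mode="area")
        assert frac == pytest.approx(0.25)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            expression_domain_fraction(_mask(np.zeros((4, 4, 4))),
                                       Volume(np.ones((4, 4, 4)), SP))


class TestMeanIntensityRatio:
    def test_identical_inputs_give_one(self, primordium):
        vol, gt = primordium
        m = Mask(gt.labels.labels > 0, vol.spacing)
        assert mean_intensity_ratio(vol, m, vol, m) == 1.0

    def test_constant_regions_give_exact_ratio(self):
        m = _mask(np.ones((3, 3, 3)))
        va = Volume(np.full((3, 3, 3), 6.0), SP)
        vb = Volume(np.full((3, 3, 3), 4.0), SP)
        assert mean_intensity_ratio(va, m, vb, m) == pytest.approx(1.5)

    def test_invariant_to_joint_rescaling(self):
        rng = np.random.default_rng(4)
        a, b = rng.random((3, 3, 3)) + 1, rng.random((3, 3, 3)) + 1
        m = _mask(np.ones((3, 3, 3)))
        r1 = mean_intensity_ratio(Volume(a, SP), m, Volume(b, SP), m)
        r2 = mean_intensity_ratio(Volume(7 * a, SP), m, Volume(7 * b, SP), m)
        assert r1 == pytest.approx(r2, rel=1e-12)

    def test_empty_mask_and_zero_denominator_rejected(self):
        m = _mask(np.ones((3, 3, 3)))
        empty = _mask(np.zeros((3, 3, 3)))
        v = Volume(np.ones((3, 3, 3)), SP)
        with pytest.raises(ValueError, match="empty"):
            mean_intensity_ratio(v, empty, v, m)
        zero = Volume(np.zeros((3, 3, 3)), SP)
        with pytest.raises(ValueError, match="denominator"):
            mean_intensity_ratio(v, m, zero, m)


def test_count_record_rejects_negative_count():
    with pytest.raises(ValueError):
        CountRecord("e1", "control", -3)
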