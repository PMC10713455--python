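"""Instance extraction, circularity gates and patch classification."""

import math

import numpy as np
import pytest

from emcaps.core import BarcodeClass
from emcaps.instances import (NO_CALL, ExclusionReason, FilterParams,
                              InstanceRecord, chain_perimeter, circularity,
                              classify_patch, extract_instances,
                              extract_masked_patch, filter_instances,
                              majority_vote_call, undersample_balance)
from emcaps.pipeline import classify_instances
from emcaps.segment import argmax_map, postprocess

B = BarcodeClass


def _disk(r, pad=2, value=1, center_offset=(0.0, 0.0)):
    n = 2 * (r + pad) + 1
    ax = np.arange(n) - (r + pad)
    d2 = ((ax[:, None] - center_offset[0]) ** 2
          + (ax[None, :] - center_offset[1]) ** 2)
    return (d2 <= (r + 0.5) ** 2).astype(np.uint8) * value


def _record(area=100, circ=0.9, border=False, bbox=(5, 5, 15, 15)):
    return InstanceRecord(id=1, class_id=1, centroid=(10.0, 10.0),
                          area_px=area, perimeter_px=1.0, circularity=circ,
                          bbox=bbox, touches_border=border,
                          mask=np.ones((1, 1), bool))


class TestExtract:
    def test_empty_raster(self):
        assert extract_instances(np.zeros((10, 10), np.uint8)) == []

    def test_two_disjoint_disks(self):
        labels = np.zeros((40, 80), np.uint8)
        d = _disk(6)
        labels[5:5 + d.shape[0], 5:5 + d.shape[1]] = d
        labels[5:5 + d.shape[0], 40:40 + d.shape[1]] = d * 3
        recs = extract_instances(labels)
        assert len(recs) == 2
        assert sorted(r.area_px for r in recs) == [int(d.sum())] * 2
        assert sorted(r.class_id for r in recs) == [1, 3]

    def test_touching_disks_merge_into_one_instance(self):
        labels = np.zeros((30, 50), np.uint8)
        d = _disk(6)
        labels[5:5 + d.shape[0], 5:5 + d.shape[1]] = d
        sub = labels[5:5 + d.shape[0], 18:18 + d.shape[1]]
        sub[d > 0] = 6  # centers 13 px apart: the two disks touch
        assert labels[13, 18] and labels[13, 19]
        recs = extract_instances(labels)
        assert len(recs) == 1


class TestCircularity:
    def test_square_closed_form(self):
        for a in (5, 20, 50):
            m = np.zeros((a + 4, a + 4), bool)
            m[2:2 + a, 2:2 + a] = True
            assert chain_perimeter(m) == pytest.approx(4 * a)
            assert circularity(m) == pytest.approx(math.pi / 4)

    def test_single_pixel_unit_square(self):
        m = np.zeros((3, 3), bool)
        m[1, 1] = True
        assert chain_perimeter(m) == 4.0
        assert circularity(m) == pytest.approx(4 * math.pi / 16)

    def test_digitized_disk_regression(self):
        # frozen value of the chosen estimator for a centered r=15 disk
        c = circularity(_disk(15).astype(bool))
        assert 0.85 <= c <= 1.0
        assert c == pytest.approx(0.8887145207333236, abs=1e-12)

    def test_continuous_disk_limit_approaches_one(self):
        cs = [circularity(_disk(r).astype(bool)) for r in (10, 16, 32, 64)]
        assert all(c >= 0.85 for c in cs)

    def test_scale_consistent_across_magnification(self):
        # re-digitizing a convex shape at twice the resolution (half the
        # pixel size) must not move the score by more than 0.05
        for r in (10, 12, 15):
            assert abs(circularity(_disk(r).astype(bool))
                       - circularity(_disk(2 * r).astype(bool))) < 0.05
        for a in (10, 21):
            sq1 = np.pad(np.ones((a, a), bool), 2)
            sq2 = np.pad(np.ones((2 * a, 2 * a), bool), 2)
            assert abs(circularity(sq1) - circularity(sq2)) < 0.05

    def test_elongated_shape_scores_low(self):
        line = np.pad(np.ones((1, 60), bool), 2)
        assert circularity(line) < 0.2

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((4, 4), bool))


class TestFilter:
    @pytest.mark.parametrize("area,reason", [
        (59, ExclusionReason.TOO_SMALL),
        (60, ExclusionReason.NONE),
        (2304, ExclusionReason.NONE),
        (2305, ExclusionReason.TOO_LARGE),
    ])
    def test_area_boundaries(self, area, reason):
        out = filter_instances([_record(area=area)], FilterParams())
        assert out[0].exclusion_reason is reason

    @pytest.mark.parametrize("circ,reason", [
        (0.79, ExclusionReason.LOW_CIRCULARITY),
        (0.80, ExclusionReason.NONE),
    ])
    def test_circularity_boundary(self, circ, reason):
        out = filter_instances([_record(circ=circ)], FilterParams())
        assert out[0].exclusion_reason is reason

    def test_border_instance_excluded_and_unclassified(self):
        out = filter_instances([_record(border=True)], FilterParams())
        assert out[0].exclusion_reason is ExclusionReason.BORDER
        assert out[0].class_id == 0

    def test_corner_disk_flagged_by_extraction(self):
        labels = np.zeros((30, 30), np.uint8)
        d = _disk(6)
        labels[:d.shape[0] - 6, :d.shape[1] - 6] = d[6:, 6:]
        recs = extract_instances(labels)
        assert recs[0].touches_border

    def test_exactly_one_reason(self):
        recs = [_record(area=10, circ=0.1, border=True)]
        out = filter_instances(recs, FilterParams())
        assert out[0].exclusion_reason is ExclusionReason.TOO_SMALL  # first match


class TestPatches:
    def test_patch_zeros_off_mask(self, scene_factory):
        mic, gt = scene_factory([B.QT_2M])
        recs = extract_instances(gt.semantic)
        patch = extract_masked_patch(mic.pixels, recs[0], 49)
        assert patch.shape == (49, 49)
        center = patch[24, 24]
        assert center != 0
        assert patch[0, 0] == 0  # corner is outside the disk footprint

    def test_full_mask_patch_equals_raw_crop(self, rng):
        raster = rng.random((60, 60)) + 0.5
        rec = InstanceRecord(id=1, class_id=1, centroid=(30.0, 30.0),
                             area_px=3600, perimeter_px=1, circularity=1,
                             bbox=(0, 0, 60, 60), touches_border=True,
                             mask=np.ones((60, 60), bool))
        patch = extract_masked_patch(raster, rec, 21)
        assert np.array_equal(patch, raster[20:41, 20:41])

    def test_noiseless_patch_profile_matches_template(self, scene_factory,
                                                      templates, scale):
        mic, gt = scene_factory([B.QT_1M], size=(128, 128))
        recs = extract_instances(gt.semantic)
        patch = extract_masked_patch(mic.pixels, recs[0], 49)
        rr, cc = np.nonzero(patch)
        d_nm = np.hypot(rr - rr.mean(), cc - cc.mean()) * scale.nm_per_pixel
        expected = 0.85 * templates[B.QT_1M](d_nm)
        assert np.abs(patch[rr, cc] - expected).mean() < 0.02

    def test_classify_noiseless_self_match(self, scene_factory, templates, scale):
        for cls in B:
            mic, gt = scene_factory([cls], size=(128, 128))
            recs = extract_instances(gt.semantic)
            patch = extract_masked_patch(mic.pixels, recs[0], 49)
            got, scores = classify_patch(patch, templates, scale)
            assert got is cls
            assert scores.shape == (6,)

    def test_all_zero_patch_rejected(self, templates, scale):
        with pytest.raises(ValueError):
            classify_patch(np.zeros((49, 49)), templates, scale)

    def test_brightness_invariance(self, scene_factory, templates, scale):
        mic, gt = scene_factory([B.MX_1M], size=(128, 128))
        recs = extract_instances(gt.semantic)
        patch = extract_masked_patch(mic.pixels, recs[0], 49)
        c1, s1 = classify_patch(patch, templates, scale)
        c2, s2 = classify_patch(patch * 2.0, templates, scale)
        assert c1 is c2
        assert np.allclose(s1, s2, atol=1e-9)

    def test_noisy_patches_diagonal_dominant(self, engine, templates, scale,
                                             scene_factory):
        confusion = np.zeros((7, 7), int)
        for cls in B:
            for i in range(8):
                mic, gt = scene_factory([cls], size=(128, 128), noiseless=False,
                                        seed=int(cls) * 100 + i)
                labels = postprocess(argmax_map(engine.predict(mic.pixels)))
                for rec in classify_instances(mic.pixels, labels, templates, scale):
                    if rec.class_id > 0:
                        confusion[int(cls), rec.class_id] += 1
        diag = np.diag(confusion)[1:]
        rows = confusion[1:, 1:].sum(axis=1)
        assert (rows > 0).all()
        assert np.all(diag >= 0.75 * rows)  # diagonal dominance at small n


class TestVoting:
    def _records(self, classes):
        return [InstanceRecord(id=i, class_id=int(c), centroid=(0, 0),
                               area_px=100, perimeter_px=1, circularity=1,
                               bbox=(0, 0, 1, 1), touches_border=False)
                for i, c in enumerate(classes)]

    def test_unanimous(self):
        recs = self._records([B.QT_1M] * 10)
        assert majority_vote_call(recs, 5, 0) is B.QT_1M

    def test_tie_is_no_call(self):
        recs = self._records([B.QT_1M] * 3 + [B.TM_1M] * 3)
        assert majority_vote_call(recs, 6, 0) is NO_CALL

    def test_no_classified_records(self):
        recs = self._records([0])
        with pytest.raises(ValueError):
            majority_vote_call(recs, 5, 0)

    def test_modal_call_recovers_dominant_class(self, rng):
        # 80% of records carry the true class; the binomial probability of a
        # wrong modal outcome at n=20 is far below 5%
        classes = [B.QT_2M] * 80 + [B.MX_2M] * 10 + [B.TM_1M] * 10
        recs = self._records(classes)
        wins = sum(majority_vote_call(recs, 20, rng) is B.QT_2M
                   for _ in range(200))
        assert wins >= 190

    def test_undersample_balance_equalizes(self, rng):
        recs = self._records([B.QT_1M] * 9 + [B.MX_1M] * 4 + [B.TM_1M] * 6)
        balanced = undersample_balance(recs, rng)
        counts = np.bincount([r.class_id for r in balanced], minlength=7)
        assert counts[int(B.QT_1M)] == counts[int(B.MX_1M)] \
            == counts[int(B.TM_1M)] == 4
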