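"""Confusion matrices, instance matching and panoptic quality."""

import itertools

import numpy as np
import pytest

from emcaps.metrics import (ConfusionMatrix, MatchResult, evaluate_dataset,
                            instance_components, match_instances,
                            match_label_maps, panoptic_scores, pixel_confusion,
                            pixel_scores)


def _square(labels, r, c, size, value):
    labels[r:r + size, c:c + size] = value


class TestPixelConfusion:
    def test_identical_rasters_diagonal(self, rng):
        labels = rng.integers(0, 7, (16, 16))
        cm = pixel_confusion(labels, labels)
        assert cm.counts.sum() == labels.size
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_pred_all_background_first_column(self, rng):
        gt = rng.integers(0, 7, (16, 16))
        cm = pixel_confusion(gt, np.zeros_like(gt))
        assert cm.counts[:, 1:].sum() == 0

    def test_matches_bruteforce_pair_counting(self, rng):
        gt = rng.integers(0, 7, (8, 8))
        pred = rng.integers(0, 7, (8, 8))
        cm = pixel_confusion(gt, pred)
        brute = np.zeros((7, 7), int)
        for i in range(8):
            for j in range(8):
                brute[gt[i, j], pred[i, j]] += 1
        assert np.array_equal(cm.counts, brute)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pixel_confusion(np.zeros((4, 4), int), np.zeros((5, 5), int))

    def test_additive_across_images(self, rng):
        a_gt, a_pr = rng.integers(0, 7, (2, 12, 12))
        b_gt, b_pr = rng.integers(0, 7, (2, 12, 12))
        summed = pixel_confusion(a_gt, a_pr) + pixel_confusion(b_gt, b_pr)
        concat = pixel_confusion(np.vstack([a_gt, b_gt]), np.vstack([a_pr, b_pr]))
        assert np.array_equal(summed.counts, concat.counts)


class TestPixelScores:
    def test_perfect_prediction(self, rng):
        labels = rng.integers(0, 7, (32, 32))
        scores = pixel_scores(pixel_confusion(labels, labels))
        present = np.unique(labels)
        for k in scores.index:
            if k in present:
                assert scores.loc[k, "dsc"] == 1.0

    def test_half_overlap_dsc(self):
        gt = np.zeros((20, 20), int)
        pred = np.zeros((20, 20), int)
        gt[0:10, 0:10] = 1          # |gt| = 100
        pred[5:15, 0:10] = 1        # |pred| = 100, overlap 50
        scores = pixel_scores(pixel_confusion(gt, pred))
        assert scores.loc[1, "dsc"] == pytest.approx(0.5)

    def test_absent_class_reported_absent_not_zero(self):
        gt = np.zeros((8, 8), int)
        gt[0, 0] = 1
        scores = pixel_scores(pixel_confusion(gt, gt))
        assert np.isnan(scores.loc[3, "dsc"])
        # absent classes are excluded from, not zeroed into, the macro mean
        assert scores["dsc"].mean() == 1.0


def _bruteforce_match(gt_inst, gt_classes, pred_inst, pred_classes, thr=0.5):
    """Exhaustive optimal one-to-one assignment maximizing matches."""
    cand = []
    for g in gt_classes:
        for p in pred_classes:
            if gt_classes[g] != pred_classes[p]:
                continue
            inter = np.sum((gt_inst == g) & (pred_inst == p))
            union = np.sum((gt_inst == g) | (pred_inst == p))
            if union and inter / union > thr:
                cand.append((g, p))
    best = 0
    for k in range(len(cand), 0, -1):
        for combo in itertools.combinations(cand, k):
            gs = [c[0] for c in combo]
            ps = [c[1] for c in combo]
            if len(set(gs)) == k and len(set(ps)) == k:
                best = max(best, k)
        if best:
            break
    return best


class TestInstanceMatching:
    def test_identical_sets_all_tp(self, rng):
        labels = np.zeros((40, 40), int)
        _square(labels, 2, 2, 6, 1)
        _square(labels, 20, 20, 8, 4)
        m = match_label_maps(labels, labels)
        assert m.tp.sum() == 2 and m.fp.sum() == 0 and m.fn.sum() == 0
        assert all(iou == 1.0 for _, _, iou in m.pairs)

    def test_iou_040_pair_unmatched(self):
        gt = np.zeros((20, 30), int)
        pred = np.zeros((20, 30), int)
        _square(gt, 5, 0, 10, 2)      # 10x10
        _square(pred, 5, 6, 10, 2)    # overlap 10x4=40, union 160 -> IoU 0.25
        pred2 = np.zeros_like(pred)
        _square(pred2, 5, 3, 10, 2)   # overlap 70, union 130 -> IoU ~0.54
        m_low = match_label_maps(gt, pred)
        m_high = match_label_maps(gt, pred2)
        assert m_low.tp.sum() == 0 and m_low.fp.sum() == 1 and m_low.fn.sum() == 1
        assert m_high.tp.sum() == 1

    def test_matches_bruteforce_assignment(self, rng):
        for seed in range(10):
            r = np.random.default_rng(seed)
            gt = np.zeros((48, 48), int)
            pred = np.zeros((48, 48), int)
            for k in range(r.integers(2, 6)):
                row, col = r.integers(0, 38, 2)
                cls = int(r.integers(1, 4))
                _square(gt, row, col, 8, cls)
                jr, jc = r.integers(-3, 4, 2)
                _square(pred, np.clip(row + jr, 0, 38),
                        np.clip(col + jc, 0, 38), 8, cls)
            gi, gc = instance_components(gt)
            pi, pc = instance_components(pred)
            m = match_instances(gi, gc, pi, pc)
            assert int(m.tp.sum()) == _bruteforce_match(gi, gc, pi, pc)

    def test_class_mismatch_never_matches(self):
        gt = np.zeros((12, 12), int)
        pred = np.zeros((12, 12), int)
        _square(gt, 2, 2, 8, 1)
        _square(pred, 2, 2, 8, 2)
        m = match_label_maps(gt, pred)
        assert m.tp.sum() == 0 and m.fp.sum() == 1 and m.fn.sum() == 1


class TestPanoptic:
    def test_perfect_match_all_ones(self):
        labels = np.zeros((20, 20), int)
        _square(labels, 2, 2, 6, 3)
        scores = panoptic_scores(match_label_maps(labels, labels))
        assert scores.loc[3, ["pq", "sq", "rq"]].tolist() == [1.0, 1.0, 1.0]

    def test_closed_form_one_tp_one_fp(self):
        m = MatchResult()
        m.tp[2] = 1
        m.iou_sum[2] = 0.8
        m.fp[2] = 1
        s = panoptic_scores(m)
        assert s.loc[2, "rq"] == pytest.approx(2 / 3)
        assert s.loc[2, "sq"] == pytest.approx(0.8)
        assert s.loc[2, "pq"] == pytest.approx(0.5333, abs=1e-4)

    def test_rq_equals_f1_identity(self, rng):
        for _ in range(20):
            tp, fp, fn = rng.integers(1, 30, 3)
            m = MatchResult()
            m.tp[1], m.fp[1], m.fn[1] = tp, fp, fn
            m.iou_sum[1] = tp * 0.9
            rq = panoptic_scores(m).loc[1, "rq"]
            prec = tp / (tp + fp)
            rec = tp / (tp + fn)
            f1 = 2 * prec * rec / (prec + rec)
            assert rq == pytest.approx(f1)

    def test_pq_is_sq_times_rq(self, rng):
        m = MatchResult()
        for k in range(1, 7):
            m.tp[k] = int(rng.integers(1, 10))
            m.fp[k] = int(rng.integers(0, 10))
            m.fn[k] = int(rng.integers(0, 10))
            m.iou_sum[k] = m.tp[k] * rng.uniform(0.5, 1.0)
        s = panoptic_scores(m)
        assert np.allclose(s["pq"], s["sq"] * s["rq"])

    def test_empty_class_absent(self):
        s = panoptic_scores(MatchResult())
        assert s["pq"].isna().all()

    def test_merged_prediction_cannot_increase_rq(self):
        # two separate gt particles; merging the two correct predictions into
        # one component turns 2 TP into 1 FP + 2 FN: pessimistic by design
        gt = np.zeros((20, 40), int)
        _square(gt, 5, 5, 10, 1)
        _square(gt, 5, 20, 10, 1)
        pred_exact = gt.copy()
        pred_merged = gt.copy()
        pred_merged[9:11, 15:20] = 1  # bridge
        rq_exact = panoptic_scores(match_label_maps(gt, pred_exact)).loc[1, "rq"]
        rq_merged = panoptic_scores(match_label_maps(gt, pred_merged)).loc[1, "rq"]
        assert rq_merged <= rq_exact
        assert rq_merged < 1.0


class TestEvaluateDataset:
    def test_single_perfect_pair(self, rng):
        labels = rng.integers(0, 3, (32, 32))
        labels[labels > 0] += 0  # classes 1..2
        rep = evaluate_dataset([labels], [labels])
        assert rep.pixel["dsc"].dropna().eq(1.0).all()

    def test_concatenation_equals_summation(self, rng):
        gts = [rng.integers(0, 7, (24, 24)) for _ in range(2)]
        preds = [rng.integers(0, 7, (24, 24)) for _ in range(2)]
        separate = evaluate_dataset(gts, preds)
        summed = pixel_confusion(gts[0], preds[0]) + pixel_confusion(gts[1], preds[1])
        assert np.array_equal(separate.confusion.counts, summed.counts)

    def test_global_aggregation_differs_from_per_image_mean(self):
        # dense image: 9 matched instances; sparse image: 1 missed instance
        dense_gt = np.zeros((40, 40), int)
        for i in range(3):
            for j in range(3):
                _square(dense_gt, 2 + i * 13, 2 + j * 13, 6, 1)
        sparse_gt = np.zeros((40, 40), int)
        _square(sparse_gt, 10, 10, 6, 1)
        rep = evaluate_dataset([dense_gt, sparse_gt],
                               [dense_gt, np.zeros_like(sparse_gt)])
        rq_global = rep.panoptic.loc[1, "rq"]
        rq_dense, rq_sparse = 1.0, 0.0
        per_image_mean = (rq_dense + rq_sparse) / 2
        assert rq_global == pytest.approx(9 / 9.5)
        assert abs(rq_global - per_image_mean) > 0.4

    def test_unpaired_lists_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            evaluate_dataset([np.zeros((4, 4), int)], [])

    def test_report_roundtrip(self, tmp_path, rng):
        labels = rng.integers(0, 7, (24, 24))
        rep = evaluate_dataset([labels], [labels])
        rep.to_json(tmp_path / "r.json")
        rep.to_csv(tmp_path / "r.csv")
        assert (tmp_path / "r.json").stat().st_size > 0
        assert (tmp_path / "r.csv").read_text().count("\n") == 7

    def test_confusion_validation(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(np.zeros((3, 3), int))
        with pytest.raises(ValueError):
            pixel_confusion(np.full((4, 4), 9), np.zeros((4, 4), int))
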