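"""Evaluation metrics: IoU arithmetic, NMS, matching, AP vs brute force,
confusion-matrix structure."""

import itertools

import numpy as np
import pytest

from wildasm.metrics import (Detection, average_precision,
                             confidence_score, confusion_matrix_normalized,
                             evaluate_detections, iou, map50, map50_95,
                             match_detections, nms, precision_recall_f1)


def det(cid, box, conf):
    return Detection(cid, tuple(map(float, box)), conf)


class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 2, 3), (0, 0, 2, 3)) == 1.0

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_half_shifted_unit_squares(self):
        assert iou((0, 0, 1, 1), (0.5, 0, 1.5, 1)) == pytest.approx(1 / 3)

    def test_inverted_coordinates_rejected(self):
        with pytest.raises(ValueError):
            iou((1, 1, 0, 0), (0, 0, 1, 1))


class TestConfidence:
    @pytest.mark.parametrize("p,i,expect", [(1.0, 1.0, 1.0), (0.8, 0.5, 0.4),
                                            (0.7, 0.0, 0.0)])
    def test_product(self, p, i, expect):
        assert confidence_score(p, i) == pytest.approx(expect)

    def test_range_checked(self):
        with pytest.raises(ValueError):
            confidence_score(1.2, 0.5)


class TestNms:
    def test_suppresses_same_class_overlap(self):
        a = det(0, (0, 0, 10, 10), 0.9)
        b = det(0, (0.5, 0.5, 10, 10), 0.8)
        assert nms([a, b], iou_threshold=0.5) == [a]

    def test_keeps_disjoint(self):
        a, b = det(0, (0, 0, 5, 5), 0.9), det(0, (20, 20, 25, 25), 0.3)
        assert set(nms([a, b], 0.5)) == {a, b}

    def test_class_aware(self):
        a = det(0, (0, 0, 10, 10), 0.9)
        b = det(1, (0, 0, 10, 10), 0.8)
        assert set(nms([a, b], 0.5)) == {a, b}


class TestMatching:
    def test_tp_above_threshold(self):
        tp, _, fn = match_detections([det(0, (0, 0, 10, 10), 0.9)],
                                     [(0, (0, 0, 10, 8))], 0.5)
        assert tp.tolist() == [True] and fn == 0

    def test_single_match_per_ground_truth(self):
        dets = [det(0, (0, 0, 10, 10), 0.9), det(0, (0, 0, 10, 10), 0.7)]
        tp, sdets, fn = match_detections(dets, [(0, (0, 0, 10, 10))], 0.5)
        assert tp.tolist() == [True, False] and fn == 0

    def test_wrong_class_is_fp_plus_fn(self):
        tp, _, fn = match_detections([det(2, (0, 0, 10, 10), 0.9)],
                                     [(5, (0, 0, 10, 10))], 0.5)
        assert tp.tolist() == [False] and fn == 1


class TestPrf:
    @pytest.mark.parametrize("p,r,f1", [
        (0.922, 0.888, 0.905),   # enhanced-model result row
        (0.92, 0.833, 0.874),    # baseline result row
    ])
    def test_published_triples(self, p, r, f1):
        assert round(2 * p * r / (p + r), 3) == f1

    def test_counts(self):
        p, r, f1 = precision_recall_f1(6, 2, 4)
        assert (p, r) == (0.75, 0.6)
        assert f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_degenerate_zero(self):
        assert precision_recall_f1(0, 0, 0) == (0.0, 0.0, 0.0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            precision_recall_f1(-1, 0, 0)


def brute_force_ap(flags, n_gt):
    """Exhaustive 101-point interpolated AP oracle."""
    tps = np.cumsum(flags)
    fps = np.cumsum([not f for f in flags])
    recalls = tps / n_gt
    precisions = tps / (tps + fps)
    total = 0.0
    for r in np.linspace(0, 1, 101):
        candidates = [p for p, rr in zip(precisions, recalls) if rr >= r - 1e-12]
        total += max(candidates) if candidates else 0.0
    return total / 101


class TestAveragePrecision:
    def test_single_perfect_detection(self):
        ap = average_precision([([det(0, (0, 0, 10, 10), 0.9)],
                                 [(0, 0, 10, 10)])])
        assert ap == pytest.approx(1.0)

    def test_tp_then_low_conf_fp(self):
        dets = [det(0, (0, 0, 10, 10), 0.9), det(0, (50, 50, 60, 60), 0.3)]
        ap = average_precision([(dets, [(0, 0, 10, 10)])])
        assert ap == pytest.approx(1.0)

    def test_matches_brute_force_on_all_small_instances(self):
        """AP equals exhaustive PR integration for every TP/FP pattern of
        up to 5 detections and 1-3 ground truths."""
        for n in range(1, 6):
            for flags in itertools.product([True, False], repeat=n):
                for n_gt in range(max(1, sum(flags)), 4):
                    dets, gts = [], [(0, (100 * g, 0, 100 * g + 10, 10))
                                     for g in range(n_gt)]
                    g = 0
                    for i, f in enumerate(flags):
                        conf = 0.9 - 0.1 * i
                        if f:
                            dets.append(det(0, gts[g][1], conf))
                            g += 1
                        else:
                            dets.append(det(0, (500 + 20 * i, 500, 510 + 20 * i, 510), conf))
                    got = average_precision([(dets, [b for _, b in gts])])
                    want = brute_force_ap(list(flags), n_gt)
                    assert got == pytest.approx(want, abs=1e-9), (flags, n_gt)

    def test_no_ground_truth_is_nan(self):
        assert np.isnan(average_precision([([], [])]))


class TestMaps:
    def test_mean_over_supported_classes(self):
        assert map50({0: 1.0, 1: 0.5}) == 0.75
        assert map50({0: 1.0, 1: float("nan")}) == 1.0
        with pytest.raises(ValueError):
            map50({0: float("nan")})

    def test_map5095_threshold_sweep_by_hand(self):
        """A detection with IoU 0.6 to its truth is a hit at thresholds
        <= 0.60 and a miss above."""
        thrs = np.round(np.arange(0.5, 0.96, 0.05), 2)
        by_thr = {0: {float(t): (1.0 if t <= 0.6 else 0.0) for t in thrs}}
        assert map50_95(by_thr) == pytest.approx(3 / 10)


class TestEndToEnd:
    def _scene(self):
        gts = [[(0, (0, 0, 20, 20)), (1, (40, 40, 80, 90))],
               [(0, (10, 10, 30, 30))]]
        dets = [[det(0, (0, 0, 20, 20), 0.9), det(1, (40, 40, 80, 90), 0.8)],
                [det(0, (10, 10, 30, 30), 0.85)]]
        return dets, gts

    def test_perfect_detector(self):
        dets, gts = self._scene()
        rep = evaluate_detections(dets, gts, nc=2)
        assert rep.map50 == pytest.approx(1.0)
        assert rep.map50_95 == pytest.approx(1.0)
        assert rep.precision == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(rep.confusion)[:2], 1.0)

    def test_map5095_never_exceeds_map50(self, rng):
        dets, gts = self._scene()
        # jitter the boxes so higher thresholds start failing
        dets = [[det(d.class_id, np.asarray(d.box) + rng.uniform(0, 6, 4),
                     d.confidence) for d in img] for img in dets]
        rep = evaluate_detections(dets, gts, nc=2)
        assert rep.map50_95 <= rep.map50 + 1e-12

    def test_image_and_detection_order_invariance(self):
        dets, gts = self._scene()
        rep_a = evaluate_detections(dets, gts, nc=2)
        rep_b = evaluate_detections([dets[1], dets[0][::-1]],
                                    [gts[1], gts[0]], nc=2)
        assert rep_a.map50 == pytest.approx(rep_b.map50)
        assert rep_a.map50_95 == pytest.approx(rep_b.map50_95)


class TestConfusionMatrix:
    def test_missed_truth_goes_to_background_row(self):
        m = confusion_matrix_normalized([[]], [[(1, (0, 0, 10, 10))]], nc=3)
        assert m[3, 1] == 1.0

    def test_ghost_detection_goes_to_background_column(self):
        m = confusion_matrix_normalized([[det(2, (0, 0, 10, 10), 0.9)]],
                                        [[]], nc=3)
        assert m[2, 3] == 1.0

    def test_mixed_scene_hand_tally(self):
        gts = [[(0, (0, 0, 10, 10)), (1, (20, 20, 30, 30)),
                (1, (40, 40, 50, 50)), (2, (60, 60, 70, 70)),
                (0, (80, 80, 90, 90))]]
        dets = [[det(0, (0, 0, 10, 10), 0.9),       # hit class 0
                 det(2, (20, 20, 30, 30), 0.8),     # class-confused hit on 1
                 det(1, (40, 40, 50, 50), 0.7),     # hit class 1
                 det(0, (200, 200, 210, 210), 0.6)]]  # ghost
        # class-2 truth missed
        m = confusion_matrix_normalized(dets, gts, nc=3)
        assert m[0, 0] == pytest.approx(0.5)   # 1 of 2 class-0 truths found
        assert m[3, 0] == pytest.approx(0.5)   # the other was missed
        assert m[2, 1] == pytest.approx(0.5)
        assert m[1, 1] == pytest.approx(0.5)
        assert m[3, 2] == pytest.approx(1.0)
        assert m[0, 3] == pytest.approx(1.0)

    def test_supported_columns_sum_to_one(self, rng):
        gts, dets = [], []
        for _ in range(4):
            img_gts, img_dets = [], []
            for _ in range(5):
                cid = int(rng.integers(3))
                x, y = rng.uniform(0, 400, 2)
                box = (x, y, x + 30, y + 30)
                img_gts.append((cid, box))
                if rng.random() < 0.8:
                    jitter = rng.uniform(-4, 4, 4)
                    img_dets.append(det(int(rng.integers(3)),
                                        np.asarray(box) + jitter,
                                        float(rng.uniform(0.3, 1))))
            gts.append(img_gts)
            dets.append(img_dets)
        m = confusion_matrix_normalized(dets, gts, nc=3)
        support = m.sum(axis=0)
        for c in range(4):
            if support[c] > 0:
                assert support[c] == pytest.approx(1.0, abs=1e-6)
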