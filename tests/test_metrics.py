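"""Detection-metric tests: IoU, matching, PR conventions, AP vs brute force."""

import numpy as np
import pytest

from cherryprep.annotations import BoundingBox
from cherryprep.metrics import (
    COCO_THRESHOLDS,
    Detection,
    GroundTruth,
    average_precision,
    evaluate,
    iou,
    match_detections,
    precision_recall,
)

from conftest import brute_force_ap


def box(x0, x1, y0, y1):
    return BoundingBox("grade_1", x0, x1, y0, y1)


def det(conf, b, image_id="img0", class_index=0):
    return Detection(image_id=image_id, class_index=class_index, confidence=conf, box=b)


def gt(b, image_id="img0", class_index=0):
    return GroundTruth(image_id=image_id, class_index=class_index, box=b)


class TestIou:
    def test_identical(self):
        assert iou(box(0, 10, 0, 10), box(0, 10, 0, 10)) == 1.0

    def test_disjoint(self):
        assert iou(box(0, 10, 0, 10), box(20, 30, 0, 10)) == 0.0

    def test_touching_edges_are_disjoint(self):
        assert iou(box(0, 10, 0, 10), box(10, 20, 0, 10)) == 0.0

    def test_quarter_overlap_worked_example(self):
        assert iou(box(0, 10, 0, 10), box(5, 15, 5, 15)) == pytest.approx(1 / 7)

    def test_symmetric(self, rng):
        for _ in range(20):
            x = rng.uniform(0, 50, 8)
            a = box(x[0], x[0] + x[1] + 1, x[2], x[2] + x[3] + 1)
            b = box(x[4], x[4] + x[5] + 1, x[6], x[6] + x[7] + 1)
            assert iou(a, b) == iou(b, a)


class TestMatching:
    def test_perfect_match(self):
        flags = match_detections([det(0.9, box(0, 10, 0, 10))], [gt(box(0, 10, 0, 10))], 0.5)
        assert flags == [True]

    def test_single_use_ground_truth(self):
        g = box(0, 10, 0, 10)
        dets = [det(0.9, g), det(0.8, box(1, 11, 0, 10))]
        assert match_detections(dets, [gt(g)], 0.5) == [True, False]

    def test_confidence_order_not_input_order(self):
        g = box(0, 10, 0, 10)
        dets = [det(0.8, box(1, 11, 0, 10)), det(0.9, g)]
        # higher-confidence detection claims the GT first
        assert match_detections(dets, [gt(g)], 0.5) == [True, False]

    def test_class_gating(self):
        flags = match_detections(
            [det(0.9, box(0, 10, 0, 10), class_index=1)], [gt(box(0, 10, 0, 10))], 0.5
        )
        assert flags == [False]

    def test_image_gating(self):
        flags = match_detections(
            [det(0.9, box(0, 10, 0, 10), image_id="other")], [gt(box(0, 10, 0, 10))], 0.5
        )
        assert flags == [False]

    def test_highest_iou_gt_preferred(self):
        near = box(0, 10, 0, 10)
        far = box(3, 13, 0, 10)
        flags = match_detections([det(0.9, box(1, 11, 0, 10))], [gt(far), gt(near)], 0.5)
        assert flags == [True]
        # the closer GT was consumed: a verbatim copy of it now has no partner
        flags2 = match_detections(
            [det(0.9, box(1, 11, 0, 10)), det(0.8, near)], [gt(near)], 0.9
        )
        assert flags2 == [False, True]


class TestPrecisionRecall:
    def test_counting_example(self):
        p, r, _ = precision_recall([True, True, False], 2)
        assert p == pytest.approx(2 / 3)
        assert r == 1.0

    def test_no_detections_vacuous_precision(self):
        p, r, _ = precision_recall([], 3)
        assert (p, r) == (1.0, 0.0)

    def test_no_gt_no_dets(self):
        p, r, _ = precision_recall([], 0)
        assert (p, r) == (1.0, 1.0)

    def test_all_true_positives(self):
        p, r, _ = precision_recall([True] * 4, 4)
        assert (p, r) == (1.0, 1.0)

    def test_recall_nondecreasing_along_sweep(self, rng):
        flags = list(rng.uniform(size=30) < 0.5)
        _, _, curve = precision_recall(flags, int(sum(flags)) + 3)
        assert (np.diff(curve.recall) >= 0).all()


class TestAveragePrecision:
    def test_perfect_detector(self):
        _, _, curve = precision_recall([True, True, True], 3)
        assert average_precision(curve) == 1.0

    def test_envelope_worked_example(self):
        _, _, curve = precision_recall([True, False, True], 3)
        assert average_precision(curve) == pytest.approx(5 / 9)

    def test_no_true_positives(self):
        _, _, curve = precision_recall([False, False], 2)
        assert average_precision(curve) == 0.0

    def test_agrees_with_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 11))
            flags = list(rng.uniform(size=n) < 0.5)
            n_gt = int(sum(flags)) + int(rng.integers(0, 4))
            if n_gt == 0:
                continue
            _, _, curve = precision_recall(flags, n_gt)
            assert average_precision(curve) == pytest.approx(brute_force_ap(flags, n_gt))

    def test_101point_close_to_allpoint(self, rng):
        flags = list(rng.uniform(size=200) < 0.7)
        _, _, curve = precision_recall(flags, int(sum(flags)) + 10)
        a = average_precision(curve, "allpoint")
        b = average_precision(curve, "101point")
        assert abs(a - b) < 0.02

    def test_invariant_to_monotone_confidence_rescaling(self, rng):
        gts = [gt(box(10 * i, 10 * i + 8, 0, 8)) for i in range(6)]
        dets = [
            det(float(c), box(10 * i + j, 10 * i + 8 + j, 0, 8))
            for i, (c, j) in enumerate(zip(rng.uniform(0.2, 0.9, 6), [0, 1, 5, 0, 2, 9]))
        ]
        rep1 = evaluate(dets, gts)
        squashed = [
            Detection(d.image_id, d.class_index, d.confidence**3, d.box) for d in dets
        ]
        rep2 = evaluate(squashed, gts)
        assert rep1.ap50 == pytest.approx(rep2.ap50)
        assert rep1.ap50_95 == pytest.approx(rep2.ap50_95)


class TestEvaluate:
    def test_perfect_detections_all_ones(self):
        gts = [gt(box(0, 10, 0, 10)), gt(box(20, 30, 0, 10), class_index=1)]
        dets = [det(1.0, g.box, class_index=g.class_index) for g in gts]
        rep = evaluate(dets, gts)
        assert (rep.precision, rep.recall, rep.ap50, rep.ap50_95) == (1, 1, 1, 1)

    def test_iou_07_detections_split_the_threshold_sweep(self):
        # dets overlap their GTs at IoU exactly 0.7: TP for t <= 0.70, FP above
        g = box(0, 10, 0, 10)
        d = box(0, 10, 0, 100 / 7)  # IoU = 100 / (10 * 100/7) = 0.7
        assert iou(g, d) == pytest.approx(0.7)
        rep = evaluate([det(1.0, d)], [gt(g)])
        assert rep.ap50 == 1.0
        assert rep.ap50_95 == pytest.approx(0.5 * rep.ap50)

    def test_empty_detection_set(self):
        rep = evaluate([], [gt(box(0, 10, 0, 10))])
        assert (rep.precision, rep.recall, rep.ap50, rep.ap50_95) == (1.0, 0.0, 0.0, 0.0)

    def test_detection_only_class_excluded_and_logged(self):
        gts = [gt(box(0, 10, 0, 10))]
        dets = [det(1.0, box(0, 10, 0, 10)), det(0.9, box(0, 10, 0, 10), class_index=3)]
        rep = evaluate(dets, gts)
        assert rep.ignored_classes == [3]
        assert rep.ap50 == 1.0  # class 3 excluded from the macro-average

    def test_ap_nonincreasing_in_threshold(self, rng):
        gts, dets = [], []
        for i in range(12):
            b = box(20 * i, 20 * i + 10, 0, 10)
            gts.append(gt(b))
            jit = float(rng.uniform(0, 4))
            dets.append(det(float(rng.uniform(0.3, 1)), box(20 * i + jit, 20 * i + 10 + jit, 0, 10)))
        aps = []
        for t in COCO_THRESHOLDS:
            flags = match_detections(dets, gts, t)
            _, _, curve = precision_recall(flags, len(gts))
            aps.append(average_precision(curve))
        assert all(a >= b - 1e-12 for a, b in zip(aps, aps[1:]))
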