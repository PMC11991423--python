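"""Tests for detection matching, PR curves, and average precision."""

import itertools

import numpy as np
import pytest

from holoplankton.detect_eval import (
    Detection,
    average_precision,
    evaluate,
    iou,
    map50,
    match_detections,
    pr_curve,
)
from holoplankton.io import YoloRecord


def box(x0, y0, x1, y1, class_id=0, frame=10.0):
    """Pixel-corner box on a `frame`-sized image, as a normalized record."""
    return YoloRecord(class_id, (x0 + x1) / 2 / frame, (y0 + y1) / 2 / frame,
                      (x1 - x0) / frame, (y1 - y0) / frame)


def det(b, conf, class_id=None):
    cid = b.class_id if class_id is None else class_id
    return Detection(class_id=cid, box=b, confidence=conf)


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def brute_force_pr(preds, truths, threshold=0.5):
    """PR points by independent enumeration: for every distinct confidence
    cut, redo the greedy matching from scratch on the retained subset."""
    confs = sorted({p.confidence for p in preds}, reverse=True)
    points = []
    for cut in confs:
        kept = [p for p in preds if p.confidence >= cut]
        kept.sort(key=lambda p: -p.confidence)
        used = [False] * len(truths)
        tp = 0
        for p in kept:
            best, best_ov = -1, -1.0
            for j, t in enumerate(truths):
                if used[j] or t.class_id != p.class_id:
                    continue
                ov = iou(p.box, t)
                if ov > best_ov:
                    best, best_ov = j, ov
            if best >= 0 and best_ov >= threshold:
                used[best] = True
                tp += 1
        points.append((tp / len(kept), tp / len(truths)))
    return points


def brute_force_ap(points):
    """AP by direct definition: integral over recall of the envelope
    max{precision at recall >= r}, evaluated on a fine recall grid."""
    if not points:
        return 0.0
    grid = np.linspace(0, 1, 100_001)[1:]  # exclude r = 0
    total = 0.0
    for r in grid:
        achievable = [p for p, rr in points if rr >= r - 1e-12]
        total += max(achievable) if achievable else 0.0
    return total / len(grid)


class TestIoU:
    def test_identical(self):
        b = box(1, 1, 4, 3)
        assert iou(b, b) == pytest.approx(1.0)

    def test_disjoint(self):
        assert iou(box(0, 0, 2, 2), box(5, 5, 7, 7)) == 0.0

    def test_touching_edges_is_zero(self):
        # center-form float round-trip can leave ~1e-17 of spurious overlap
        assert iou(box(0, 0, 2, 2), box(2, 0, 4, 2)) == pytest.approx(0.0, abs=1e-12)

    def test_hand_case_one_third(self):
        # pixel boxes [0,0,2,2] and [1,0,3,2]: intersection 2, union 6
        assert iou(box(0, 0, 2, 2), box(1, 0, 3, 2)) == pytest.approx(1 / 3)

    def test_degenerate_box_is_zero(self):
        assert iou(box(1, 1, 1, 3), box(0, 0, 3, 3)) == 0.0

    def test_symmetry_and_bounds(self, rng):
        for _ in range(50):
            xs, ys = np.sort(rng.uniform(0, 9, 2)), np.sort(rng.uniform(0, 9, 2))
            a = box(xs[0], ys[0], xs[1] + 0.5, ys[1] + 0.5)
            xs, ys = np.sort(rng.uniform(0, 9, 2)), np.sort(rng.uniform(0, 9, 2))
            b = box(xs[0], ys[0], xs[1] + 0.5, ys[1] + 0.5)
            v = iou(a, b)
            assert 0.0 <= v <= 1.0
            assert v == pytest.approx(iou(b, a))


class TestMatchDetections:
    def test_perfect_predictions(self):
        truths = [box(0, 0, 2, 2, 0), box(5, 5, 8, 8, 1)]
        preds = [det(t, 0.9) for t in truths]
        result = match_detections(preds, truths)
        assert sum(result.fp.values()) == 0
        assert result.precision() == pytest.approx(1.0)
        assert result.recall() == pytest.approx(1.0)

    def test_no_predictions(self):
        truths = [box(0, 0, 2, 2, 0), box(5, 5, 8, 8, 0)]
        result = match_detections([], truths)
        assert sum(result.tp.values()) == 0
        assert sum(result.fn.values()) == 2
        assert result.recall() == 0.0

    def test_low_overlap_is_fp(self):
        truths = [box(0, 0, 2, 2, 0), box(6, 6, 8, 8, 0)]
        preds = [det(box(0, 0, 2, 2, 0), 0.9),
                 det(box(6, 6, 8, 8, 0), 0.8),
                 det(box(1, 0, 3, 2, 0), 0.7)]  # IoU 1/3 < 0.5 with first truth
        result = match_detections(preds, truths)
        assert result.tp[0] == 2 and result.fp[0] == 1 and result.fn[0] == 0

    def test_class_must_agree(self):
        truths = [box(0, 0, 2, 2, class_id=1)]
        preds = [det(box(0, 0, 2, 2), 0.9, class_id=0)]
        result = match_detections(preds, truths)
        assert result.tp.get(0, 0) == 0 and result.fp[0] == 1 and result.fn[1] == 1

    def test_each_truth_consumed_once(self):
        truths = [box(0, 0, 2, 2, 0)]
        preds = [det(box(0, 0, 2, 2, 0), 0.9), det(box(0, 0, 2, 2, 0), 0.8)]
        result = match_detections(preds, truths)
        assert result.tp[0] == 1 and result.fp[0] == 1

    def test_boundary_iou_inclusive_vs_exclusive(self):
        truths = [box(0, 0, 2, 2, 0)]
        # overlap exactly 0.5: boxes [0,0,2,2] and [0,0,2,1]-> inter 2, union 4
        preds = [det(box(0, 0, 2, 1, 0), 0.9)]
        assert match_detections(preds, truths, 0.5, inclusive=True).tp[0] == 1
        assert match_detections(preds, truths, 0.5, inclusive=False).tp[0] == 0

    def test_counting_identities_random(self, rng):
        for seed in range(20):
            gen = np.random.default_rng(seed)
            truths, preds = [], []
            for _ in range(gen.integers(1, 6)):
                x, y = gen.uniform(0, 7, 2)
                truths.append(box(x, y, x + 2, y + 2, int(gen.integers(2))))
            for _ in range(gen.integers(0, 8)):
                x, y = gen.uniform(0, 7, 2)
                preds.append(det(box(x, y, x + 2, y + 2, int(gen.integers(2))),
                                 float(gen.random())))
            result = match_detections(preds, truths)
            for c in set(t.class_id for t in truths) | set(p.class_id for p in preds):
                n_truth = sum(1 for t in truths if t.class_id == c)
                n_pred = sum(1 for p in preds if p.class_id == c)
                assert result.tp.get(c, 0) + result.fn.get(c, 0) == n_truth
                assert result.tp.get(c, 0) + result.fp.get(c, 0) == n_pred


class TestPRCurve:
    def test_perfect_detector(self):
        truths = [box(0, 0, 2, 2, 0), box(5, 5, 7, 7, 0)]
        preds = [det(truths[0], 0.9), det(truths[1], 0.8)]
        points = pr_curve(preds, truths)
        assert points == [(1.0, 0.5), (1.0, 1.0)]

    def test_all_wrong_detector(self):
        truths = [box(0, 0, 2, 2, 0)]
        preds = [det(box(5, 5, 7, 7, 0), 0.9), det(box(5, 0, 7, 2, 0), 0.5)]
        points = pr_curve(preds, truths)
        assert all(p == 0.0 for p, _ in points)

    def test_recall_non_decreasing(self, rng):
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 0), box(7, 0, 9, 2, 0)]
        preds = [det(box(0, 0, 2, 2, 0), 0.95), det(box(4, 4, 6, 6, 0), 0.6),
                 det(box(2, 6, 4, 8, 0), 0.8), det(box(7, 0, 9, 2, 0), 0.3)]
        points = pr_curve(preds, truths)
        recalls = [r for _, r in points]
        assert recalls == sorted(recalls)

    def test_four_prediction_case_matches_bruteforce(self):
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 0)]
        preds = [det(box(0, 0, 2, 2, 0), 0.9),     # TP
                 det(box(6, 0, 8, 2, 0), 0.7),     # FP
                 det(box(4, 4, 6, 6, 0), 0.6),     # TP
                 det(box(0, 6, 2, 8, 0), 0.2)]     # FP
        assert pr_curve(preds, truths) == brute_force_pr(preds, truths)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            pr_curve([det(box(0, 0, 2, 2, 0), 0.5)], [])


class TestAveragePrecision:
    def test_perfect_detector_ap_one(self):
        truths = [box(0, 0, 2, 2, 0), box(5, 5, 7, 7, 0)]
        preds = [det(truths[0], 0.9), det(truths[1], 0.8)]
        assert average_precision(pr_curve(preds, truths)) == pytest.approx(1.0)

    def test_zero_tp_gives_zero(self):
        truths = [box(0, 0, 2, 2, 0)]
        preds = [det(box(5, 5, 7, 7, 0), 0.9)]
        assert average_precision(pr_curve(preds, truths)) == 0.0

    def test_ranked_tp_fp_tp_hand_case(self):
        """Ranked [TP, FP, TP] over 2 truths.  Cuts give (1, .5), (.5, .5),
        (2/3, 1); the precision envelope is 1 on (0, .5] and 2/3 on
        (.5, 1] so AP = .5*1 + .5*(2/3) = 5/6 (value frozen from the
        brute-force envelope oracle below)."""
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 0)]
        preds = [det(box(0, 0, 2, 2, 0), 0.9),
                 det(box(6, 0, 8, 2, 0), 0.7),
                 det(box(4, 4, 6, 6, 0), 0.6)]
        points = pr_curve(preds, truths)
        ap = average_precision(points)
        assert ap == pytest.approx(5 / 6)
        assert ap == pytest.approx(brute_force_ap(points), abs=1e-4)

    def test_matches_bruteforce_on_random_cases(self, rng):
        for seed in range(10):
            gen = np.random.default_rng(seed)
            truths, preds = [], []
            for _ in range(gen.integers(1, 5)):
                x, y = gen.uniform(0, 7, 2)
                truths.append(box(x, y, x + 2, y + 2, 0))
            for _ in range(gen.integers(1, 7)):
                x, y = gen.uniform(0, 7, 2)
                preds.append(det(box(x, y, x + 2, y + 2, 0),
                                 round(float(gen.random()), 3)))
            points = pr_curve(preds, truths)
            assert average_precision(points) == pytest.approx(
                brute_force_ap(points), abs=1e-4)

    def test_ap_bounds_and_monotone_in_threshold(self):
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 0)]
        preds = [det(box(0, 0, 2, 1.6, 0), 0.9),   # IoU 0.8 with truth 1
                 det(box(4, 4, 6, 5, 0), 0.8)]     # IoU 0.5 with truth 2
        last = 1.1
        for thr in (0.3, 0.5, 0.7, 0.9):
            ap = average_precision(pr_curve(preds, truths, thr))
            assert 0.0 <= ap <= 1.0
            assert ap <= last + 1e-12
            last = ap

    def test_permutation_invariance_at_equal_confidence(self):
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 0)]
        base = [det(box(0, 0, 2, 2, 0), 0.5), det(box(4, 4, 6, 6, 0), 0.5),
                det(box(7, 7, 9, 9, 0), 0.5)]
        aps = set()
        for perm in itertools.permutations(base):
            aps.add(round(average_precision(pr_curve(list(perm), truths)), 12))
        assert len(aps) == 1


class TestMap:
    def test_perfect_map_one(self):
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 1)]
        preds = [det(truths[0], 0.9), det(truths[1], 0.8)]
        report = evaluate(preds, truths)
        assert report["map"] == pytest.approx(1.0)
        assert set(report["per_class_ap"]) == {0, 1}

    def test_mean_over_truth_classes_only(self):
        truths = [box(0, 0, 2, 2, 0), box(4, 4, 6, 6, 1)]
        preds = [det(truths[0], 0.9),
                 det(box(7, 7, 9, 9, 3), 0.8)]  # class absent from truth
        report = evaluate(preds, truths)
        assert set(report["per_class_ap"]) == {0, 1}
        assert report["map"] == pytest.approx(0.5)

    def test_map50_empty(self):
        assert map50({}) == 0.0
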