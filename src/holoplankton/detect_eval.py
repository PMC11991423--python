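"""Detection scoring against YOLO-format ground truth.

Greedy confidence-ordered matching in the Pascal-VOC style: predictions
are ranked by descending confidence, each claims the highest-IoU unused
ground-truth box of its class, and counts as a true positive when the
overlap reaches the IoU threshold (inclusive ``>= 0.5`` by default).
AP uses all-point interpolation -- the area under the running-maximum
precision envelope as a function of recall -- and mAP averages AP over
the classes present in the ground truth.

A "true negative" has no standard meaning for detection boxes and is
never counted here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .io import YoloRecord

__all__ = [
    "Detection",
    "MatchResult",
    "iou",
    "match_detections",
    "pr_curve",
    "average_precision",
    "map50",
    "evaluate",
]


@dataclass(frozen=True)
class Detection:
    """One predicted box with its class and confidence score."""

    class_id: int
    box: YoloRecord
    confidence: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")


@dataclass
class MatchResult:
    tp: dict[int, int] = field(default_factory=dict)
    fp: dict[int, int] = field(default_factory=dict)
    fn: dict[int, int] = field(default_factory=dict)
    pairs: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, truth, IoU)

    def precision(self, class_id: int | None = None) -> float:
        tp, fp = self._totals(class_id)[:2]
        return tp / (tp + fp) if tp + fp else 0.0

    def recall(self, class_id: int | None = None) -> float:
        tp, _, fn = self._totals(class_id)
        return tp / (tp + fn) if tp + fn else 0.0

    def _totals(self, class_id: int | None):
        if class_id is None:
            return (sum(self.tp.values()), sum(self.fp.values()),
                    sum(self.fn.values()))
        return (self.tp.get(class_id, 0), self.fp.get(class_id, 0),
                self.fn.get(class_id, 0))


def iou(box_a: YoloRecord, box_b: YoloRecord) -> float:
    """Intersection-over-union of two center-form boxes; 0 when disjoint
    or when either box has zero area."""
    ax0, ay0, ax1, ay1 = box_a.corners()
    bx0, by0, bx1, by1 = box_b.corners()
    area_a = max(ax1 - ax0, 0.0) * max(ay1 - ay0, 0.0)
    area_b = max(bx1 - bx0, 0.0) * max(by1 - by0, 0.0)
    if area_a == 0.0 or area_b == 0.0:
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def _accepts(overlap: float, threshold: float, inclusive: bool) -> bool:
    return overlap >= threshold if inclusive else overlap > threshold


def _rank(preds: list[Detection]) -> list[int]:
    """Indices of predictions by descending confidence, input order on ties."""
    return sorted(range(len(preds)), key=lambda i: (-preds[i].confidence, i))


def _greedy_flags(preds: list[Detection], truths: list[YoloRecord],
                  iou_threshold: float, inclusive: bool):
    """Per-ranked-prediction TP flags plus the matched (pred, truth, IoU) pairs."""
    order = _rank(preds)
    used = [False] * len(truths)
    flags: list[bool] = []
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        det = preds[pi]
        best_j, best_ov = -1, -1.0
        for j, gt in enumerate(truths):
            if used[j] or gt.class_id != det.class_id:
                continue
            ov = iou(det.box, gt)
            if ov > best_ov:
                best_j, best_ov = j, ov
        if best_j >= 0 and _accepts(best_ov, iou_threshold, inclusive):
            used[best_j] = True
            flags.append(True)
            pairs.append((pi, best_j, best_ov))
        else:
            flags.append(False)
    return order, flags, pairs


def match_detections(preds: list[Detection], truths: list[YoloRecord],
                     iou_threshold: float = 0.5,
                     inclusive: bool = True) -> MatchResult:
    """Match predictions to ground truth at a fixed IoU threshold.

    Satisfies the counting identities ``TP + FN = |truth|`` and
    ``TP + FP = |preds|`` per class.
    """
    if not (0.0 < iou_threshold < 1.0):
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    order, flags, pairs = _greedy_flags(preds, truths, iou_threshold, inclusive)
    result = MatchResult(pairs=pairs)
    classes = {d.class_id for d in preds} | {t.class_id for t in truths}
    for c in classes:
        result.tp[c] = result.fp[c] = 0
        result.fn[c] = sum(1 for t in truths if t.class_id == c)
    for pi, flag in zip(order, flags):
        c = preds[pi].class_id
        if flag:
            result.tp[c] += 1
            result.fn[c] -= 1
        else:
            result.fp[c] += 1
    return result


def pr_curve(preds: list[Detection], truths: list[YoloRecord],
             iou_threshold: float = 0.5,
             inclusive: bool = True) -> list[tuple[float, float]]:
    """(precision, recall) at every distinct confidence cut, highest first.

    Matching is decided once over the full ranked list; each cut keeps the
    top-ranked predictions, so recall is non-decreasing along the sweep.
    """
    if not truths:
        raise ValueError("ground truth is empty: recall is undefined")
    if not preds:
        return []
    order, flags, _ = _greedy_flags(preds, truths, iou_threshold, inclusive)
    n_truth = len(truths)
    points: list[tuple[float, float]] = []
    tp = fp = 0
    for rank, (pi, flag) in enumerate(zip(order, flags)):
        tp += int(flag)
        fp += int(not flag)
        last_of_cut = (rank == len(order) - 1
                       or preds[order[rank + 1]].confidence != preds[pi].confidence)
        if last_of_cut:
            points.append((tp / (tp + fp), tp / n_truth))
    return points


def average_precision(points: list[tuple[float, float]]) -> float:
    """All-point-interpolated AP: area under the precision envelope vs recall."""
    if not points:
        return 0.0
    pts = sorted(points, key=lambda pr: pr[1])
    recalls = [0.0] + [r for _, r in pts]
    envelope = []
    for i in range(len(pts)):
        envelope.append(max(p for p, r in pts[i:]))  # running max from the right
    ap = 0.0
    for i, (dr, env) in enumerate(zip(
            (recalls[i + 1] - recalls[i] for i in range(len(pts))), envelope)):
        ap += dr * env
    return ap


def map50(per_class_ap: dict[int, float]) -> float:
    """Unweighted mean AP over the classes present in the ground truth."""
    if not per_class_ap:
        return 0.0
    return sum(per_class_ap.values()) / len(per_class_ap)


def evaluate(preds: list[Detection], truths: list[YoloRecord],
             iou_threshold: float = 0.5,
             inclusive: bool = True) -> dict:
    """Per-class AP/precision/recall plus mAP at the given threshold."""
    classes = sorted({t.class_id for t in truths})
    per_class_ap: dict[int, float] = {}
    for c in classes:
        c_preds = [p for p in preds if p.class_id == c]
        c_truths = [t for t in truths if t.class_id == c]
        pts = pr_curve(c_preds, c_truths, iou_threshold, inclusive) if c_preds else []
        per_class_ap[c] = average_precision(pts)
    match = match_detections(preds, truths, iou_threshold, inclusive)
    return {
        "per_class_ap": per_class_ap,
        "map": map50(per_class_ap),
        "precision": {c: match.precision(c) for c in classes},
        "recall": {c: match.recall(c) for c in classes},
        "match": match,
    }
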