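"""Object-detection evaluation: IoU matching, precision/recall, AP and mAP.

Detections are matched to ground truth greedily in descending confidence
order, the VOC/COCO convention: each detection claims the highest-IoU
still-unmatched ground-truth box of the same class in the same image,
provided IoU >= threshold; a ground truth can be claimed once.  Precision =
TP/(TP+FP), recall = TP/n_gt.  Average precision integrates the precision
envelope over recall (all-point interpolation by default; COCO's 101-point
grid is available behind ``interpolation="101point"``); AP@[0.5:0.95] is the
mean of AP at IoU thresholds 0.50, 0.55, ..., 0.95.

Edge conventions, chosen explicitly: with no detections precision is vacuously
1.0; with no ground truth and no false positives recall is vacuously 1.0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .annotations import BoundingBox

__all__ = [
    "Detection",
    "PRCurve",
    "EvalReport",
    "iou",
    "match_detections",
    "precision_recall",
    "average_precision",
    "evaluate",
    "COCO_THRESHOLDS",
]

#: The ten IoU thresholds averaged by AP@[0.5:0.95].
COCO_THRESHOLDS = tuple(np.round(np.arange(0.50, 0.96, 0.05), 2))


@dataclass(frozen=True)
class Detection:
    image_id: str
    class_index: int
    confidence: float
    box: BoundingBox

    def __post_init__(self) -> None:
        if not 0 <= self.confidence <= 1:
            raise ValueError(f"confidence out of [0,1]: {self.confidence}")


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    class_index: int
    box: BoundingBox


@dataclass
class PRCurve:
    """Precision/recall pairs along the descending-confidence sweep."""

    recall: np.ndarray
    precision: np.ndarray
    n_gt: int


@dataclass
class EvalReport:
    """Per-class and macro-averaged detection metrics."""

    per_class: dict[int, dict[str, float]]
    precision: float
    recall: float
    ap50: float
    ap50_95: float
    ignored_classes: list[int] = field(default_factory=list)


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection over union of two half-open boxes; 0 when disjoint."""
    ix = max(0.0, min(a.x1, b.x1) - max(a.x0, b.x0))
    iy = max(0.0, min(a.y1, b.y1) - max(a.y0, b.y0))
    inter = ix * iy
    if inter == 0:
        return 0.0
    union = a.area + b.area - inter
    return inter / union


def match_detections(dets, gts, iou_threshold: float) -> list[bool]:
    """Greedy confidence-ordered matching; returns per-detection TP flags.

    ``dets`` are processed in descending confidence (ties broken by input
    order); ``gts`` within one image/class can each be matched at most once.
    The returned flags follow the *sorted* detection order, matching the
    order used by :func:`precision_recall`.
    """
    order = sorted(range(len(dets)), key=lambda i: -dets[i].confidence)
    used = [False] * len(gts)
    by_key: dict[tuple[str, int], list[int]] = {}
    for j, g in enumerate(gts):
        by_key.setdefault((g.image_id, g.class_index), []).append(j)

    flags = []
    for i in order:
        d = dets[i]
        best_j, best_iou = -1, 0.0
        for j in by_key.get((d.image_id, d.class_index), ()):
            if used[j]:
                continue
            v = iou(d.box, gts[j].box)
            if v > best_iou:
                best_iou, best_j = v, j
        if best_j >= 0 and best_iou >= iou_threshold:
            used[best_j] = True
            flags.append(True)
        else:
            flags.append(False)
    return flags


def precision_recall(flags, n_gt: int) -> tuple[float, float, PRCurve]:
    """Final precision/recall plus the cumulative PR curve.

    ``flags`` are TP booleans in descending-confidence order.  Vacuous
    conventions: no detections -> precision 1.0; n_gt == 0 -> recall 1.0 if
    there are also no false positives, else recall 0 contributes nothing
    (curve is empty).
    """
    if n_gt < 0:
        raise ValueError("n_gt must be >= 0")
    flags = np.asarray(list(flags), dtype=bool)
    tp = np.cumsum(flags)
    fp = np.cumsum(~flags)
    with np.errstate(invalid="ignore", divide="ignore"):
        prec = tp / (tp + fp)
        rec = tp / n_gt if n_gt > 0 else np.ones_like(tp, dtype=float)
    curve = PRCurve(recall=rec.astype(float), precision=prec.astype(float), n_gt=n_gt)

    if len(flags) == 0:
        precision = 1.0
        recall = 1.0 if n_gt == 0 else 0.0
    else:
        precision = float(tp[-1] / (tp[-1] + fp[-1]))
        recall = float(tp[-1] / n_gt) if n_gt > 0 else (1.0 if fp[-1] == 0 else 0.0)
    return precision, recall, curve


def average_precision(curve: PRCurve, interpolation: str = "allpoint") -> float:
    """Area under the interpolated precision envelope.

    ``allpoint``: precision at each recall is replaced by the maximum
    precision at any recall >= it, then integrated exactly over recall.
    ``101point``: the envelope is sampled on COCO's 101 equally spaced recall
    points and averaged.
    """
    if curve.n_gt == 0 or len(curve.recall) == 0:
        return 0.0
    rec = np.concatenate([[0.0], curve.recall, [1.0]])
    prec = np.concatenate([[1.0], curve.precision, [0.0]])
    # precision envelope: running max from the right
    env = np.maximum.accumulate(prec[::-1])[::-1]
    if interpolation == "allpoint":
        idx = np.where(rec[1:] != rec[:-1])[0]
        return float(np.sum((rec[idx + 1] - rec[idx]) * env[idx + 1]))
    if interpolation == "101point":
        # sample the envelope as a right-continuous step: precision at the
        # first achieved recall >= each grid point, 0 past the last recall
        grid = np.linspace(0.0, 1.0, 101)
        idx = np.searchsorted(rec, grid, side="left")
        sampled = np.where(idx < len(rec), env[np.minimum(idx, len(rec) - 1)], 0.0)
        return float(sampled.mean())
    raise ValueError(f"unknown interpolation {interpolation!r}")


def _class_metrics(dets, gts, thr, interpolation):
    flags = match_detections(dets, gts, thr)
    precision, recall, curve = precision_recall(flags, len(gts))
    return precision, recall, average_precision(curve, interpolation)


def evaluate(
    dets,
    gts,
    thresholds=COCO_THRESHOLDS,
    primary_threshold: float = 0.5,
    interpolation: str = "allpoint",
) -> EvalReport:
    """Full evaluation report: per-class and macro precision/recall/AP.

    Precision and recall are reported at ``primary_threshold``;
    ``ap50_95`` averages AP over ``thresholds``.  Classes present only in the
    detections contribute false positives to nothing here — they are excluded
    from the macro-average and listed in ``ignored_classes``.
    """
    gt_classes = sorted({g.class_index for g in gts})
    det_classes = {d.class_index for d in dets}
    ignored = sorted(det_classes - set(gt_classes))

    per_class: dict[int, dict[str, float]] = {}
    for c in gt_classes:
        cdets = [d for d in dets if d.class_index == c]
        cgts = [g for g in gts if g.class_index == c]
        precision, recall, ap50 = _class_metrics(
            cdets, cgts, primary_threshold, interpolation
        )
        aps = [
            _class_metrics(cdets, cgts, t, interpolation)[2] for t in thresholds
        ]
        per_class[c] = {
            "precision": precision,
            "recall": recall,
            "ap50": ap50,
            "ap50_95": float(np.mean(aps)) if aps else 0.0,
        }

    if per_class:
        macro = {
            k: float(np.mean([m[k] for m in per_class.values()]))
            for k in ("precision", "recall", "ap50", "ap50_95")
        }
    else:
        macro = {"precision": 1.0, "recall": 1.0, "ap50": 0.0, "ap50_95": 0.0}
    return EvalReport(
        per_class=per_class,
        precision=macro["precision"],
        recall=macro["recall"],
        ap50=macro["ap50"],
        ap50_95=macro["ap50_95"],
        ignored_classes=ignored,
    )
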