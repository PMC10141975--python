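"""Evaluation metrics for the three pipeline stages.

Detection: precision P = TP/(TP+FP), recall R = TP/(TP+FN), average
precision AP (area under the precision-recall curve, all-points
interpolation, greedy confidence-ordered matching at an IoU threshold), and
mAP (unweighted mean over classes).

Segmentation: pixel-level per-class P, R, IoU = TP/(TP+FP+FN), and MIoU
(mean IoU over the k+1 classes, background included).

Endpoints: DE, the mean of the two per-endpoint Euclidean distances between
prediction and ground truth (pixels); AE, the absolute difference of the two
long-axis angles reduced modulo 180 degrees to [0, 90] (slope arctangents
are direction-free axis angles, so naive subtraction would report spurious
~180 degree errors for near-vertical axes); and CA = T/(T+F), the fraction
of individual head/root label decisions that are correct.
"""

from __future__ import annotations

import csv
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .mask import BinaryMask
from .pipeline import EndpointPair

__all__ = [
    "ConfusionCounts",
    "GroundTruthBox",
    "PredictedBox",
    "DetectionImage",
    "DetectionSet",
    "EndpointEvalRecord",
    "ClassPixelMetrics",
    "SegmentationReport",
    "EvalReport",
    "box_iou",
    "precision_recall",
    "average_precision",
    "mean_average_precision",
    "segmentation_metrics",
    "distance_error",
    "angle_error",
    "endpoint_label_outcomes",
    "classification_accuracy",
    "evaluate_endpoints",
]

Box = tuple[float, float, float, float]  # half-open (x_min, y_min, x_max, y_max)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int = 0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


@dataclass(frozen=True)
class GroundTruthBox:
    class_id: int
    box: Box

    def __post_init__(self) -> None:
        _check_box(self.box)


@dataclass(frozen=True)
class PredictedBox:
    class_id: int
    confidence: float
    box: Box

    def __post_init__(self) -> None:
        _check_box(self.box)
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")


@dataclass
class DetectionImage:
    ground_truth: list[GroundTruthBox] = field(default_factory=list)
    predictions: list[PredictedBox] = field(default_factory=list)


@dataclass
class DetectionSet:
    """Per-image predicted and ground-truth boxes for detection scoring."""

    images: list[DetectionImage] = field(default_factory=list)

    def class_ids(self) -> list[int]:
        ids = {g.class_id for im in self.images for g in im.ground_truth}
        return sorted(ids)


@dataclass(frozen=True)
class EndpointEvalRecord:
    """A predicted endpoint pair next to its ground truth (same frame)."""

    predicted: EndpointPair
    truth: EndpointPair


def _check_box(box: Box) -> None:
    x0, y0, x1, y1 = box
    if not (x1 > x0 and y1 > y0):
        raise ValueError(f"box {box} has non-positive area")


def box_iou(b1: Box, b2: Box) -> float:
    """IoU of two half-open axis-aligned rectangles."""
    ix = max(0.0, min(b1[2], b2[2]) - max(b1[0], b2[0]))
    iy = max(0.0, min(b1[3], b2[3]) - max(b1[1], b2[1]))
    inter = ix * iy
    if inter == 0.0:
        return 0.0
    a1 = (b1[2] - b1[0]) * (b1[3] - b1[1])
    a2 = (b2[2] - b2[0]) * (b2[3] - b2[1])
    return inter / (a1 + a2 - inter)


def precision_recall(c: ConfusionCounts) -> tuple[Optional[float], Optional[float]]:
    """(P, R); an undefined metric (empty denominator) is returned as None."""
    p = c.tp / (c.tp + c.fp) if c.tp + c.fp > 0 else None
    r = c.tp / (c.tp + c.fn) if c.tp + c.fn > 0 else None
    if p is None:
        warnings.warn("precision undefined: no predicted positives", stacklevel=2)
    if r is None:
        warnings.warn("recall undefined: no ground-truth positives", stacklevel=2)
    return p, r


def _match_outcomes(d: DetectionSet, class_id: int, iou_threshold: float) -> tuple[np.ndarray, np.ndarray, int]:
    """Confidence-sorted TP/FP outcomes for one class, plus GT count.

    Greedy matching: predictions in descending confidence order each claim
    the highest-IoU unmatched ground truth of their class when that IoU
    reaches the threshold; duplicates of an already-claimed truth count as
    false positives.
    """
    entries: list[tuple[float, int, Box]] = []
    gts: list[list[Box]] = []
    for idx, im in enumerate(d.images):
        gts.append([g.box for g in im.ground_truth if g.class_id == class_id])
        for p in im.predictions:
            if p.class_id == class_id:
                entries.append((p.confidence, idx, p.box))
    n_gt = sum(len(g) for g in gts)
    entries.sort(key=lambda e: -e[0])
    matched = [np.zeros(len(g), dtype=bool) for g in gts]
    conf = np.array([e[0] for e in entries])
    is_tp = np.zeros(len(entries), dtype=bool)
    for i, (_, idx, box) in enumerate(entries):
        best_iou, best_j = 0.0, -1
        for j, gbox in enumerate(gts[idx]):
            iou = box_iou(box, gbox)
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold and not matched[idx][best_j]:
            matched[idx][best_j] = True
            is_tp[i] = True
    return conf, is_tp, n_gt


def average_precision(d: DetectionSet, class_id: int, iou_threshold: float = 0.5) -> Optional[float]:
    """Area under the precision-recall curve for one class.

    Uses all-points interpolation: the exact integral of the precision
    envelope over recall.  Returns None when the class has no ground truth.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError(f"iou_threshold must lie in (0, 1), got {iou_threshold}")
    _, is_tp, n_gt = _match_outcomes(d, class_id, iou_threshold)
    if n_gt == 0:
        return None
    if is_tp.size == 0:
        return 0.0
    tp_cum = np.cumsum(is_tp)
    fp_cum = np.cumsum(~is_tp)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # Precision envelope (running max from the right), integrated exactly.
    r = np.concatenate([[0.0], recall])
    p = np.concatenate([[1.0], precision])
    for i in range(p.size - 2, -1, -1):
        p[i] = max(p[i], p[i + 1])
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def mean_average_precision(d: DetectionSet, iou_threshold: float = 0.5) -> float:
    """Unweighted mean AP over the classes that have ground truth."""
    aps = [
        ap
        for cid in d.class_ids()
        if (ap := average_precision(d, cid, iou_threshold)) is not None
    ]
    if not aps:
        raise ValueError("no class has ground truth")
    return float(np.mean(aps))


@dataclass(frozen=True)
class ClassPixelMetrics:
    counts: ConfusionCounts
    precision: Optional[float]
    recall: Optional[float]
    iou: Optional[float]


@dataclass(frozen=True)
class SegmentationReport:
    per_class: dict[int, ClassPixelMetrics]
    miou: float


def segmentation_metrics(pred_mask: BinaryMask | np.ndarray, gt_mask: BinaryMask | np.ndarray) -> SegmentationReport:
    """Pixel-level P, R, IoU per class (0 = background, 1 = fruit) and MIoU.

    MIoU averages IoU over both classes; an undefined per-class IoU (class
    absent from both masks) contributes 1.0, matching the empty-set
    convention of identical masks.
    """
    pred = pred_mask.values if isinstance(pred_mask, BinaryMask) else np.asarray(pred_mask)
    gt = gt_mask.values if isinstance(gt_mask, BinaryMask) else np.asarray(gt_mask)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    per_class: dict[int, ClassPixelMetrics] = {}
    ious: list[float] = []
    for cls in (0, 1):
        p = pred == cls
        g = gt == cls
        tp = int(np.logical_and(p, g).sum())
        fp = int(np.logical_and(p, ~g).sum())
        fn = int(np.logical_and(~p, g).sum())
        tn = int(np.logical_and(~p, ~g).sum())
        counts = ConfusionCounts(tp, fp, fn, tn)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prec, rec = precision_recall(counts)
        denom = tp + fp + fn
        iou = tp / denom if denom > 0 else None
        per_class[cls] = ClassPixelMetrics(counts, prec, rec, iou)
        ious.append(iou if iou is not None else 1.0)
    return SegmentationReport(per_class=per_class, miou=float(np.mean(ious)))


def distance_error(r: EndpointEvalRecord) -> float:
    """Mean of the two per-endpoint Euclidean distances, in pixels.

    Head is compared to head and root to root; labels must already be
    assigned.  Symmetric under swapping prediction and ground truth.
    """
    dh = math.dist(
        (r.predicted.head.x, r.predicted.head.y), (r.truth.head.x, r.truth.head.y)
    )
    dr = math.dist(
        (r.predicted.root.x, r.predicted.root.y), (r.truth.root.x, r.truth.root.y)
    )
    return (dh + dr) / 2.0


def _axis_angle_deg(pair: EndpointPair) -> float:
    dx = pair.head.x - pair.root.x
    dy = pair.head.y - pair.root.y
    if dx == 0.0 and dy == 0.0:
        raise ValueError("coincident endpoints have no axis angle")
    return math.degrees(math.atan2(dy, dx)) % 180.0


def angle_error(r: EndpointEvalRecord) -> float:
    """Absolute long-axis angle difference in degrees, reduced to [0, 90]."""
    diff = abs(_axis_angle_deg(r.predicted) - _axis_angle_deg(r.truth)) % 180.0
    return min(diff, 180.0 - diff)


def endpoint_label_outcomes(r: EndpointEvalRecord) -> tuple[bool, bool]:
    """Correctness of the two label decisions in one record.

    Each predicted endpoint is matched to its nearest ground-truth endpoint;
    the decision is correct when the nearest truth carries the same label.
    """
    gt_head = np.array([r.truth.head.x, r.truth.head.y])
    gt_root = np.array([r.truth.root.x, r.truth.root.y])
    ph = np.array([r.predicted.head.x, r.predicted.head.y])
    pr = np.array([r.predicted.root.x, r.predicted.root.y])
    head_ok = np.linalg.norm(ph - gt_head) <= np.linalg.norm(ph - gt_root)
    root_ok = np.linalg.norm(pr - gt_root) <= np.linalg.norm(pr - gt_head)
    return bool(head_ok), bool(root_ok)


def classification_accuracy(outcomes: Sequence[bool]) -> float:
    """T / (T + F) over individual endpoint label decisions."""
    if len(outcomes) == 0:
        raise ValueError("no label outcomes to aggregate")
    return float(np.mean(np.asarray(outcomes, dtype=bool)))


@dataclass(frozen=True)
class EvalReport:
    """Aggregated dataset-level metrics across the three stages."""

    detection_ap: dict[int, Optional[float]] = None
    detection_map: Optional[float] = None
    segmentation_miou: Optional[float] = None
    mean_de: Optional[float] = None
    mean_ae: Optional[float] = None
    ca: Optional[float] = None


def evaluate_endpoints(records: Iterable[EndpointEvalRecord]) -> tuple[float, float, float]:
    """Dataset-level (mean DE, mean AE, CA) over endpoint records."""
    des, aes, outcomes = [], [], []
    for r in records:
        des.append(distance_error(r))
        aes.append(angle_error(r))
        outcomes.extend(endpoint_label_outcomes(r))
    if not des:
        raise ValueError("no endpoint records")
    return float(np.mean(des)), float(np.mean(aes)), classification_accuracy(outcomes)


def write_report_csv(path: str, rows: list[dict]) -> None:
    """Write per-class and aggregate metric rows to CSV."""
    if not rows:
        raise ValueError("no rows to write")
    keys: list[str] = []
    for row in rows:
        for k in row:
            if k not in keys:
                keys.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=keys)
        writer.writeheader()
        writer.writerows(rows)
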