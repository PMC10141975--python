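"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results through different algorithms and code
paths than the package: the ellipse-fit oracle solves the full 6x6
constrained generalized eigenproblem with a dense decomposition (the
package uses the partitioned 3x3 reduction), and the AP oracle enumerates
every confidence threshold and integrates the exact PR staircase point by
point (the package integrates cumulative-count vectors).
"""

from __future__ import annotations

import numpy as np
import scipy.linalg


def fit_ellipse_oracle(points: np.ndarray) -> np.ndarray:
    """Constrained least-squares conic via dense generalized eigensolve.

    Minimizes ||H s||^2 subject to s^T K s = 1 with the ellipse constraint
    matrix K (4AC - B^2 = 1).  Points are centered and scaled for
    conditioning; the conic is mapped back by conjugating its 3x3 matrix
    form with the affine transform.  Returns a unit-norm coefficient
    vector (A, B, C, D, E, F).
    """
    pts = np.asarray(points, dtype=float)
    mean = pts.mean(axis=0)
    scale = float(np.sqrt(np.mean(np.sum((pts - mean) ** 2, axis=1))))
    u = (pts - mean) / scale

    x, y = u[:, 0], u[:, 1]
    h = np.column_stack([x * x, x * y, y * y, x, y, np.ones_like(x)])
    s_mat = h.T @ h
    k = np.zeros((6, 6))
    k[0, 2] = k[2, 0] = 2.0
    k[1, 1] = -1.0

    eigvals, eigvecs = scipy.linalg.eig(s_mat, k)
    best = None
    for i in range(6):
        if not np.isfinite(eigvals[i]) or abs(eigvals[i].imag) > 1e-9 * (
            1 + abs(eigvals[i].real)
        ):
            continue
        v = np.real(eigvecs[:, i])
        cons = v @ k @ v  # = 4AC - B^2 (times 2 symmetry factors folded in)
        if cons <= 0:
            continue
        v = v / np.sqrt(cons)
        cost = float(v @ s_mat @ v)
        if best is None or cost < best[0]:
            best = (cost, v)
    if best is None:
        raise ValueError("oracle found no elliptical solution")
    a, b, c, d, e, f = best[1]

    # Map conic back through p = M u + mean with M = scale * I, using the
    # 3x3 homogeneous matrix form Q' -> T^{-T} Q' T^{-1} conjugation.
    q = np.array([[a, b / 2, d / 2], [b / 2, c, e / 2], [d / 2, e / 2, f]])
    t_inv = np.array(
        [
            [1.0 / scale, 0.0, -mean[0] / scale],
            [0.0, 1.0 / scale, -mean[1] / scale],
            [0.0, 0.0, 1.0],
        ]
    )
    q_orig = t_inv.T @ q @ t_inv
    vec = np.array(
        [
            q_orig[0, 0],
            2.0 * q_orig[0, 1],
            q_orig[1, 1],
            2.0 * q_orig[0, 2],
            2.0 * q_orig[1, 2],
            q_orig[2, 2],
        ]
    )
    vec = vec / np.linalg.norm(vec)
    if vec[0] + vec[2] < 0:
        vec = -vec
    return vec


def _rect_iou(b1, b2) -> float:
    w = min(b1[2], b2[2]) - max(b1[0], b2[0])
    h = min(b1[3], b2[3]) - max(b1[1], b2[1])
    if w <= 0 or h <= 0:
        return 0.0
    inter = w * h
    area1 = (b1[2] - b1[0]) * (b1[3] - b1[1])
    area2 = (b2[2] - b2[0]) * (b2[3] - b2[1])
    return inter / (area1 + area2 - inter)


def _count_at_threshold(images, class_id, conf_threshold, iou_threshold):
    """(TP, n_pred) over predictions with confidence >= conf_threshold."""
    tp = 0
    n_pred = 0
    for gt_boxes, preds in images:
        kept = [p for p in preds if p[0] >= conf_threshold]
        kept.sort(key=lambda p: -p[0])
        claimed = [False] * len(gt_boxes)
        for conf, box in kept:
            n_pred += 1
            ious = [_rect_iou(box, g) for g in gt_boxes]
            order = sorted(range(len(gt_boxes)), key=lambda j: -ious[j])
            for j in order:
                if ious[j] >= iou_threshold and not claimed[j]:
                    claimed[j] = True
                    tp += 1
                    break
                break  # only the best-IoU truth is considered
    return tp, n_pred


def average_precision_oracle(detection_set, class_id, iou_threshold=0.5):
    """Exhaustive threshold-enumeration AP with exact envelope integration."""
    images = []
    confs = set()
    n_gt = 0
    for im in detection_set.images:
        gt_boxes = [g.box for g in im.ground_truth if g.class_id == class_id]
        preds = [
            (p.confidence, p.box) for p in im.predictions if p.class_id == class_id
        ]
        n_gt += len(gt_boxes)
        confs.update(c for c, _ in preds)
        images.append((gt_boxes, preds))
    if n_gt == 0:
        return None
    points = [(0.0, 1.0)]
    for t in sorted(confs, reverse=True):
        tp, n_pred = _count_at_threshold(images, class_id, t, iou_threshold)
        if n_pred > 0:
            points.append((tp / n_gt, tp / n_pred))
    recalls = sorted({r for r, _ in points})
    ap = 0.0
    prev_r = 0.0
    for r in recalls:
        if r <= prev_r:
            continue
        envelope = max(p for rr, p in points if rr >= r)
        ap += (r - prev_r) * envelope
        prev_r = r
    return ap
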