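"""Seeded generator of fruit-like scenes and toy detection sets.

A scene emulates one detector crop of an elongated fruit seen from the
side: a filled elliptical mask with optional smooth boundary noise, speckle
distractors and an occlusion bite, plus a paired RGB image in which a
bright cue (an attached flower) is planted near the head endpoint.  Every
scene carries its generating ellipse and labeled endpoints, so each
pipeline stage can be scored against exact ground truth without any
external dataset.

Boundary noise is a low-order Fourier perturbation of the radius function
(smooth, fruit-like undulation rather than pixel salt); its RMS radial
displacement equals ``boundary_sigma`` pixels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .ellipse import EllipseParams, PlanePoint, long_axis_endpoints
from .mask import BinaryMask
from .metrics import Box, DetectionImage, DetectionSet, GroundTruthBox, PredictedBox

__all__ = [
    "SceneConfig",
    "SyntheticScene",
    "generate_scene",
    "DetectionSetConfig",
    "generate_detection_set",
    "expected_average_precision",
]

FRUIT_COLOR = (196, 58, 90)
BACKGROUND_COLOR = (38, 66, 42)
CUE_COLOR = (255, 244, 180)


@dataclass(frozen=True)
class SceneConfig:
    """Study conditions for one synthetic crop.

    Canvas defaults to 224 x 224 (the working resolution of the
    segmentation stage the pipeline sits behind).  Semi-major axes of
    40-70 px with elongation (a/b) 1.6-2.6 give fruit that fill a realistic
    fraction of the crop while keeping a clearly elongated long axis.
    """

    height: int = 224
    width: int = 224
    semi_major_range: tuple[float, float] = (40.0, 70.0)
    elongation_range: tuple[float, float] = (1.6, 2.6)
    center_jitter: float = 10.0
    boundary_sigma: float = 0.0
    speck_count: int = 0
    bite_fraction: float = 0.0
    cue_radius: float = 5.0
    noise_harmonics: tuple[int, ...] = (2, 3, 4)


@dataclass(frozen=True)
class SyntheticScene:
    image: np.ndarray  # (h, w, 3) uint8
    mask: BinaryMask
    true_ellipse: EllipseParams
    true_head: PlanePoint
    true_root: PlanePoint
    noise_spec: tuple[float, int, float]  # (boundary sigma px, specks, bite fraction)
    seed: int


def _render_mask(cfg: SceneConfig, e: EllipseParams, coeffs: np.ndarray, phases: np.ndarray) -> np.ndarray:
    """Filled perturbed ellipse: inside iff normalized radius <= 1 + d/r."""
    xs = np.arange(cfg.width, dtype=float)
    ys = np.arange(cfg.height, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = (gx - e.cx) * ct + (gy - e.cy) * st
    v = -(gx - e.cx) * st + (gy - e.cy) * ct
    m = np.sqrt((u / e.a) ** 2 + (v / e.b) ** 2)
    if coeffs.size == 0 or not np.any(coeffs):
        return (m <= 1.0).astype(np.uint8)
    t = np.arctan2(v / e.b, u / e.a)
    delta = np.zeros_like(m)
    for k, c, ph in zip(cfg.noise_harmonics, coeffs, phases):
        delta += c * np.cos(k * t + ph)
    # Radial distance from center to the unperturbed boundary along t.
    r_t = np.sqrt((e.a * np.cos(t)) ** 2 + (e.b * np.sin(t)) ** 2)
    return (m <= 1.0 + delta / r_t).astype(np.uint8)


def _stamp_disc(grid: np.ndarray, cx: float, cy: float, radius: float, value: int) -> None:
    h, w = grid.shape[:2]
    y0, y1 = max(0, int(cy - radius - 1)), min(h, int(cy + radius + 2))
    x0, x1 = max(0, int(cx - radius - 1)), min(w, int(cx + radius + 2))
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    inside = (xx - cx) ** 2 + (yy - cy) ** 2 <= radius**2
    grid[y0:y1, x0:x1][inside] = value


def generate_scene(config: SceneConfig | None = None, seed: int = 0) -> SyntheticScene:
    """Generate one seeded scene; the same seed is bit-identical.

    Raises
    ------
    ValueError
        Infeasible configuration: the sampled ellipse cannot fit on the
        canvas with its endpoints inside.
    """
    cfg = config or SceneConfig()
    rng = np.random.default_rng(seed)
    a_lo, a_hi = cfg.semi_major_range
    if a_hi + cfg.center_jitter + 4 >= min(cfg.height, cfg.width) / 2.0:
        raise ValueError(
            f"ellipse (a up to {a_hi}) cannot fit a {cfg.height}x{cfg.width} canvas"
        )
    cx = cfg.width / 2.0 + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
    cy = cfg.height / 2.0 + rng.uniform(-cfg.center_jitter, cfg.center_jitter)
    a = rng.uniform(a_lo, a_hi)
    b = a / rng.uniform(*cfg.elongation_range)
    theta = rng.uniform(0.0, math.pi)
    ellipse = EllipseParams(cx, cy, a, b, theta)

    n_harm = len(cfg.noise_harmonics)
    if cfg.boundary_sigma > 0:
        raw = rng.standard_normal(n_harm)
        rms = math.sqrt(float(np.sum(raw**2)) / 2.0)
        coeffs = raw * (cfg.boundary_sigma / rms) if rms > 0 else np.zeros(n_harm)
        phases = rng.uniform(0.0, 2.0 * math.pi, n_harm)
    else:
        coeffs = np.zeros(n_harm)
        phases = np.zeros(n_harm)
    mask_vals = _render_mask(cfg, ellipse, coeffs, phases)

    if cfg.bite_fraction > 0:
        t_b = rng.uniform(0.0, 2.0 * math.pi)
        ct, st = math.cos(theta), math.sin(theta)
        bx = cx + a * math.cos(t_b) * ct - b * math.sin(t_b) * st
        by = cy + a * math.cos(t_b) * st + b * math.sin(t_b) * ct
        r_bite = math.sqrt(cfg.bite_fraction * a * b)
        _stamp_disc(mask_vals, bx, by, r_bite, 0)

    # Speck distractors: 1-3 px clusters well outside the fruit boundary.
    placed = 0
    guard = 0
    ct, st = math.cos(theta), math.sin(theta)
    while placed < cfg.speck_count and guard < 1000:
        guard += 1
        sx = rng.uniform(2, cfg.width - 3)
        sy = rng.uniform(2, cfg.height - 3)
        u = (sx - cx) * ct + (sy - cy) * st
        v = -(sx - cx) * st + (sy - cy) * ct
        if math.hypot(u / a, v / b) < 1.5:
            continue
        px, py = int(sx), int(sy)
        size = int(rng.integers(1, 4))
        mask_vals[py, px] = 1
        if size >= 2:
            mask_vals[py, min(px + 1, cfg.width - 1)] = 1
        if size >= 3:
            mask_vals[min(py + 1, cfg.height - 1), px] = 1
        placed += 1

    p1, p2 = long_axis_endpoints(ellipse)
    head, root = (p1, p2) if rng.random() < 0.5 else (p2, p1)

    image = np.empty((cfg.height, cfg.width, 3), dtype=np.uint8)
    image[:] = BACKGROUND_COLOR
    image[mask_vals.astype(bool)] = FRUIT_COLOR
    # Bright flower cue just beyond the head tip, along the major axis.
    direction = np.array([head.x - cx, head.y - cy])
    direction = direction / np.linalg.norm(direction)
    cue_center = np.array([head.x, head.y]) + direction * (cfg.cue_radius * 0.6)
    cue = np.zeros(mask_vals.shape, dtype=np.uint8)
    _stamp_disc(cue, cue_center[0], cue_center[1], cfg.cue_radius, 1)
    image[cue.astype(bool)] = CUE_COLOR

    return SyntheticScene(
        image=image,
        mask=BinaryMask(mask_vals, (0.0, 0.0)),
        true_ellipse=ellipse,
        true_head=head,
        true_root=root,
        noise_spec=(cfg.boundary_sigma, cfg.speck_count, cfg.bite_fraction),
        seed=seed,
    )


@dataclass(frozen=True)
class DetectionSetConfig:
    """Planned hit/miss pattern per class for a toy detection set.

    ``patterns`` maps a class id to ``(n_ground_truth, outcomes)`` where
    outcomes is a confidence-descending sequence of True (hit: the
    prediction overlaps an unclaimed truth box with IoU 1) and False (miss:
    the prediction lands on empty canvas).  The realized AP is therefore
    known analytically from the staircase.
    """

    patterns: dict[int, tuple[int, tuple[bool, ...]]] = field(
        default_factory=lambda: {0: (2, (True, False, True))}
    )
    box_size: float = 20.0


def expected_average_precision(outcomes: tuple[bool, ...] | list[bool], n_gt: int) -> float:
    """Exact all-points AP of a planned TP/FP staircase (generator truth)."""
    if n_gt <= 0:
        raise ValueError("need ground truth to define AP")
    tp = 0
    points = [(0.0, 1.0)]
    for i, hit in enumerate(outcomes, start=1):
        tp += int(hit)
        points.append((tp / n_gt, tp / i))
    ap = 0.0
    for i in range(1, len(points)):
        r0, _ = points[i - 1]
        r1, _ = points[i]
        envelope = max(p for r, p in points[i:])
        ap += (r1 - r0) * envelope
    return ap


def generate_detection_set(
    config: DetectionSetConfig | None = None, seed: int = 0
) -> tuple[DetectionSet, dict[int, float]]:
    """Materialize the planned staircases as boxes on a virtual canvas.

    Returns the detection set and the analytically expected AP per class.
    Hits reuse a truth box verbatim (IoU 1); misses are placed on a
    disjoint grid row so they overlap nothing.  Confidences decrease in
    plan order with small seeded jitter in the gaps, which leaves the
    ordering (and hence the AP) unchanged.
    """
    cfg = config or DetectionSetConfig()
    rng = np.random.default_rng(seed)
    image = DetectionImage()
    expected: dict[int, float] = {}
    s = cfg.box_size
    for row, (cid, (n_gt, outcomes)) in enumerate(sorted(cfg.patterns.items())):
        if any(outcomes) and sum(outcomes) > n_gt:
            raise ValueError(f"class {cid}: more hits than ground-truth boxes")
        class_gt: list[Box] = []
        for j in range(n_gt):
            x0 = j * 2.0 * s
            y0 = row * 4.0 * s
            class_gt.append((x0, y0, x0 + s, y0 + s))
            image.ground_truth.append(GroundTruthBox(cid, class_gt[-1]))
        hit_idx = 0
        n = len(outcomes)
        for i, hit in enumerate(outcomes):
            # Base gap 1/(n+1) exceeds the jitter band, so order is preserved.
            conf = min((n - i) / (n + 1) + float(rng.uniform(0.0, 0.4 / (n + 1))), 1.0)
            if hit:
                box = class_gt[hit_idx]
                hit_idx += 1
            else:
                x0 = i * 2.0 * s
                y0 = row * 4.0 * s + 2.0 * s
                box = (x0, y0, x0 + s, y0 + s)
            image.predictions.append(PredictedBox(cid, conf, box))
        expected[cid] = expected_average_precision(outcomes, n_gt)
    return DetectionSet(images=[image]), expected
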