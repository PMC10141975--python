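"""Candidate ellipse fitting and max-IoU selection.

Speckle noise in a segmentation mask forms extra connected components; an
ellipse is fitted to each component's boundary and the candidate whose
rasterization best overlaps the whole fruit foreground (largest IoU) wins.
A speck's tiny ellipse covers almost none of the fruit area, so the rule is
robust to distractor components without explicit size thresholds.
"""

from __future__ import annotations

import logging
import math

import numpy as np

from .ellipse import EllipseParams, conic_to_params, fit_ellipse
from .errors import DegenerateConicError, EllipseFitError, SelectionError
from .mask import BinaryMask, Component

__all__ = ["rasterize_ellipse", "mask_iou", "select_best_ellipse"]

logger = logging.getLogger(__name__)


def rasterize_ellipse(
    e: EllipseParams,
    height: int,
    width: int,
    frame_offset: tuple[float, float] = (0.0, 0.0),
) -> BinaryMask:
    """Fill the ellipse interior on an ``height x width`` canvas.

    A pixel is foreground iff its center satisfies the interior inequality;
    parts outside the canvas are cropped.
    """
    if height < 1 or width < 1:
        raise ValueError(f"canvas must be positive, got {height}x{width}")
    dx, dy = frame_offset
    xs = np.arange(width, dtype=float)
    ys = np.arange(height, dtype=float)
    gx, gy = np.meshgrid(xs, ys)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    u = (gx - e.cx) * ct + (gy - e.cy) * st
    v = -(gx - e.cx) * st + (gy - e.cy) * ct
    inside = (u / e.a) ** 2 + (v / e.b) ** 2 <= 1.0
    return BinaryMask(inside.astype(np.uint8), (dx, dy))


def mask_iou(m1: BinaryMask, m2: BinaryMask) -> float:
    """Intersection over union of two foreground sets; 0 for empty union."""
    if m1.values.shape != m2.values.shape or m1.frame_offset != m2.frame_offset:
        raise ValueError(
            "masks must share shape and frame offset: "
            f"{m1.values.shape}@{m1.frame_offset} vs {m2.values.shape}@{m2.frame_offset}"
        )
    a = m1.values.astype(bool)
    b = m2.values.astype(bool)
    union = int(np.logical_or(a, b).sum())
    if union == 0:
        return 0.0
    return int(np.logical_and(a, b).sum()) / union


def select_best_ellipse(
    components: list[Component], fruit_mask: BinaryMask
) -> tuple[EllipseParams, float]:
    """Fit one ellipse per component and keep the max-IoU candidate.

    Each candidate is rasterized on the fruit mask's canvas and compared
    against the full foreground.  Components whose boundary has fewer than
    6 points or whose fit fails are skipped (logged).  Exact IoU ties are
    broken toward the larger component.  The returned parameters live in the
    mask's local pixel grid; callers map them to the original frame via
    ``fruit_mask.frame_offset``.
    """
    if not components:
        raise SelectionError("no components to fit")
    best: tuple[float, int, EllipseParams] | None = None
    for comp in components:
        if comp.boundary.shape[0] < 6:
            logger.debug("skipping component (area %d): boundary < 6 points", comp.area)
            continue
        try:
            params = conic_to_params(fit_ellipse(comp.boundary))
        except (EllipseFitError, DegenerateConicError) as exc:
            logger.debug("skipping component (area %d): %s", comp.area, exc)
            continue
        candidate = rasterize_ellipse(
            params, fruit_mask.height, fruit_mask.width, fruit_mask.frame_offset
        )
        iou = mask_iou(candidate, fruit_mask)
        if best is None or (iou, comp.area) > (best[0], best[1]):
            best = (iou, comp.area, params)
    if best is None:
        raise SelectionError("no component yielded a valid ellipse")
    return best[2], best[0]
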