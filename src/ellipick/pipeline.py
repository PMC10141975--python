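"""End-to-end endpoint detection: mask -> ellipse -> endpoints -> labeled
head/root, with frame transforms, border clipping, and the confidence
tie-break for conflicting classifier outputs.

The fruit's picking point sits at the root (branch) end of the long axis;
the blossom end is the head.  Geometry finds the two long-axis endpoints but
cannot tell which is which, so a pluggable patch classifier (the
:class:`EndpointClassifier` contract) looks at a rectangular crop around
each endpoint.  When both crops are assigned the same class, the one with
the higher prediction confidence keeps it and the other receives the
opposite class.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np

from .ellipse import EllipseParams, PlanePoint, long_axis_endpoints
from .errors import ClippingError, ContractViolationError, EmptyMaskError
from .mask import BinaryMask, binarize, extract_components, morphological_clean, zero_pad
from .select import select_best_ellipse

__all__ = [
    "EndpointPair",
    "CropBox",
    "EndpointClassifier",
    "PipelineConfig",
    "EndpointDetection",
    "crop_boxes",
    "assign_labels",
    "detect_endpoints",
]

logger = logging.getLogger(__name__)

HEAD = "head"
ROOT = "root"

#: Contract for the endpoint classifier: maps an RGB patch (h, w, 3) to a
#: (class, confidence) pair with class in {"head", "root"} and confidence in
#: [0, 1].  Must be deterministic for a fixed patch.
EndpointClassifier = Callable[[np.ndarray], tuple[str, float]]


@dataclass(frozen=True)
class EndpointPair:
    """Labeled head/root coordinates in the original-image frame."""

    head: PlanePoint
    root: PlanePoint
    head_confidence: float
    root_confidence: float

    def __post_init__(self) -> None:
        if (self.head.x, self.head.y) == (self.root.x, self.root.y):
            raise ValueError("head and root must be distinct points")
        for c in (self.head_confidence, self.root_confidence):
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"confidence {c} outside [0, 1]")


@dataclass(frozen=True)
class CropBox:
    """Half-open pixel rectangle [x_min, x_max) x [y_min, y_max)."""

    x_min: int
    y_min: int
    x_max: int
    y_max: int

    def __post_init__(self) -> None:
        if not (self.x_max > self.x_min and self.y_max > self.y_min):
            raise ValueError(f"degenerate crop box {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def extract(self, image: np.ndarray) -> np.ndarray:
        return image[self.y_min : self.y_max, self.x_min : self.x_max]


@dataclass
class PipelineConfig:
    """Tunable knobs of the endpoint pipeline.

    pad_margin: background border added before fitting; ``None`` selects
        ``max(height, width) // 2``, which bounds any ellipse fitted to a
        mask that touches the crop edges.
    open_radius / close_radius: disc radii of the morphological cleanup.
    alpha: the endpoint crop measures ``round(alpha * fruit_w) x
        round(alpha * fruit_h)`` where fruit_w/h is the cropped fruit image
        size; covers the fruit tip plus adjacent context.
    min_crop: lower bound on either crop dimension, in pixels.
    foreground_class: label value treated as fruit in the input mask.
    """

    pad_margin: Optional[int] = None
    open_radius: int = 1
    close_radius: int = 2
    alpha: float = 0.4
    min_crop: int = 8
    foreground_class: int = 1


@dataclass(frozen=True)
class EndpointDetection:
    """Full pipeline output: labeled endpoints plus the fitted ellipse
    (original-image frame) and its IoU with the fruit foreground."""

    endpoints: EndpointPair
    ellipse: EllipseParams
    iou: float


def crop_boxes(
    p1: PlanePoint,
    p2: PlanePoint,
    image_h: int,
    image_w: int,
    fruit_w: int,
    fruit_h: int,
    alpha: float = 0.4,
    min_crop: int = 8,
) -> tuple[CropBox, CropBox]:
    """Rectangular crops of size K1 x K2 centered on the two endpoints.

    ``K1 = round(alpha * fruit_w)`` and ``K2 = round(alpha * fruit_h)``,
    each forced to at least ``min_crop`` pixels, then intersected with the
    image bounds.  A box that vanishes entirely after clipping raises
    :class:`ClippingError` for that endpoint.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha must lie in (0, 1], got {alpha}")
    k1 = max(int(round(alpha * fruit_w)), min_crop)
    k2 = max(int(round(alpha * fruit_h)), min_crop)

    def box_for(p: PlanePoint, tag: str) -> CropBox:
        x0 = int(round(p.x - k1 / 2.0))
        y0 = int(round(p.y - k2 / 2.0))
        x_min, x_max = max(x0, 0), min(x0 + k1, image_w)
        y_min, y_max = max(y0, 0), min(y0 + k2, image_h)
        if x_max <= x_min or y_max <= y_min:
            raise ClippingError(
                f"{tag} crop around ({p.x:.1f}, {p.y:.1f}) lies outside the image"
            )
        return CropBox(x_min, y_min, x_max, y_max)

    return box_for(p1, "first endpoint"), box_for(p2, "second endpoint")


def _validated(output: tuple[str, float]) -> tuple[str, float]:
    try:
        label, conf = output
    except (TypeError, ValueError) as exc:
        raise ContractViolationError(f"classifier returned {output!r}") from exc
    if label not in (HEAD, ROOT):
        raise ContractViolationError(f"invalid class {label!r}, expected 'head' or 'root'")
    conf = float(conf)
    if not (math.isfinite(conf) and 0.0 <= conf <= 1.0):
        raise ContractViolationError(f"confidence {conf} outside [0, 1]")
    return label, conf


def assign_labels(
    patch1: np.ndarray, patch2: np.ndarray, clf: EndpointClassifier
) -> tuple[str, str, float, float]:
    """Resolve head/root labels for two endpoint patches.

    If the classifier assigns different classes, both are kept.  If both
    patches receive the same class, the higher-confidence patch keeps it and
    the other is flipped to the opposite class; its reported confidence
    becomes one minus the overridden prediction's confidence.  An exact tie
    is broken toward the first patch (logged).

    Returns ``(label1, label2, confidence1, confidence2)``.
    """
    if patch1.size == 0 or patch2.size == 0:
        raise ValueError("endpoint patches must be non-empty")
    l1, c1 = _validated(clf(patch1))
    l2, c2 = _validated(clf(patch2))
    if l1 != l2:
        return l1, l2, c1, c2
    other = ROOT if l1 == HEAD else HEAD
    if c1 == c2:
        logger.info("classifier tie (%s, %.3f); keeping class on first patch", l1, c1)
    if c1 >= c2:
        return l1, other, c1, 1.0 - c2
    return other, l2, 1.0 - c1, c2


def detect_endpoints(
    mask: BinaryMask | np.ndarray,
    image: np.ndarray,
    clf: EndpointClassifier,
    config: PipelineConfig | None = None,
) -> EndpointDetection:
    """Run the full geometric pipeline on one cropped fruit.

    Stages: binarize -> zero-pad -> morphological clean -> connected
    components -> max-IoU ellipse selection -> long-axis endpoints ->
    transform to the original frame -> endpoint crops -> head/root
    labeling.  Stage failures propagate with a stage tag in the message.

    Parameters
    ----------
    mask : BinaryMask or 2-D label array
        Segmentation of the cropped fruit (same frame as ``image``).
    image : (h, w, 3) array
        The RGB crop the endpoint patches are taken from.
    clf : EndpointClassifier
        Patch classifier distinguishing the blossom (head) end from the
        branch (root) end.
    """
    cfg = config or PipelineConfig()
    if isinstance(mask, BinaryMask):
        m = mask
    else:
        m = binarize(np.asarray(mask), cfg.foreground_class)
    if m.foreground_count == 0:
        raise EmptyMaskError("[binarize] mask contains no foreground pixels")
    if image.ndim != 3 or image.shape[:2] != (m.height, m.width):
        raise ValueError(
            f"image shape {image.shape} does not match mask {m.height}x{m.width}"
        )

    margin = cfg.pad_margin if cfg.pad_margin is not None else max(m.height, m.width) // 2
    padded = zero_pad(m, margin)
    cleaned = morphological_clean(padded, cfg.open_radius, cfg.close_radius)
    if cleaned.foreground_count == 0:
        raise EmptyMaskError("[morphology] cleanup removed all foreground")
    components = extract_components(cleaned)
    ellipse_local, iou = select_best_ellipse(components, cleaned)
    ellipse = ellipse_local.translated(*cleaned.frame_offset)
    p1, p2 = long_axis_endpoints(ellipse)

    box1, box2 = crop_boxes(
        p1, p2, image.shape[0], image.shape[1], m.width, m.height, cfg.alpha, cfg.min_crop
    )
    l1, l2, c1, c2 = assign_labels(box1.extract(image), box2.extract(image), clf)
    if l1 == HEAD:
        pair = EndpointPair(head=p1, root=p2, head_confidence=c1, root_confidence=c2)
    else:
        pair = EndpointPair(head=p2, root=p1, head_confidence=c2, root_confidence=c1)
    return EndpointDetection(endpoints=pair, ellipse=ellipse, iou=iou)
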