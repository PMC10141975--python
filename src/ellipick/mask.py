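"""Binary-mask post-processing: binarization, zero padding, morphological
cleanup, connected components, and ordered outer-boundary extraction.

These stages turn a raw segmentation output into clean per-candidate point
sets for ellipse fitting.  A :class:`BinaryMask` carries a ``frame_offset``
``(dx, dy)`` that locates its pixel ``(0, 0)`` inside the original image
frame, so coordinates survive cropping and padding: an original-frame
coordinate is ``mask coordinate + offset``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage import measure, morphology

from .errors import EmptyMaskError

__all__ = [
    "BinaryMask",
    "Component",
    "binarize",
    "zero_pad",
    "morphological_clean",
    "extract_components",
]


@dataclass
class BinaryMask:
    """A 2-D foreground grid over {0, 1} with frame bookkeeping."""

    values: np.ndarray
    frame_offset: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        arr = np.asarray(self.values)
        if arr.ndim != 2 or arr.size == 0:
            raise ValueError("mask must be a non-empty 2-D grid")
        uniq = np.unique(arr)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("mask values must be 0 or 1")
        self.values = arr.astype(np.uint8)
        self.frame_offset = (float(self.frame_offset[0]), float(self.frame_offset[1]))

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def foreground_count(self) -> int:
        return int(self.values.sum())

    def to_original_frame(self, x: float, y: float) -> tuple[float, float]:
        """Map a mask-local coordinate to the original image frame."""
        return x + self.frame_offset[0], y + self.frame_offset[1]


@dataclass
class Component:
    """One 8-connected foreground region with its traced outer boundary.

    ``boundary`` is an ordered, duplicate-free closed loop of sub-pixel
    ``(x, y)`` points in the mask's local pixel grid, suitable as direct
    input to the ellipse fit.
    """

    pixels: np.ndarray  # (n, 2) integer (x, y) member coordinates
    boundary: np.ndarray  # (m, 2) float (x, y) ordered outer contour
    area: int = field(init=False)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=int)
        self.boundary = np.asarray(self.boundary, dtype=float)
        self.area = int(self.pixels.shape[0])
        if self.area < 1:
            raise ValueError("component must contain at least one pixel")


def binarize(label_image: np.ndarray, foreground_class: int) -> BinaryMask:
    """1 where the label equals ``foreground_class``, else 0.

    An all-background result is valid; emptiness is detected downstream.
    """
    arr = np.asarray(label_image)
    if arr.size == 0 or arr.ndim != 2:
        raise EmptyMaskError("label image is empty or not 2-D")
    return BinaryMask((arr == foreground_class).astype(np.uint8), (0.0, 0.0))


def zero_pad(m: BinaryMask, margin: int) -> BinaryMask:
    """Surround the mask with ``margin`` background pixels on every side.

    This prevents a fitted ellipse from exceeding the working canvas when
    the fruit touches the crop edge.  ``frame_offset`` shifts by
    ``(-margin, -margin)`` so original-frame coordinates are preserved.
    """
    margin = int(margin)
    if margin < 0:
        raise ValueError(f"margin must be non-negative, got {margin}")
    if margin == 0:
        return BinaryMask(m.values.copy(), m.frame_offset)
    padded = np.pad(m.values, margin, mode="constant", constant_values=0)
    dx, dy = m.frame_offset
    return BinaryMask(padded, (dx - margin, dy - margin))


def morphological_clean(m: BinaryMask, open_radius: int = 1, close_radius: int = 2) -> BinaryMask:
    """Morphological opening then closing with disc structuring elements.

    Opening removes speckle noise smaller than the disc; closing fills
    small boundary gaps and pits.  A radius of 0 skips that step.
    """
    if open_radius < 0 or close_radius < 0:
        raise ValueError("radii must be non-negative")
    out = m.values.astype(bool)
    if open_radius > 0:
        out = morphology.opening(out, morphology.disk(open_radius))
    if close_radius > 0:
        out = morphology.closing(out, morphology.disk(close_radius))
    return BinaryMask(out.astype(np.uint8), m.frame_offset)


def _trace_boundary(region_mask: np.ndarray, row0: int, col0: int) -> np.ndarray:
    """Ordered closed outer contour of one region, as (x, y) in mask frame.

    Marching squares on the zero-padded region image yields a closed,
    non-self-intersecting loop at the 0.5 iso-level; the longest loop is the
    outer boundary (shorter ones trace interior holes).
    """
    padded = np.pad(region_mask.astype(float), 1, mode="constant")
    contours = measure.find_contours(padded, 0.5)
    outer = max(contours, key=len)
    if np.allclose(outer[0], outer[-1]):
        outer = outer[:-1]
    rows = outer[:, 0] - 1.0 + row0
    cols = outer[:, 1] - 1.0 + col0
    return np.column_stack([cols, rows])


def extract_components(m: BinaryMask) -> list[Component]:
    """8-connected foreground components, largest area first.

    Each component carries its traced outer boundary; an empty mask yields
    an empty list.
    """
    labels = measure.label(m.values, connectivity=2)
    comps: list[Component] = []
    for region in measure.regionprops(labels):
        r0, c0, _, _ = region.bbox
        boundary = _trace_boundary(region.image, r0, c0)
        pixels = np.column_stack([region.coords[:, 1], region.coords[:, 0]])
        comps.append(Component(pixels=pixels, boundary=boundary))
    comps.sort(key=lambda c: c.area, reverse=True)
    return comps
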