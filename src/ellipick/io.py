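"""File formats: PNG masks/images, JSON annotations, and detection crops.

The annotation schema is a documented JSON layout:

.. code-block:: json

    [{"image_id": "img_001",
      "class": "DF_S",
      "box": [x_min, y_min, x_max, y_max],
      "head": [x, y],
      "root": [x, y]}]

Boxes use 0-based, half-open pixel coordinates; ``head``/``root`` are
optional (front-view fruit need no endpoints).  Readers validate and reject
rather than silently coerce.  A best-effort converter from Labelme-style
JSON (rectangle + point shapes) is provided.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Optional

import numpy as np
from PIL import Image

from .errors import AnnotationError

__all__ = [
    "AnnotationRecord",
    "read_annotations",
    "write_annotations",
    "convert_labelme",
    "crop_detection",
    "read_mask_png",
    "write_mask_png",
    "read_image_png",
    "write_image_png",
]

VALID_CLASSES = ("DF_S", "DF_F")  # side view (endpoints needed) / front view


@dataclass(frozen=True)
class AnnotationRecord:
    image_id: str
    fruit_class: str
    box: tuple[float, float, float, float]
    head: Optional[tuple[float, float]] = None
    root: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if self.fruit_class not in VALID_CLASSES:
            raise AnnotationError(
                f"field 'class': {self.fruit_class!r} not in {VALID_CLASSES}"
            )
        x0, y0, x1, y1 = self.box
        if not (x1 > x0 and y1 > y0):
            raise AnnotationError(f"field 'box': {self.box} has non-positive extent")
        for name, pt in (("head", self.head), ("root", self.root)):
            if pt is not None and not all(np.isfinite(pt)):
                raise AnnotationError(f"field '{name}': non-finite coordinates {pt}")


def _record_from_dict(obj: dict, index: int) -> AnnotationRecord:
    try:
        return AnnotationRecord(
            image_id=str(obj["image_id"]),
            fruit_class=obj["class"],
            box=tuple(float(v) for v in obj["box"]),
            head=tuple(float(v) for v in obj["head"]) if obj.get("head") else None,
            root=tuple(float(v) for v in obj["root"]) if obj.get("root") else None,
        )
    except KeyError as exc:
        raise AnnotationError(f"record {index}: missing field {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise AnnotationError(f"record {index}: {exc}") from exc


def read_annotations(path: str | Path) -> list[AnnotationRecord]:
    """Load and validate an annotation JSON file."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise AnnotationError("annotation file must contain a JSON array")
    return [_record_from_dict(obj, i) for i, obj in enumerate(data)]


def write_annotations(records: list[AnnotationRecord], path: str | Path) -> None:
    payload = []
    for r in records:
        obj = {"image_id": r.image_id, "class": r.fruit_class, "box": list(r.box)}
        if r.head is not None:
            obj["head"] = list(r.head)
        if r.root is not None:
            obj["root"] = list(r.root)
        payload.append(obj)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def convert_labelme(path: str | Path) -> list[AnnotationRecord]:
    """Best-effort conversion of a Labelme-style JSON file.

    Rectangle shapes labeled DF_S/DF_F become boxes; point shapes labeled
    ``head``/``root`` attach to the record whose box contains them.
    """
    with open(path) as fh:
        data = json.load(fh)
    image_id = str(data.get("imagePath", Path(path).stem))
    records: list[dict] = []
    points: list[tuple[str, tuple[float, float]]] = []
    for shape in data.get("shapes", []):
        label = shape.get("label", "")
        stype = shape.get("shape_type", "")
        pts = shape.get("points", [])
        if stype == "rectangle" and label in VALID_CLASSES and len(pts) == 2:
            (x0, y0), (x1, y1) = pts
            box = (min(x0, x1), min(y0, y1), max(x0, x1), max(y0, y1))
            records.append({"class": label, "box": box, "head": None, "root": None})
        elif stype == "point" and label in ("head", "root") and len(pts) == 1:
            points.append((label, (float(pts[0][0]), float(pts[0][1]))))
    for label, (px, py) in points:
        for rec in records:
            x0, y0, x1, y1 = rec["box"]
            if x0 <= px < x1 and y0 <= py < y1:
                rec[label] = (px, py)
                break
    return [
        AnnotationRecord(image_id, r["class"], r["box"], r["head"], r["root"])
        for r in records
    ]


def crop_detection(image: np.ndarray, box: tuple[float, float, float, float]) -> tuple[np.ndarray, tuple[int, int]]:
    """Half-open crop of a detection box, with its original-frame offset.

    Returns ``(crop, (dx, dy))`` such that a crop-local coordinate plus the
    offset reproduces the original-frame coordinate.
    """
    h, w = image.shape[:2]
    x0, y0 = max(int(box[0]), 0), max(int(box[1]), 0)
    x1, y1 = min(int(box[2]), w), min(int(box[3]), h)
    if x1 <= x0 or y1 <= y0:
        raise ValueError(f"box {box} does not intersect a {h}x{w} image")
    return image[y0:y1, x0:x1], (x0, y0)


def read_mask_png(path: str | Path) -> np.ndarray:
    """Read a single-channel PNG label mask; nonzero pixels are foreground."""
    arr = np.asarray(Image.open(path).convert("L"))
    return (arr != 0).astype(np.uint8)


def write_mask_png(values: np.ndarray, path: str | Path) -> None:
    Image.fromarray((np.asarray(values) != 0).astype(np.uint8) * 255, mode="L").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB"))


def write_image_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8), mode="RGB").save(path)
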