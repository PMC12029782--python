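"""Annotation I/O and dataset splitting.

Two polygon-annotation dialects are supported for the two segmentation
classes BAC (bacterial colony) and AS (solubilization halo, always the
total halo-plus-colony region):

* YOLO-seg label text: one object per line,
  ``class_id x1 y1 x2 y2 ...`` with coordinates normalized to [0, 1].
  Prediction files may carry an optional confidence token after the class
  id; it is accepted on read and emitted on write only when < 1.
* COCO-style segmentation JSON with polygon segmentations in absolute
  pixel coordinates, normalized on read using the image entry.

The train/test split shuffles item identifiers with a seeded RNG and
assigns ``floor(n * train_fraction)`` items to training (default 75/25).
"""

from __future__ import annotations

import enum
import json
import logging
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "ClassLabel",
    "CLASS_IDS",
    "PolygonAnnotation",
    "DatasetSplit",
    "TrainingConfig",
    "AnnotationParseError",
    "read_yolo_seg",
    "write_yolo_seg",
    "read_coco_segmentation",
    "write_class_map",
    "read_class_map",
    "split_dataset",
    "polygon_area",
]


class ClassLabel(str, enum.Enum):
    """Segmentation classes: colony (BAC) and total halo region (AS)."""

    BAC = "BAC"
    AS = "AS"


#: Fixed class ids used in YOLO-seg files.
CLASS_IDS: dict[ClassLabel, int] = {ClassLabel.BAC: 0, ClassLabel.AS: 1}
_ID_TO_CLASS = {v: k for k, v in CLASS_IDS.items()}


class AnnotationParseError(ValueError):
    """Raised for malformed annotation files; carries file/line context."""


@dataclass(frozen=True)
class PolygonAnnotation:
    """One class-labeled polygon with normalized vertices and a confidence.

    Vertices are (x, y) pairs in [0, 1], x = column / image width,
    y = row / image height, origin at the top-left corner.
    """

    class_label: ClassLabel
    vertices: tuple[tuple[float, float], ...]
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError(
                f"polygon needs >= 3 vertices, got {len(self.vertices)}"
            )
        for x, y in self.vertices:
            if not (0.0 <= x <= 1.0 and 0.0 <= y <= 1.0):
                raise ValueError(f"vertex ({x}, {y}) outside [0, 1]")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(f"confidence {self.confidence} outside [0, 1]")
        object.__setattr__(
            self, "vertices", tuple((float(x), float(y)) for x, y in self.vertices)
        )


@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint train/test partition of item identifiers."""

    train_items: tuple[str, ...]
    test_items: tuple[str, ...]


@dataclass(frozen=True)
class TrainingConfig:
    """Configuration metadata of the segmentation-model training recipe.

    Kept as provenance for imported predictions; no training happens here.
    The confidence threshold is the post-inference filter applied to
    predictions (30% by default).
    """

    epochs: int = 200
    batch_size: int = 4
    image_size_px: int = 800
    confidence_threshold: float = 0.30

    def __post_init__(self) -> None:
        if self.epochs <= 0 or self.batch_size <= 0 or self.image_size_px <= 0:
            raise ValueError("epochs, batch_size and image_size_px must be positive")
        if not 0.0 <= self.confidence_threshold <= 1.0:
            raise ValueError("confidence_threshold must lie in [0, 1]")


def polygon_area(vertices: Sequence[tuple[float, float]]) -> float:
    """Shoelace area of a polygon (same units as the coordinates)."""
    area = 0.0
    n = len(vertices)
    for i in range(n):
        x1, y1 = vertices[i]
        x2, y2 = vertices[(i + 1) % n]
        area += x1 * y2 - x2 * y1
    return abs(area) / 2.0


def read_yolo_seg(
    path: str | Path,
    class_map: dict[int, ClassLabel] | None = None,
) -> list[PolygonAnnotation]:
    """Parse a YOLO-seg label/prediction file into annotations.

    Each non-empty line is ``class_id [confidence] x1 y1 x2 y2 ...`` with
    at least three normalized vertices.  A second token in (0, 1) followed
    by an even number of coordinates is read as a confidence; label files
    without one get confidence 1.0.
    """
    class_map = class_map or _ID_TO_CLASS
    path = Path(path)
    annotations: list[PolygonAnnotation] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = line.split()
        try:
            class_id = int(tokens[0])
        except ValueError:
            raise AnnotationParseError(
                f"{path}:{lineno}: class id {tokens[0]!r} is not an integer"
            ) from None
        if class_id not in class_map:
            raise AnnotationParseError(
                f"{path}:{lineno}: unknown class id {class_id}"
            )
        try:
            values = [float(t) for t in tokens[1:]]
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None

        confidence = 1.0
        # Odd value count => first value is a confidence token.
        if len(values) % 2 == 1:
            confidence = values[0]
            values = values[1:]
        if len(values) < 6:
            raise AnnotationParseError(
                f"{path}:{lineno}: polygon needs >= 3 vertex pairs, "
                f"got {len(values)} coordinates"
            )
        vertices = tuple(zip(values[0::2], values[1::2]))
        try:
            annotations.append(
                PolygonAnnotation(class_map[class_id], vertices, confidence)
            )
        except ValueError as exc:
            raise AnnotationParseError(f"{path}:{lineno}: {exc}") from None
    return annotations


def write_yolo_seg(
    annotations: Iterable[PolygonAnnotation], path: str | Path
) -> None:
    """Write annotations as YOLO-seg lines with fixed 6-decimal coordinates.

    A confidence token is emitted only for predictions (confidence < 1);
    ground-truth labels stay in the plain dialect.
    """
    lines = []
    for ann in annotations:
        parts = [str(CLASS_IDS[ann.class_label])]
        if ann.confidence < 1.0:
            parts.append(f"{ann.confidence:.6f}")
        parts.extend(f"{c:.6f}" for xy in ann.vertices for c in xy)
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_coco_segmentation(path: str | Path) -> list[PolygonAnnotation]:
    """Read polygon annotations from a COCO-style segmentation JSON.

    Category names must map (case-insensitively) onto BAC/AS; absolute
    polygon coordinates are normalized by the owning image's width/height.
    Run-length-encoded segmentations are not supported.
    """
    path = Path(path)
    doc = json.loads(path.read_text())
    images = {img["id"]: img for img in doc.get("images", [])}
    categories: dict[int, ClassLabel] = {}
    for cat in doc.get("categories", []):
        name = str(cat["name"]).upper()
        try:
            categories[cat["id"]] = ClassLabel(name)
        except ValueError:
            raise AnnotationParseError(
                f"{path}: category {cat['name']!r} is not one of BAC/AS"
            ) from None

    annotations: list[PolygonAnnotation] = []
    for ann in doc.get("annotations", []):
        seg = ann.get("segmentation")
        if isinstance(seg, dict) or (
            isinstance(seg, list) and seg and not isinstance(seg[0], list)
        ):
            raise AnnotationParseError(
                f"{path}: RLE segmentations are not supported "
                f"(annotation id {ann.get('id')})"
            )
        img = images.get(ann["image_id"])
        if img is None:
            raise AnnotationParseError(
                f"{path}: annotation id {ann.get('id')} references unknown "
                f"image id {ann['image_id']}"
            )
        w, h = float(img["width"]), float(img["height"])
        if ann["category_id"] not in categories:
            raise AnnotationParseError(
                f"{path}: annotation id {ann.get('id')} references unknown "
                f"category id {ann['category_id']}"
            )
        label = categories[ann["category_id"]]
        confidence = float(ann.get("score", 1.0))
        for ring in seg:
            if len(ring) % 2 == 1:
                raise AnnotationParseError(
                    f"{path}: odd coordinate count in annotation id {ann.get('id')}"
                )
            xs = [x / w for x in ring[0::2]]
            ys = [y / h for y in ring[1::2]]
            if any(not 0.0 <= v <= 1.0 for v in xs + ys):
                raise AnnotationParseError(
                    f"{path}: coordinates outside the image in annotation id "
                    f"{ann.get('id')}"
                )
            annotations.append(
                PolygonAnnotation(label, tuple(zip(xs, ys)), confidence)
            )
    return annotations


def write_class_map(path: str | Path) -> None:
    """Write the data.yaml-style class map accompanying YOLO-seg labels."""
    doc = {
        "names": {CLASS_IDS[label]: label.value for label in ClassLabel},
        "nc": len(CLASS_IDS),
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_class_map(path: str | Path) -> dict[int, ClassLabel]:
    """Read a data.yaml-style class map into an id -> label mapping."""
    doc = yaml.safe_load(Path(path).read_text())
    names = doc["names"]
    if isinstance(names, list):
        names = dict(enumerate(names))
    return {int(k): ClassLabel(str(v).upper()) for k, v in names.items()}


def split_dataset(
    item_ids: Sequence[str],
    train_fraction: float = 0.75,
    seed: int | None = None,
) -> DatasetSplit:
    """Seeded shuffle-and-split of item identifiers into train/test.

    The train set size is floor(n * train_fraction); with the 0.75 default
    this realizes a 75/25 split.  train_fraction may be exactly 1 (all
    items train).  Deterministic for a given seed.
    """
    items = list(item_ids)
    if not items:
        raise ValueError("cannot split an empty item list")
    if not (0.0 < train_fraction < 1.0 or train_fraction == 1.0):
        raise ValueError(
            f"train_fraction must be in (0, 1) or exactly 1, got {train_fraction}"
        )
    rng = random.Random(seed)
    rng.shuffle(items)
    n_train = int(len(items) * train_fraction)
    return DatasetSplit(
        train_items=tuple(items[:n_train]), test_items=tuple(items[n_train:])
    )
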