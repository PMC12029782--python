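"""Plate segmentation: reference segmenter, prediction import, and mask
conversion.

Two routes produce per-class polygon annotations for a plate image:

* ``segment_reference`` — a classical intensity-based segmenter.  It
  locates the dish as the largest bright region, splits the intensities
  inside the dish into three classes (dark colony, agar, bright halo)
  with multi-level Otsu thresholding, cleans the masks morphologically,
  and pairs each colony with the total halo region that contains it.
  Its annotations carry confidence 1.0: a thresholding pipeline has no
  probabilistic head.
* ``import_predictions`` — reads externally produced YOLO-seg or COCO
  predictions (e.g. from an instance-segmentation model) from disk.

Either way the annotations pass through the same confidence filter
(default threshold 0.30, inclusive) and the same polygon rasterizer, so
downstream quantification does not care where masks came from.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage import draw, filters, morphology

from .annotations_io import (
    ClassLabel,
    PolygonAnnotation,
    read_coco_segmentation,
    read_yolo_seg,
)
from .plate_synth import mask_to_polygon

logger = logging.getLogger(__name__)

__all__ = [
    "SegmentationSource",
    "SegmentationResult",
    "ReferenceSegmenterConfig",
    "DishNotFoundError",
    "filter_by_confidence",
    "polygons_to_masks",
    "segment_reference",
    "import_predictions",
    "read_plate_image",
]

#: Default post-inference confidence threshold (inclusive).
DEFAULT_CONFIDENCE_THRESHOLD = 0.30


class DishNotFoundError(RuntimeError):
    """Raised when no plausible dish region is detected in the image."""


class SegmentationSource(str, enum.Enum):
    reference = "reference"
    imported = "imported"


@dataclass(frozen=True)
class SegmentationResult:
    """Annotations for one plate plus their provenance and image size."""

    annotations: tuple[PolygonAnnotation, ...]
    source: SegmentationSource
    image_size_px: tuple[int, int]


@dataclass(frozen=True)
class ReferenceSegmenterConfig:
    """Tunables of the classical reference segmenter.

    ``min_object_px`` discards connected components smaller than this
    (relative to a 1746 px image; scaled by (size/1746)^2 at runtime).
    ``morph_radius_px`` is the structuring-element radius of the
    opening/closing cleanup, scaled linearly with image size.
    ``min_dish_fraction`` is the smallest credible dish area as a
    fraction of the image.
    """

    min_object_px: int = 400
    morph_radius_px: int = 5
    min_dish_fraction: float = 0.05


def filter_by_confidence(
    result: SegmentationResult,
    threshold: float = DEFAULT_CONFIDENCE_THRESHOLD,
) -> SegmentationResult:
    """Keep annotations with confidence >= threshold (inclusive), in order.

    Idempotent, and monotone: raising the threshold never adds annotations.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    kept = tuple(a for a in result.annotations if a.confidence >= threshold)
    return SegmentationResult(kept, result.source, result.image_size_px)


def polygons_to_masks(
    result: SegmentationResult,
    image_size: tuple[int, int] | None = None,
) -> dict[ClassLabel, list[np.ndarray]]:
    """Rasterize each annotation to a full-resolution boolean mask per class.

    Normalized vertices are scaled by the image width/height and filled
    with the pixel-center-in-polygon rule.  Degenerate polygons (< 3
    distinct vertices) are skipped with a warning.
    """
    rows, cols = image_size or result.image_size_px
    out: dict[ClassLabel, list[np.ndarray]] = {
        ClassLabel.BAC: [],
        ClassLabel.AS: [],
    }
    for ann in result.annotations:
        if len(set(ann.vertices)) < 3:
            logger.warning(
                "skipping degenerate %s polygon with %d distinct vertices",
                ann.class_label.value,
                len(set(ann.vertices)),
            )
            continue
        ys = np.array([y * rows for _, y in ann.vertices])
        xs = np.array([x * cols for x, _ in ann.vertices])
        mask = np.zeros((rows, cols), dtype=bool)
        rr, cc = draw.polygon(ys, xs, shape=(rows, cols))
        mask[rr, cc] = True
        out[ann.class_label].append(mask)
    return out


def read_plate_image(path: str | Path) -> np.ndarray:
    """Load a plate photo (PNG/TIFF/JPEG) as a [0, 1] grayscale float array."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # RGB(A) -> luminance
        arr = arr[..., :3] @ np.array([0.2126, 0.7152, 0.0722])
    if arr.max() > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def import_predictions(
    path: str | Path, image_size: tuple[int, int]
) -> SegmentationResult:
    """Load external model predictions (YOLO-seg txt or COCO JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        annotations = read_coco_segmentation(path)
    else:
        annotations = read_yolo_seg(path)
    return SegmentationResult(
        tuple(annotations), SegmentationSource.imported, tuple(image_size)
    )


def segment_reference(
    image: np.ndarray,
    cfg: ReferenceSegmenterConfig | None = None,
) -> SegmentationResult:
    """Segment colonies and total halo regions with classical thresholding.

    Pipeline: dish = largest bright connected region (Otsu on the whole
    image, holes filled); inside the dish a three-class multi-level Otsu
    split separates dark colonies from agar from bright halos;
    morphological opening/closing removes speckle; each connected colony
    becomes one BAC annotation and is paired with the smallest
    halo-union-colony region containing its centroid, which becomes the
    AS annotation (total region, always containing its colony).

    A blank dish yields an empty result; an image with no credible dish
    raises DishNotFoundError.
    """
    cfg = cfg or ReferenceSegmenterConfig()
    image = np.asarray(image, dtype=np.float64)
    rows, cols = image.shape
    scale = cols / 1746.0
    min_obj = max(8, int(cfg.min_object_px * scale**2))
    selem = morphology.disk(max(1, round(cfg.morph_radius_px * scale)))

    dish = _find_dish(image, cfg)

    inside = image[dish]
    if np.unique(inside).size < 3:
        return SegmentationResult((), SegmentationSource.reference, (rows, cols))
    try:
        t_low, t_high = filters.threshold_multiotsu(inside, classes=3)
    except ValueError:  # intensity histogram too degenerate to split
        return SegmentationResult((), SegmentationSource.reference, (rows, cols))

    colony_raw = dish & (image < t_low)
    bright_raw = dish & (image > t_high)

    colony = morphology.closing(morphology.opening(colony_raw, selem), selem)
    colony = morphology.remove_small_objects(colony, max_size=min_obj - 1)
    bright = morphology.closing(morphology.opening(bright_raw, selem), selem)
    bright = morphology.remove_small_objects(bright, max_size=min_obj - 1)

    if not colony.any() and not bright.any():
        return SegmentationResult((), SegmentationSource.reference, (rows, cols))

    # A genuine plate has both a dark colony and a bright clearing; a lone
    # "bright" or "dark" blob on an otherwise uniform dish is noise split
    # into thirds by the forced 3-class threshold.
    if not colony.any() or not bright.any():
        return SegmentationResult((), SegmentationSource.reference, (rows, cols))

    structure = ndimage.generate_binary_structure(2, 2)
    colony_labels, n_colonies = ndimage.label(colony, structure=structure)
    total_region = ndimage.binary_fill_holes(bright | colony)
    total_labels, n_total = ndimage.label(total_region, structure=structure)
    total_sizes = ndimage.sum_labels(
        total_region, total_labels, index=np.arange(1, n_total + 1)
    )

    annotations: list[PolygonAnnotation] = []
    used_total: set[int] = set()
    for i in range(1, n_colonies + 1):
        cmask = colony_labels == i
        cy, cx = ndimage.center_of_mass(cmask)
        # Smallest total region containing the colony centroid; fall back
        # to any region overlapping the colony.
        lbl = int(total_labels[int(round(cy)), int(round(cx))])
        if lbl == 0:
            overlapping = np.unique(total_labels[cmask])
            overlapping = overlapping[overlapping > 0]
            if overlapping.size == 0:
                continue
            lbl = int(overlapping[np.argmin(total_sizes[overlapping - 1])])
        total_mask = (total_labels == lbl) | cmask
        used_total.add(lbl)

        cpoly = mask_to_polygon(cmask)
        tpoly = mask_to_polygon(total_mask)
        if cpoly is None or tpoly is None:
            continue
        annotations.append(PolygonAnnotation(ClassLabel.BAC, cpoly, 1.0))
        annotations.append(PolygonAnnotation(ClassLabel.AS, tpoly, 1.0))

    unpaired = set(range(1, n_total + 1)) - used_total
    for lbl in sorted(unpaired):
        logger.warning(
            "halo region %d (%d px) has no colony inside; excluded from pairing",
            lbl,
            int(total_sizes[lbl - 1]),
        )

    return SegmentationResult(
        tuple(annotations), SegmentationSource.reference, (rows, cols)
    )


def _find_dish(image: np.ndarray, cfg: ReferenceSegmenterConfig) -> np.ndarray:
    """Largest bright connected region, holes filled, as the dish mask."""
    if np.unique(image).size < 2:
        raise DishNotFoundError("image is uniform; no dish boundary to detect")
    t = filters.threshold_otsu(image)
    bright = image > t
    labels, n = ndimage.label(bright)
    if n == 0:
        raise DishNotFoundError("no bright region found")
    sizes = ndimage.sum_labels(bright, labels, index=np.arange(1, n + 1))
    dish = labels == (int(np.argmax(sizes)) + 1)
    dish = ndimage.binary_fill_holes(dish)
    if dish.sum() < cfg.min_dish_fraction * image.size:
        raise DishNotFoundError(
            f"largest bright region covers {dish.sum() / image.size:.1%} of the "
            f"image, below the {cfg.min_dish_fraction:.0%} dish minimum"
        )
    return dish
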