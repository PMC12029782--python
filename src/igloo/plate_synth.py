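"""Synthetic Petri-dish plate generator with exact ground truth.

Emulates standardized plate photographs: a square grayscale image (1746 px
by default, an 11 cm dish) containing an agar disk on a dark background,
with one or more dark colony disks each surrounded by a brighter clearing
halo.  The default intensity ordering is colony < agar < halo: a halo is a
cleared zone in an opaque phosphate medium and therefore brighter than the
surrounding agar, while dense colony growth is darker.

Ground truth is geometric, not photographic: every mask is the noiseless
rasterized disk (pixel-center distance <= radius), the halo mask is the
TOTAL halo-plus-colony disk, and the true solubilization efficiency of
each colony is (colony_area + halo_area) / colony_area computed on those
rasterized masks.  Illumination gradient and Gaussian noise perturb the
image only, never the ground truth.  Generation is a pure function of the
configuration, including its seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage import measure

from .annotations_io import ClassLabel, PolygonAnnotation, write_class_map, write_yolo_seg

logger = logging.getLogger(__name__)

__all__ = [
    "ColonySpec",
    "SynthConfig",
    "SyntheticGroundTruth",
    "GeometryError",
    "rasterize_disk",
    "generate_plate",
    "ground_truth_to_annotations",
    "mask_to_polygon",
    "write_plate_png",
    "write_dataset",
]


class GeometryError(ValueError):
    """Raised when a colony/halo does not fit inside the dish."""


@dataclass(frozen=True)
class ColonySpec:
    """One colony: center (row, col) and colony/halo radii in pixels.

    The halo radius is the radius of the total cleared region and must be
    at least the colony radius.
    """

    center_px: tuple[float, float]
    colony_radius_px: float
    halo_radius_px: float

    def __post_init__(self) -> None:
        if self.colony_radius_px <= 0:
            raise ValueError("colony_radius_px must be positive")
        if self.halo_radius_px < self.colony_radius_px:
            raise ValueError(
                f"halo_radius_px ({self.halo_radius_px}) must be >= "
                f"colony_radius_px ({self.colony_radius_px})"
            )


@dataclass(frozen=True)
class SynthConfig:
    """Full description of one synthetic plate image.

    Intensities are grayscale levels in [0, 1].  ``illumination_gradient``
    is the total relative intensity change across the image width (a
    multiplicative left-to-right ramp centered on 1), emulating imperfect
    lighting; 0 disables it.  ``noise_sd`` is the standard deviation of
    additive Gaussian pixel noise.
    """

    image_size_px: int = 1746
    dish_diameter_cm: float = 11.0
    dish_margin_px: int = 60
    colonies: tuple[ColonySpec, ...] = ()
    background_level: float = 0.08
    agar_level: float = 0.55
    halo_level: float = 0.85
    colony_level: float = 0.25
    noise_sd: float = 0.0
    illumination_gradient: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.image_size_px < 64:
            raise ValueError("image_size_px must be >= 64")
        if self.dish_diameter_cm <= 0:
            raise ValueError("dish_diameter_cm must be positive")
        if self.dish_margin_px < 0:
            raise ValueError("dish_margin_px must be non-negative")
        for name in ("background_level", "agar_level", "halo_level", "colony_level"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.illumination_gradient <= 0.3:
            raise ValueError("illumination_gradient must lie in [0, 0.3]")
        object.__setattr__(self, "colonies", tuple(self.colonies))

    @property
    def dish_center_px(self) -> tuple[float, float]:
        c = (self.image_size_px - 1) / 2.0
        return (c, c)

    @property
    def dish_radius_px(self) -> float:
        return self.image_size_px / 2.0 - self.dish_margin_px


@dataclass(frozen=True)
class SyntheticGroundTruth:
    """Noiseless geometric truth for one synthetic plate.

    ``halo_masks[i]`` is the total halo-plus-colony region of colony i and
    always contains ``colony_masks[i]``; ``true_Ef_per_colony[i]`` is
    (colony_area + halo_area) / colony_area on the rasterized masks.
    """

    colony_masks: tuple[np.ndarray, ...]
    halo_masks: tuple[np.ndarray, ...]
    true_Ef_per_colony: tuple[float, ...]
    dish_mask: np.ndarray


def rasterize_disk(
    center: tuple[float, float], radius: float, shape: tuple[int, int]
) -> np.ndarray:
    """Boolean disk mask: pixel (r, c) is set iff its center lies within
    ``radius`` (inclusive) of ``center`` in Euclidean distance.

    This inclusive pixel-center rule is the single membership convention
    shared by synthesis and quantification.
    """
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    rows, cols = shape
    if rows <= 0 or cols <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    rr, cc = np.ogrid[:rows, :cols]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def generate_plate(cfg: SynthConfig) -> tuple[np.ndarray, SyntheticGroundTruth]:
    """Render a synthetic plate image and its exact ground truth.

    Composition order: background, agar dish disk, then per colony the
    halo disk and the colony disk on top; afterwards the multiplicative
    illumination ramp and additive Gaussian noise (clipped to [0, 1]) are
    applied to the image only.  Identical configs produce byte-identical
    arrays.
    """
    n = cfg.image_size_px
    shape = (n, n)
    dish_center = cfg.dish_center_px
    dish_radius = cfg.dish_radius_px

    for i, colony in enumerate(cfg.colonies):
        dr = math.hypot(
            colony.center_px[0] - dish_center[0],
            colony.center_px[1] - dish_center[1],
        )
        if dr + colony.halo_radius_px > dish_radius:
            raise GeometryError(
                f"colony {i} (center {colony.center_px}, halo radius "
                f"{colony.halo_radius_px}) extends outside the dish"
            )

    dish_mask = rasterize_disk(dish_center, dish_radius, shape)
    image = np.full(shape, cfg.background_level, dtype=np.float64)
    image[dish_mask] = cfg.agar_level

    colony_masks: list[np.ndarray] = []
    halo_masks: list[np.ndarray] = []
    efs: list[float] = []
    for colony in cfg.colonies:
        halo = rasterize_disk(colony.center_px, colony.halo_radius_px, shape)
        cmask = rasterize_disk(colony.center_px, colony.colony_radius_px, shape)
        image[halo] = cfg.halo_level
        image[cmask] = cfg.colony_level
        colony_masks.append(cmask)
        halo_masks.append(halo)
        a = int(np.count_nonzero(cmask))
        b = int(np.count_nonzero(halo))
        efs.append((a + b) / a)

    if cfg.illumination_gradient > 0:
        ramp = 1.0 + cfg.illumination_gradient * (
            np.linspace(0.0, 1.0, n) - 0.5
        )
        image = image * ramp[np.newaxis, :]
    if cfg.noise_sd > 0:
        rng = np.random.default_rng(cfg.seed)
        image = image + rng.normal(0.0, cfg.noise_sd, size=shape)
    image = np.clip(image, 0.0, 1.0)

    truth = SyntheticGroundTruth(
        colony_masks=tuple(colony_masks),
        halo_masks=tuple(halo_masks),
        true_Ef_per_colony=tuple(efs),
        dish_mask=dish_mask,
    )
    return image, truth


def mask_to_polygon(
    mask: np.ndarray, max_vertices: int = 200
) -> tuple[tuple[float, float], ...] | None:
    """Outer contour of a mask as a normalized (x, y) vertex tuple.

    Returns None for an empty mask.  The longest 0.5-level contour is
    taken and evenly subsampled to at most ``max_vertices`` points; for
    disk-like regions the re-rasterized polygon overlaps the source mask
    at IoU >= 0.98.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return None
    rows, cols = mask.shape
    contours = measure.find_contours(mask.astype(float), 0.5)
    if not contours:
        return None
    contour = max(contours, key=len)
    if len(contour) > max_vertices:
        idx = np.linspace(0, len(contour) - 1, max_vertices).astype(int)
        contour = contour[idx]
    xs = np.clip(contour[:, 1] / cols, 0.0, 1.0)
    ys = np.clip(contour[:, 0] / rows, 0.0, 1.0)
    return tuple(zip(xs.tolist(), ys.tolist()))


def ground_truth_to_annotations(
    gt: SyntheticGroundTruth, image_size: tuple[int, int] | int | None = None
) -> list[PolygonAnnotation]:
    """Convert ground-truth masks to normalized polygon annotations.

    Colony masks become BAC polygons and halo (total-region) masks become
    AS polygons, all with confidence 1.0.  Empty masks are skipped with a
    warning.
    """
    annotations: list[PolygonAnnotation] = []
    for label, masks in (
        (ClassLabel.BAC, gt.colony_masks),
        (ClassLabel.AS, gt.halo_masks),
    ):
        for i, mask in enumerate(masks):
            vertices = mask_to_polygon(mask)
            if vertices is None:
                logger.warning("skipping empty %s mask %d", label.value, i)
                continue
            annotations.append(PolygonAnnotation(label, vertices, 1.0))
    return annotations


def write_plate_png(image: np.ndarray, path: str | Path) -> None:
    """Write a [0, 1] float image as an 8-bit grayscale PNG."""
    import imageio.v3 as iio

    iio.imwrite(
        Path(path), (np.clip(image, 0.0, 1.0) * 255).round().astype(np.uint8)
    )


def write_dataset(
    out_dir: str | Path,
    n_plates: int,
    seed: int = 0,
    colonies_per_plate: int = 1,
    noise_sd: float = 0.0,
    image_size_px: int = 1746,
) -> list[Path]:
    """Generate a directory of plate PNGs with YOLO-seg labels.

    Images go to ``out_dir/images``, labels to ``out_dir/labels`` plus a
    ``data.yaml`` class map.  Colony placement and radii are drawn from
    the master seed, so the whole dataset is reproducible.
    """
    out_dir = Path(out_dir)
    img_dir = out_dir / "images"
    lbl_dir = out_dir / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    written: list[Path] = []
    for k in range(n_plates):
        cfg = _random_plate_config(
            rng,
            image_size_px=image_size_px,
            colonies=colonies_per_plate,
            noise_sd=noise_sd,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        image, truth = generate_plate(cfg)
        stem = f"plate_{k:04d}"
        write_plate_png(image, img_dir / f"{stem}.png")
        write_yolo_seg(ground_truth_to_annotations(truth), lbl_dir / f"{stem}.txt")
        written.append(img_dir / f"{stem}.png")
    write_class_map(out_dir / "data.yaml")
    return written


def _random_plate_config(
    rng: np.random.Generator,
    image_size_px: int,
    colonies: int,
    noise_sd: float,
    seed: int,
) -> SynthConfig:
    """Draw a plate config with non-overlapping colonies inside the dish."""
    base = SynthConfig(image_size_px=image_size_px, noise_sd=noise_sd, seed=seed)
    scale = image_size_px / 1746.0
    placed: list[ColonySpec] = []
    attempts = 0
    while len(placed) < colonies and attempts < 1000:
        attempts += 1
        colony_r = rng.uniform(45, 85) * scale
        halo_r = colony_r * rng.uniform(1.25, 1.6)
        max_off = base.dish_radius_px - halo_r - 5 * scale
        if max_off <= 0:
            continue
        angle = rng.uniform(0, 2 * math.pi)
        dist = math.sqrt(rng.uniform(0, 1)) * max_off
        center = (
            base.dish_center_px[0] + dist * math.sin(angle),
            base.dish_center_px[1] + dist * math.cos(angle),
        )
        if any(
            math.hypot(center[0] - p.center_px[0], center[1] - p.center_px[1])
            < halo_r + p.halo_radius_px + 10 * scale
            for p in placed
        ):
            continue
        placed.append(ColonySpec(center, colony_r, halo_r))
    return SynthConfig(
        image_size_px=image_size_px,
        colonies=tuple(placed),
        noise_sd=noise_sd,
        seed=seed,
    )
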