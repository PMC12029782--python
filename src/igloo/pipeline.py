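"""End-to-end plate-analysis workflow.

Wires the stages together: load a plate (image, imported predictions, or
pre-computed masks), segment, apply the confidence filter, rasterize
polygons to masks, quantify areas and the solubilization efficiency, and
collect everything into a per-plate report.  When manual reference
measurements are supplied the report also carries the relative difference
of the automated Ef against them, the validation protocol for comparing
the automated readout with traditional visual measurement.

Configuration comes from a single YAML file (or is built in code); every
CLI flag maps onto one of its fields.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .annotations_io import ClassLabel
from .quantify import (
    Calibration,
    EfMode,
    MeasurementError,
    PlateMeasurement,
    analyze_plate,
    relative_difference_pct,
)
from .segmentation import (
    DEFAULT_CONFIDENCE_THRESHOLD,
    SegmentationResult,
    filter_by_confidence,
    import_predictions,
    polygons_to_masks,
    read_plate_image,
    segment_reference,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PlateSpec",
    "PipelineConfig",
    "PlateResult",
    "PlateReport",
    "run_analysis",
    "run_validation",
    "load_mask_png",
]


@dataclass(frozen=True)
class PlateSpec:
    """One plate to analyze: an image, or a colony/halo mask pair.

    ``predictions`` points at an external YOLO-seg/COCO prediction file
    (used with method "import"); ``manual_ef`` is an optional manually
    measured solubilization efficiency for validation.
    """

    name: str
    image: str | None = None
    colony_mask: str | None = None
    halo_mask: str | None = None
    predictions: str | None = None
    manual_ef: float | None = None


@dataclass(frozen=True)
class PipelineConfig:
    """Full configuration of one analysis run.

    Defaults reproduce the standardized imaging setup: 1746 px wide image
    of an 11 cm dish and a 30% confidence threshold.
    """

    plates: tuple[PlateSpec, ...]
    image_width_px: int = 1746
    dish_diameter_cm: float = 11.0
    method: str = "reference"
    confidence_threshold: float = DEFAULT_CONFIDENCE_THRESHOLD
    ef_mode: EfMode = EfMode.area_px
    out_dir: str | None = None
    save_masks: bool = False
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ef_mode", EfMode(self.ef_mode))
        object.__setattr__(
            self,
            "plates",
            tuple(
                p if isinstance(p, PlateSpec) else PlateSpec(**p)
                for p in self.plates
            ),
        )
        if self.method not in ("reference", "import"):
            raise ValueError(f"method must be 'reference' or 'import', got {self.method!r}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**doc)

    @property
    def calibration(self) -> Calibration:
        return Calibration(self.image_width_px, self.dish_diameter_cm)


@dataclass(frozen=True)
class PlateResult:
    """Outcome for one plate: a measurement, or an error message."""

    name: str
    measurement: PlateMeasurement | None
    manual_ef: float | None = None
    relative_difference_pct: float | None = None
    error: str | None = None
    warnings: tuple[str, ...] = ()


@dataclass(frozen=True)
class PlateReport:
    """All per-plate results plus aggregate Ef statistics."""

    plates: tuple[PlateResult, ...]
    mean_ef: float | None
    max_relative_difference_pct: float | None
    mean_relative_difference_pct: float | None

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.plates:
            m = p.measurement
            rows.append(
                {
                    "plate": p.name,
                    "colony_area_px": m.colony_area_px if m else None,
                    "halo_area_px": m.halo_area_px if m else None,
                    "pixels_per_cm": m.pixels_per_cm if m else None,
                    "colony_equiv_diameter_cm": (
                        round(m.colony_equiv_diameter_cm, 4) if m else None
                    ),
                    "halo_equiv_diameter_cm": (
                        round(m.halo_equiv_diameter_cm, 4) if m else None
                    ),
                    "mode": m.mode.value if m else None,
                    "Ef": m.Ef if m else None,
                    "manual_Ef": p.manual_ef,
                    "relative_difference_pct": (
                        round(p.relative_difference_pct, 2)
                        if p.relative_difference_pct is not None
                        else None
                    ),
                    "error": p.error,
                }
            )
        return pd.DataFrame(rows)

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame = self.to_frame()
        frame.to_csv(out_dir / "report.csv", index=False)
        summary = {
            "n_plates": len(self.plates),
            "mean_ef": self.mean_ef,
            "max_relative_difference_pct": self.max_relative_difference_pct,
            "mean_relative_difference_pct": self.mean_relative_difference_pct,
            "plates": json.loads(frame.to_json(orient="records")),
        }
        (out_dir / "report.json").write_text(
            json.dumps(summary, indent=2, sort_keys=True) + "\n"
        )


def load_mask_png(path: str | Path) -> np.ndarray:
    """Read a mask image; any non-zero pixel counts as set."""
    import imageio.v3 as iio

    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., :3].max(axis=-1)
    return np.asarray(arr) > 0


def _masks_for_plate(
    spec: PlateSpec, config: PipelineConfig
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Produce the colony and total-halo mask for one plate spec."""
    notes: list[str] = []
    if spec.colony_mask and spec.halo_mask:
        return load_mask_png(spec.colony_mask), load_mask_png(spec.halo_mask), notes
    if not spec.image:
        raise ValueError(f"plate {spec.name}: neither masks nor an image given")

    image = read_plate_image(spec.image)
    if config.method == "import":
        if not spec.predictions:
            raise ValueError(
                f"plate {spec.name}: method 'import' needs a predictions file"
            )
        result: SegmentationResult = import_predictions(
            spec.predictions, image.shape
        )
    else:
        result = segment_reference(image)
    result = filter_by_confidence(result, config.confidence_threshold)
    per_class = polygons_to_masks(result)
    colonies = per_class[ClassLabel.BAC]
    halos = per_class[ClassLabel.AS]
    if not colonies:
        raise MeasurementError("no colony detected")
    if not halos:
        raise MeasurementError("no solubilization halo detected")
    if len(colonies) > 1 or len(halos) > 1:
        notes.append(
            f"{len(colonies)} colonies / {len(halos)} halo regions found; "
            "measuring the largest pair"
        )
    shape = colonies[0].shape
    colony = np.zeros(shape, dtype=bool)
    for m in colonies:
        colony |= m
    halo = np.zeros(shape, dtype=bool)
    for m in halos:
        halo |= m
    return colony, halo, notes


def run_analysis(config: PipelineConfig) -> PlateReport:
    """Run the full workflow over every configured plate.

    Per-plate failures are recorded in the report and the run continues;
    an empty plate list is an error.  Deterministic for a fixed config.
    """
    if not config.plates:
        raise ValueError("no plates configured")
    logging.basicConfig(level=config.log_level)
    cal = config.calibration
    results: list[PlateResult] = []
    for spec in config.plates:
        t0 = time.perf_counter()
        try:
            colony, halo, notes = _masks_for_plate(spec, config)
            measurement = analyze_plate(colony, halo, cal, config.ef_mode)
            rel = (
                relative_difference_pct(measurement.Ef, spec.manual_ef)
                if spec.manual_ef
                else None
            )
            results.append(
                PlateResult(
                    name=spec.name,
                    measurement=measurement,
                    manual_ef=spec.manual_ef,
                    relative_difference_pct=rel,
                    warnings=tuple(notes),
                )
            )
            if config.save_masks and config.out_dir:
                _dump_masks(spec.name, colony, halo, Path(config.out_dir))
        except Exception as exc:  # keep the batch alive on per-plate errors
            logger.error("plate %s failed: %s", spec.name, exc)
            results.append(
                PlateResult(name=spec.name, measurement=None, error=str(exc))
            )
        logger.info(
            "plate %s analyzed in %.3f s", spec.name, time.perf_counter() - t0
        )

    efs = [r.measurement.Ef for r in results if r.measurement]
    rels = [
        r.relative_difference_pct
        for r in results
        if r.relative_difference_pct is not None
    ]
    report = PlateReport(
        plates=tuple(results),
        mean_ef=round(float(np.mean(efs)), 4) if efs else None,
        max_relative_difference_pct=round(max(rels), 2) if rels else None,
        mean_relative_difference_pct=(
            round(float(np.mean(rels)), 2) if rels else None
        ),
    )
    if config.out_dir:
        report.write(config.out_dir)
    return report


def run_validation(
    pairs: Sequence[tuple[str, float, float]],
) -> pd.DataFrame:
    """Compare automated and manual Ef values plate by plate.

    ``pairs`` holds (plate name, automated Ef, manual Ef) triples; rows
    with a missing value are listed with NaN difference and excluded from
    the aggregate.  The last two rows carry the max and mean relative
    difference.
    """
    rows = []
    diffs = []
    for name, auto, manual in pairs:
        if auto is None or manual is None or not manual:
            rows.append(
                {"plate": name, "Ef_auto": auto, "Ef_manual": manual,
                 "relative_difference_pct": float("nan")}
            )
            continue
        d = round(relative_difference_pct(auto, manual), 2)
        diffs.append(d)
        rows.append(
            {"plate": name, "Ef_auto": auto, "Ef_manual": manual,
             "relative_difference_pct": d}
        )
    frame = pd.DataFrame(rows)
    if diffs:
        frame = pd.concat(
            [
                frame,
                pd.DataFrame(
                    [
                        {"plate": "max", "relative_difference_pct": max(diffs)},
                        {
                            "plate": "mean",
                            "relative_difference_pct": round(
                                float(np.mean(diffs)), 2
                            ),
                        },
                    ]
                ),
            ],
            ignore_index=True,
        )
    return frame


def _dump_masks(
    name: str, colony: np.ndarray, halo: np.ndarray, out_dir: Path
) -> None:
    from .plate_synth import write_plate_png

    mask_dir = out_dir / "masks"
    mask_dir.mkdir(parents=True, exist_ok=True)
    write_plate_png(colony.astype(float), mask_dir / f"{name}_colony.png")
    write_plate_png(halo.astype(float), mask_dir / f"{name}_halo.png")
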