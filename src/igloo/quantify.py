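"""Quantification of colony/halo masks: areas, calibration, and the
solubilization efficiency.

The headline quantity is the solubilization efficiency (or solubilization
index)

    Ef = (A + B) / A

where ``A`` is the colony measure and ``B`` the halo measure, both in the
same units.  ``B`` is always the *total* halo region (halo united with the
enclosed colony), which is why ``Ef >= 2`` whenever the halo mask contains
the colony mask.  Ef is dimensionless and scale invariant, so it is
identical whether A and B are pixel areas, cm^2 areas, or any other common
unit; a ``diameter_cm`` mode applies the same formula to equivalent-circle
diameters instead.

Pixel measurements are converted to physical units through an integer
pixels-per-centimeter factor obtained by truncating (image width in px) /
(dish diameter in cm); for a 1746 px image of an 11 cm dish this gives 158.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
from scipy import ndimage

__all__ = [
    "Calibration",
    "EfMode",
    "PlateMeasurement",
    "MeasurementError",
    "mask_area",
    "largest_component",
    "pixels_per_cm",
    "equivalent_diameter_cm",
    "solubilization_efficiency",
    "relative_difference_pct",
    "analyze_plate",
]


class MeasurementError(ValueError):
    """Raised when a measurement is requested on unusable input."""


class EfMode(str, enum.Enum):
    """Which measure Eq Ef = (A+B)/A is applied to."""

    area_px = "area_px"
    area_cm2 = "area_cm2"
    diameter_cm = "diameter_cm"


@dataclass(frozen=True)
class Calibration:
    """Pixel-to-centimeter calibration for one standardized plate image.

    The factor is the *truncated* integer quotient of image width by dish
    diameter: 1746 px / 11 cm -> 158 px/cm (158.727... truncated).
    """

    image_width_px: int
    dish_diameter_cm: float
    pixels_per_cm: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "pixels_per_cm",
            pixels_per_cm(self.image_width_px, self.dish_diameter_cm),
        )


@dataclass(frozen=True)
class PlateMeasurement:
    """Areas, diameters, and Ef for one colony/halo pair.

    ``A`` and ``B`` are the measures Ef was computed from, in the units the
    mode selects; the pixel areas and equivalent diameters are always
    recorded regardless of mode.
    """

    A: float
    B: float
    Ef: float
    mode: EfMode
    colony_area_px: int
    halo_area_px: int
    colony_equiv_diameter_cm: float
    halo_equiv_diameter_cm: float
    pixels_per_cm: int


def mask_area(mask: np.ndarray) -> int:
    """Number of set pixels in a boolean mask."""
    return int(np.count_nonzero(mask))


def largest_component(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Retain only the largest connected component of a boolean mask.

    Parameters
    ----------
    connectivity : 4 or 8 (8 by default: diagonal neighbours connect).
    """
    if connectivity not in (4, 8):
        raise ValueError(f"connectivity must be 4 or 8, got {connectivity}")
    mask = np.asarray(mask, dtype=bool)
    structure = ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return np.zeros_like(mask)
    sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
    return labels == (int(np.argmax(sizes)) + 1)


def pixels_per_cm(image_width_px: int, dish_diameter_cm: float) -> int:
    """Integer calibration factor: floor(image width / dish diameter).

    Truncation (not rounding) is the convention: 1746/11 = 158.727 -> 158.
    """
    if image_width_px <= 0 or dish_diameter_cm <= 0:
        raise ValueError(
            "image_width_px and dish_diameter_cm must both be positive, "
            f"got {image_width_px} and {dish_diameter_cm}"
        )
    factor = int(image_width_px / dish_diameter_cm)
    if factor < 1:
        raise ValueError(
            "calibration factor below 1 px/cm: image too small for dish diameter"
        )
    return factor


def equivalent_diameter_cm(area_px: int, cal: Calibration) -> float:
    """Diameter (cm) of the circle with the same pixel area: 2*sqrt(A/pi)/f."""
    if area_px < 0:
        raise ValueError(f"area_px must be non-negative, got {area_px}")
    return 2.0 * math.sqrt(area_px / math.pi) / cal.pixels_per_cm


def solubilization_efficiency(A: float, B: float) -> float:
    """Ef = (A + B)/A, rounded half-up to two decimals.

    A and B must be in the same units; the ratio is dimensionless.
    """
    if A <= 0:
        raise ValueError(f"colony measure A must be positive, got {A}")
    if B < 0:
        raise ValueError(f"halo measure B must be non-negative, got {B}")
    ef = (A + B) / A
    return float(Decimal(repr(ef)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def relative_difference_pct(value: float, reference: float) -> float:
    """Absolute relative difference |value - reference| / |reference| in %."""
    if reference == 0:
        raise ValueError("reference must be non-zero")
    return abs(value - reference) / abs(reference) * 100.0


def analyze_plate(
    colony_mask: np.ndarray,
    halo_mask: np.ndarray,
    cal: Calibration,
    mode: EfMode | str = EfMode.area_px,
) -> PlateMeasurement:
    """Measure one colony/halo mask pair and compute Ef in the given mode.

    Only the largest connected component of each mask is measured (one
    colony/halo pair per plate; smaller fragments are cleanup noise).  The
    halo mask is expected to be the total halo-plus-colony region.
    """
    mode = EfMode(mode)
    colony_mask = np.asarray(colony_mask, dtype=bool)
    halo_mask = np.asarray(halo_mask, dtype=bool)
    if colony_mask.shape != halo_mask.shape:
        raise ValueError(
            f"mask shapes differ: {colony_mask.shape} vs {halo_mask.shape}"
        )
    colony = largest_component(colony_mask)
    halo = largest_component(halo_mask)
    colony_px = mask_area(colony)
    halo_px = mask_area(halo)
    if colony_px == 0:
        raise MeasurementError("no colony detected: colony mask is empty")

    colony_d = equivalent_diameter_cm(colony_px, cal)
    halo_d = equivalent_diameter_cm(halo_px, cal)

    if mode is EfMode.area_px:
        A, B = float(colony_px), float(halo_px)
    elif mode is EfMode.area_cm2:
        f2 = cal.pixels_per_cm**2
        A, B = colony_px / f2, halo_px / f2
    else:  # diameter_cm
        A, B = colony_d, halo_d

    return PlateMeasurement(
        A=A,
        B=B,
        Ef=solubilization_efficiency(A, B),
        mode=mode,
        colony_area_px=colony_px,
        halo_area_px=halo_px,
        colony_equiv_diameter_cm=colony_d,
        halo_equiv_diameter_cm=halo_d,
        pixels_per_cm=cal.pixels_per_cm,
    )
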