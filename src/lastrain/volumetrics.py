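"""Ventricular and atrial volumetrics, body-size metrics and indexing.

LV volumes and mass come from short-axis contour stacks by summation of
discs; LA volumes from long-axis areas/lengths by the biplane area-length
method; BSA by Mosteller (Du Bois available), BMI as weight/height^2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidGeometryError, InvalidInputError
from .geometry import Contour

MYOCARDIAL_DENSITY_G_PER_ML = 1.05  # standard literature constant


@dataclass(frozen=True)
class ShortAxisSlice:
    endo_ed: Contour
    endo_es: Contour
    epi_ed: Contour


@dataclass(frozen=True)
class ShortAxisStack:
    """Short-axis LV contour stack, base to apex."""

    slices: tuple[ShortAxisSlice, ...]
    slice_thickness: float  # mm
    slice_gap: float = 0.0  # mm

    def __post_init__(self) -> None:
        if len(self.slices) < 5:
            raise InvalidInputError(f"short-axis stack needs >= 5 slices, got {len(self.slices)}")
        if self.slice_thickness <= 0:
            raise InvalidInputError("slice thickness must be positive")
        object.__setattr__(self, "slices", tuple(self.slices))


@dataclass(frozen=True)
class SubjectRecord:
    """Demographics plus derived body-size metrics for one subject."""

    id: str
    group: str  # "control" | "ObT2D"
    height_cm: float | None = None
    weight_kg: float | None = None
    age: float | None = None
    sex: str | None = None

    @property
    def bsa(self) -> float | None:
        if self.height_cm is None or self.weight_kg is None:
            return None
        return body_metrics(self.height_cm, self.weight_kg)["bsa"]

    @property
    def bmi(self) -> float | None:
        if self.height_cm is None or self.weight_kg is None:
            return None
        return body_metrics(self.height_cm, self.weight_kg)["bmi"]


def _polygon_area(contour: Contour) -> float:
    """Enclosed area (mm^2) by the shoelace formula; contour treated as closed."""
    p = contour.points
    x, y = p[:, 0], p[:, 1]
    area = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))
    if area <= 0:
        raise InvalidGeometryError("contour encloses zero area")
    return float(area)


def lv_volumes(stack: ShortAxisStack, myocardial_density: float = MYOCARDIAL_DENSITY_G_PER_ML) -> dict[str, float]:
    """Summation-of-discs LV metrics.

    Returns edv, esv, sv (mL), ef (fraction) and mass (g). Each slice
    contributes area x (thickness + gap); mass is the end-diastolic
    epicardial-minus-endocardial muscle volume times density.
    """
    dz = stack.slice_thickness + stack.slice_gap
    edv = sum(_polygon_area(s.endo_ed) for s in stack.slices) * dz / 1000.0
    esv = sum(_polygon_area(s.endo_es) for s in stack.slices) * dz / 1000.0
    epi = sum(_polygon_area(s.epi_ed) for s in stack.slices) * dz / 1000.0
    sv = edv - esv
    if edv <= 0:
        raise InvalidInputError("zero end-diastolic volume")
    muscle_ml = epi - edv
    if muscle_ml < 0:
        raise InvalidGeometryError("epicardial volume smaller than endocardial volume")
    return {
        "edv": edv,
        "esv": esv,
        "sv": sv,
        "ef": sv / edv,
        "mass": muscle_ml * myocardial_density,
    }


def la_volume_biplane(area_2ch: float, area_4ch: float, length_2ch: float, length_4ch: float) -> float:
    """Biplane area-length LA volume (mL).

    V = 0.85 * A_2ch * A_4ch / min(L_2ch, L_4ch); areas in mm^2, lengths in mm.
    """
    for v in (area_2ch, area_4ch, length_2ch, length_4ch):
        if v <= 0:
            raise InvalidInputError("areas and lengths must be positive")
    return 0.85 * area_2ch * area_4ch / min(length_2ch, length_4ch) / 1000.0


def la_volume_single_plane(area: float, length: float) -> float:
    """Single-plane area-length fallback when only one long-axis view exists."""
    if area <= 0 or length <= 0:
        raise InvalidInputError("area and length must be positive")
    return 0.85 * area * area / length / 1000.0


def body_metrics(height_cm: float, weight_kg: float, bsa_formula: str = "mosteller") -> dict[str, float]:
    """BSA (m^2) and BMI (kg/m^2) from height and weight.

    Mosteller: sqrt(h*w/3600); Du Bois: 0.007184 * h^0.725 * w^0.425.
    """
    if height_cm <= 0 or weight_kg <= 0:
        raise InvalidInputError("height and weight must be positive")
    if bsa_formula == "mosteller":
        bsa = float(np.sqrt(height_cm * weight_kg / 3600.0))
    elif bsa_formula == "dubois":
        bsa = 0.007184 * height_cm**0.725 * weight_kg**0.425
    else:
        raise InvalidInputError(f"unknown BSA formula {bsa_formula!r}")
    return {"bsa": bsa, "bmi": weight_kg / (height_cm / 100.0) ** 2}


def index_to_bsa(value: float, bsa: float) -> float:
    """Index a volume (mL) or mass (g) to body surface area."""
    if bsa <= 0:
        raise InvalidInputError("BSA must be positive")
    return value / bsa
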