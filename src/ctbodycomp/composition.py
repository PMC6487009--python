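"""Per-patient body-composition parameters and their risk cutoffs.

From the per-ROI tissue areas this module derives the seven
cross-sectional areas of the L3-L4 protocol

    A_TAT  fat in ROI A            A_MPSO  muscle in ROI C
    A_VAT  fat in ROI B            A_MSPI  muscle in ROI D
    A_SAT  A_TAT - A_VAT           A_MVEN  muscle(A) - muscle(C) - muscle(D)
                                   A_MTOT  A_MPSO + A_MSPI + A_MVEN

plus the mean muscle attenuation MA (pixel-pooled mean HU of muscle-range
pixels in ROIs C∪D, deliberately ignoring the ventral wall where ascites
mimics muscle density), the skeletal muscle index SMI = A_MTOT / height²
(cm²/m²), and sarcopenia status against sex- and BMI-specific cutoffs.
Pancreatic morphometry (duct and parenchyma diameters, DPD/DPP) is
caliper-based and stratified at the conventional 3 mm / 12 mm cutoffs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .segmentation import (
    CTSlice,
    Polygon,
    TissueRange,
    is_standardized,
    pixels_in_roi_mask,
)

CLAVIEN_GRADES = ("0", "I", "II", "IIIa", "IIIb", "IV", "V")
POPF_GRADES = ("none", "A", "B", "C")

DUCT_CUTOFF_MM = 3.0
PARENCHYMA_CUTOFF_MM = 12.0


class CompositionError(ValueError):
    pass


@dataclass(frozen=True)
class BodyComposition:
    """Derived quantities for one patient; areas in cm², MA in HU.

    ``a_sat`` is ``None`` when the body contour exceeded the scan field of
    view, in which case subcutaneous fat cannot be quantified.
    """

    a_tat: float
    a_vat: float
    a_sat: Optional[float]
    a_mpso: float
    a_mspi: float
    a_mven: float
    a_mtot: float
    ma: Optional[float] = None
    smi: Optional[float] = None
    sarcopenic_by_smi: Optional[bool] = None
    sarcopenic_by_ma: Optional[bool] = None

    @property
    def sarcopenic(self) -> Optional[bool]:
        if self.sarcopenic_by_smi is None or self.sarcopenic_by_ma is None:
            return None
        return self.sarcopenic_by_smi or self.sarcopenic_by_ma


@dataclass
class PatientRecord:
    patient_id: str
    sex: str  # "female" | "male"
    age: float
    height: float  # m
    bmi: float  # kg/m²
    dpd: Optional[float]  # mm; None = unmeasurable
    dpp: Optional[float]  # mm
    clavien_dindo: str
    popf: str
    composition: BodyComposition

    def __post_init__(self):
        if self.sex not in ("female", "male"):
            raise CompositionError(f"sex must be female/male, got {self.sex!r}")
        if self.height <= 0 or self.bmi <= 0:
            raise CompositionError("height and bmi must be > 0")
        if self.clavien_dindo not in CLAVIEN_GRADES:
            raise CompositionError(f"unknown Clavien-Dindo grade {self.clavien_dindo!r}")
        if self.popf not in POPF_GRADES:
            raise CompositionError(f"unknown ISGPF grade {self.popf!r}")
        for v, name in ((self.dpd, "dpd"), (self.dpp, "dpp")):
            if v is not None and v <= 0:
                raise CompositionError(f"{name} must be > 0 when present")

    @property
    def major_complication(self) -> bool:
        """Clavien-Dindo grade IIIb or higher."""
        return CLAVIEN_GRADES.index(self.clavien_dindo) >= CLAVIEN_GRADES.index("IIIb")

    @property
    def severe_popf(self) -> bool:
        """ISGPF grade B or C."""
        return self.popf in ("B", "C")


@dataclass(frozen=True)
class SarcopeniaThresholds:
    """Sex- and BMI-class-specific SMI/MA cutoffs (strict ``<``).

    Defaults follow the survival-prognosis convention of Martin et al.:
    SMI below 43 cm²/m² (men, BMI < 25) / 53 (men, BMI ≥ 25) / 41 (women,
    any BMI); MA below 41 HU (BMI < 25) / 33 HU (BMI ≥ 25).
    """

    smi_male_low_bmi: float = 43.0
    smi_male_high_bmi: float = 53.0
    smi_female: float = 41.0
    ma_low_bmi: float = 41.0
    ma_high_bmi: float = 33.0
    bmi_class_boundary: float = 25.0

    def __post_init__(self):
        for f in (
            self.smi_male_low_bmi, self.smi_male_high_bmi, self.smi_female,
            self.ma_low_bmi, self.ma_high_bmi, self.bmi_class_boundary,
        ):
            if f <= 0:
                raise CompositionError("all cutoffs must be positive")

    def smi_cutoff(self, sex: str, bmi: float) -> float:
        if sex == "female":
            return self.smi_female
        return (
            self.smi_male_high_bmi
            if bmi >= self.bmi_class_boundary
            else self.smi_male_low_bmi
        )

    def ma_cutoff(self, bmi: float) -> float:
        return self.ma_high_bmi if bmi >= self.bmi_class_boundary else self.ma_low_bmi


def derive_areas(
    fat_a: float,
    fat_b: float,
    muscle_a: float,
    muscle_c: float,
    muscle_d: float,
    fov_truncated: bool = False,
) -> BodyComposition:
    """Combine per-ROI fat/muscle areas (cm²) into the seven parameters.

    ``a_sat`` becomes ``None`` when the field of view is truncated;
    everything else is still computed.
    """
    for v, name in (
        (fat_a, "fat(A)"), (fat_b, "fat(B)"), (muscle_a, "muscle(A)"),
        (muscle_c, "muscle(C)"), (muscle_d, "muscle(D)"),
    ):
        if v < 0:
            raise CompositionError(f"{name} must be >= 0")
    if fat_b > fat_a:
        raise CompositionError("nesting violation: fat(B) > fat(A)")
    if muscle_c + muscle_d > muscle_a:
        raise CompositionError("nesting violation: muscle(C) + muscle(D) > muscle(A)")
    return BodyComposition(
        a_tat=fat_a,
        a_vat=fat_b,
        a_sat=None if fov_truncated else fat_a - fat_b,
        a_mpso=muscle_c,
        a_mspi=muscle_d,
        a_mven=muscle_a - muscle_c - muscle_d,
        a_mtot=muscle_a,
    )


def mean_muscle_attenuation(
    ct: CTSlice, roi_c: Polygon, roi_d: Polygon, muscle_range: TissueRange
) -> float:
    """Pixel-pooled mean HU of muscle-range pixels in ROIs C ∪ D.

    The union is taken before averaging, so an overlap between the psoas
    and paraspinal polygons is never double-counted.  Raises if no muscle
    pixel exists — an MA of 0 HU would be a valid density, not a sentinel.
    """
    if not is_standardized(ct):
        raise CompositionError("slice must be standardized to 1 mm first")
    union = pixels_in_roi_mask(ct.shape, roi_c) | pixels_in_roi_mask(ct.shape, roi_d)
    sel = union & muscle_range.contains(ct.pixels)
    if not sel.any():
        raise CompositionError("no muscle-range pixels in ROIs C ∪ D")
    return float(ct.pixels[sel].mean())


def skeletal_muscle_index(a_mtot: float, height_m: float) -> float:
    """SMI = total muscle area / height², cm²/m²."""
    if height_m <= 0:
        raise CompositionError("height must be > 0")
    if a_mtot < 0:
        raise CompositionError("a_mtot must be >= 0")
    return a_mtot / height_m**2


def classify_sarcopenia(
    smi: float,
    ma: float,
    sex: str,
    bmi: float,
    thresholds: SarcopeniaThresholds | None = None,
) -> tuple[bool, bool, bool]:
    """(by_smi, by_ma, combined) under strict-< cutoffs.

    A patient exactly at a cutoff is not sarcopenic; the combined flag is
    the OR of the two arms.
    """
    missing = [n for n, v in (("smi", smi), ("ma", ma), ("sex", sex), ("bmi", bmi))
               if v is None]
    if missing:
        raise CompositionError(f"missing covariates: {', '.join(missing)}")
    if sex not in ("female", "male"):
        raise CompositionError(f"sex must be female/male, got {sex!r}")
    th = thresholds or SarcopeniaThresholds()
    by_smi = smi < th.smi_cutoff(sex, bmi)
    by_ma = ma < th.ma_cutoff(bmi)
    return by_smi, by_ma, by_smi or by_ma


def caliper_mm(
    p1: tuple[float, float],
    p2: tuple[float, float],
    pixel_spacing: tuple[float, float],
    shape: tuple[int, int] | None = None,
) -> float:
    """Euclidean distance between two pixel points, in mm.

    Anisotropic spacing is honoured per axis.  When ``shape`` is given,
    points off the raster raise.
    """
    rs, cs = pixel_spacing
    if shape is not None:
        rows, cols = shape
        for r, c in (p1, p2):
            if not (0 <= r <= rows - 1 and 0 <= c <= cols - 1):
                raise CompositionError(f"caliper point ({r}, {c}) off the raster")
    dr = (p2[0] - p1[0]) * rs
    dc = (p2[1] - p1[1]) * cs
    return math.hypot(dr, dc)


def stratify_duct(dpd: Optional[float], cutoff: float = DUCT_CUTOFF_MM) -> str:
    """'narrow' iff DPD < cutoff (strict), 'wide' otherwise, 'unmeasurable'
    when the duct could not be seen.  Unmeasurable ducts stay their own
    category because dropping them biases toward wide ducts."""
    if cutoff <= 0:
        raise CompositionError("cutoff must be > 0")
    if dpd is None or (isinstance(dpd, float) and np.isnan(dpd)):
        return "unmeasurable"
    return "narrow" if dpd < cutoff else "wide"


def stratify_parenchyma(dpp: Optional[float], cutoff: float = PARENCHYMA_CUTOFF_MM) -> str:
    """'thin' iff DPP < cutoff (strict); same conventions as the duct."""
    if cutoff <= 0:
        raise CompositionError("cutoff must be > 0")
    if dpp is None or (isinstance(dpp, float) and np.isnan(dpp)):
        return "unmeasurable"
    return "thin" if dpp < cutoff else "thick"


def impute_unmeasurable_dpd(
    records: list[PatientRecord], standard_width_mm: float
) -> list[PatientRecord]:
    """Sensitivity mode: set every unmeasurable DPD to a standard width
    (e.g. the slice thickness) instead of excluding it."""
    if standard_width_mm <= 0:
        raise CompositionError("standard width must be > 0")
    out = []
    for r in records:
        if r.dpd is None:
            r = PatientRecord(
                patient_id=r.patient_id, sex=r.sex, age=r.age, height=r.height,
                bmi=r.bmi, dpd=standard_width_mm, dpp=r.dpp,
                clavien_dindo=r.clavien_dindo, popf=r.popf, composition=r.composition,
            )
        out.append(r)
    return out
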