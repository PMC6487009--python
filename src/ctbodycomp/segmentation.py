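"""Density-threshold tissue quantification inside polygonal ROIs.

The quantification engine works on a single axial CT slice in Hounsfield
units (HU).  Tissue is identified purely by a density window — adipose
tissue between -190 and -30 HU, skeletal muscle between -30 and 150 HU —
and counted pixel-wise inside manually placed closed-polygon regions of
interest.  Cross-sectional areas are reported in cm² after the slice
thickness has been standardized to 1 mm, so that the tool's volume
bookkeeping (cm³ per 1 mm slab) and the reported area coincide:
45.63 cm³ at 0.1 cm thickness is 456.3 cm².

Pixel membership follows one rule everywhere: a pixel belongs to a region
iff its *center* lies inside (or exactly on) the polygon boundary.  The
synthetic phantom generator rasterizes with the same rule, which is what
makes ground truth and segmentation agree bit-exactly on noise-free input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _ShapelyPolygon

HU_MIN = -1024.0
HU_MAX = 3071.0

#: printed adipose detection window, HU
ADIPOSE_RANGE = (-190.0, -30.0)
#: printed skeletal-muscle detection window, HU
MUSCLE_RANGE = (-30.0, 150.0)


class SegmentationError(ValueError):
    """Invalid slice, polygon or tissue-range input."""


@dataclass(frozen=True)
class CTSlice:
    """One axial CT slice with its geometric calibration.

    Parameters
    ----------
    pixels
        2-D float array of HU values, shape (rows, cols).
    pixel_spacing
        (row, col) spacing in mm per pixel.
    slice_thickness
        Reconstructed slice thickness in mm.
    patient_id
        Opaque identifier carried through to output tables.
    acquisition
        Free-text scanner / contrast-phase metadata, kept for audit.
    """

    pixels: np.ndarray
    pixel_spacing: tuple[float, float]
    slice_thickness: float
    patient_id: str = ""
    acquisition: dict = field(default_factory=dict)

    def __post_init__(self):
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2:
            raise SegmentationError("pixels must be a 2-D raster")
        object.__setattr__(self, "pixels", px)
        rs, cs = self.pixel_spacing
        if rs <= 0 or cs <= 0:
            raise SegmentationError("pixel_spacing components must be > 0")
        if self.slice_thickness <= 0:
            raise SegmentationError("slice_thickness must be > 0")
        if px.size and (px.min() < HU_MIN or px.max() > HU_MAX):
            raise SegmentationError(
                f"HU values outside CT representable range [{HU_MIN}, {HU_MAX}]"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def pixel_area_mm2(self) -> float:
        return self.pixel_spacing[0] * self.pixel_spacing[1]


@dataclass(frozen=True)
class TissueRange:
    """A named HU detection window with explicit bound inclusivity.

    ``interval_rule`` is one of ``"[]"``, ``"(]"``, ``"[)"``, ``"()"``.
    The defaults keep adipose ``[-190, -30]`` closed and muscle
    ``(-30, 150]`` half-open so the shared -30 HU boundary is never
    double-counted and the two windows partition ``[-190, 150]``.
    """

    name: str
    hu_low: float
    hu_high: float
    interval_rule: str = "[]"

    def __post_init__(self):
        if self.hu_low >= self.hu_high:
            raise SegmentationError("hu_low must be < hu_high")
        if self.interval_rule not in ("[]", "(]", "[)", "()"):
            raise SegmentationError(f"bad interval_rule {self.interval_rule!r}")

    def contains(self, hu: np.ndarray) -> np.ndarray:
        hu = np.asarray(hu, dtype=float)
        lo = hu >= self.hu_low if self.interval_rule[0] == "[" else hu > self.hu_low
        hi = hu <= self.hu_high if self.interval_rule[1] == "]" else hu < self.hu_high
        return lo & hi


def adipose_range() -> TissueRange:
    return TissueRange("adipose", *ADIPOSE_RANGE, interval_rule="[]")


def muscle_range() -> TissueRange:
    return TissueRange("muscle", *MUSCLE_RANGE, interval_rule="(]")


Polygon = Sequence[tuple[float, float]]  # (row, col) vertices, first != last


def _as_shapely(roi: Polygon) -> _ShapelyPolygon:
    verts = np.asarray(roi, dtype=float)
    if verts.ndim != 2 or verts.shape[1] != 2 or len(np.unique(verts, axis=0)) < 3:
        raise SegmentationError("polygon needs >= 3 distinct (row, col) vertices")
    # shapely works in (x, y) = (col, row)
    poly = _ShapelyPolygon(verts[:, ::-1])
    if not poly.is_valid or poly.area == 0:
        raise SegmentationError("polygon is self-intersecting or degenerate")
    return poly


@dataclass(frozen=True)
class ROISet:
    """The four nested ROIs of the L3-L4 protocol.

    A: outer body contour (total abdominal tissue).  B: inner border of the
    abdominal wall (visceral compartment).  C: the paired psoas muscles,
    bridged across the anterior spinal canal into one polygon.  D: outer
    border of the paravertebral muscle compartment.
    """

    roi_a: Polygon
    roi_b: Polygon
    roi_c: Polygon
    roi_d: Polygon

    def validate(self, shape: tuple[int, int]) -> None:
        """Check polygon validity and B, C, D ⊆ A by pixel membership."""
        inner = {}
        for name in ("roi_a", "roi_b", "roi_c", "roi_d"):
            inner[name] = pixels_in_roi_mask(shape, getattr(self, name))
        for name in ("roi_b", "roi_c", "roi_d"):
            if np.any(inner[name] & ~inner["roi_a"]):
                raise SegmentationError(f"{name} is not contained in roi_a")

    def as_dict(self) -> dict[str, list[list[float]]]:
        return {
            k: [list(map(float, v)) for v in getattr(self, k)]
            for k in ("roi_a", "roi_b", "roi_c", "roi_d")
        }


def standardize_slice(ct: CTSlice) -> CTSlice:
    """Normalize slice thickness to 1 mm without touching the raster.

    The scanner's 3 or 5 mm reconstruction only scales the per-voxel
    volume, not the in-plane geometry, so standardization is bookkeeping:
    the returned slice has ``slice_thickness = 1.0`` and the original
    thickness preserved under ``acquisition["original_slice_thickness_mm"]``.
    Idempotent.
    """
    if ct.slice_thickness <= 0:  # CTSlice already guards; belt and braces
        raise SegmentationError("slice_thickness must be > 0")
    meta = dict(ct.acquisition)
    meta.setdefault("original_slice_thickness_mm", ct.slice_thickness)
    return replace(ct, slice_thickness=1.0, acquisition=meta)


def is_standardized(ct: CTSlice) -> bool:
    return ct.slice_thickness == 1.0


def pixels_in_roi_mask(shape: tuple[int, int], roi: Polygon) -> np.ndarray:
    """Boolean mask of pixels whose centers fall inside the polygon.

    Pixel (r, c) has its center at coordinates (r, c); points exactly on
    the boundary count as inside.  A polygon lying wholly or partly off
    the raster simply contributes no / fewer pixels.
    """
    poly = _as_shapely(roi)
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    minx, miny, maxx, maxy = poly.bounds
    r0 = max(0, math.floor(miny))
    r1 = min(rows - 1, math.ceil(maxy))
    c0 = max(0, math.floor(minx))
    c1 = min(cols - 1, math.ceil(maxx))
    if r0 > r1 or c0 > c1:
        return mask
    rr, cc = np.meshgrid(np.arange(r0, r1 + 1), np.arange(c0, c1 + 1), indexing="ij")
    hit = shapely.intersects_xy(poly, cc.ravel().astype(float), rr.ravel().astype(float))
    mask[rr.ravel()[hit], cc.ravel()[hit]] = True
    return mask


def pixels_in_roi(ct: CTSlice, roi: Polygon) -> set[tuple[int, int]]:
    """Set of (row, col) indices of pixel centers inside the polygon."""
    mask = pixels_in_roi_mask(ct.shape, roi)
    return set(zip(*np.nonzero(mask)))


def quantify_tissue_area(ct: CTSlice, roi: Polygon, trange: TissueRange) -> float:
    """Cross-sectional tissue area in cm² inside one ROI.

    Counts pixels inside ``roi`` whose HU falls in ``trange`` and converts
    with the pixel footprint: ``count * row_spacing * col_spacing / 100``.
    Requires a 1 mm standardized slice so that the count-based area equals
    the slab volume divided by 0.1 cm.
    """
    if not is_standardized(ct):
        raise SegmentationError(
            f"slice thickness is {ct.slice_thickness} mm; call standardize_slice first"
        )
    mask = pixels_in_roi_mask(ct.shape, roi)
    n = int(np.count_nonzero(trange.contains(ct.pixels) & mask))
    return n * ct.pixel_area_mm2 / 100.0


def area_cm2_from_volume_cm3(volume_cm3: float, slice_thickness_mm: float = 1.0) -> float:
    """Slab volume → cross-sectional area (cm³ / thickness-in-cm = cm²)."""
    if slice_thickness_mm <= 0:
        raise SegmentationError("slice_thickness must be > 0")
    return volume_cm3 / (slice_thickness_mm / 10.0)


def detect_fov_truncation(ct: CTSlice, roi_a: Polygon) -> bool:
    """True iff the body contour touches or exits the image border.

    A vertex on (or beyond) the outermost row/column, or any enclosed
    pixel on the outermost row/column, counts as truncated; subcutaneous
    fat is then not quantifiable because part of it may lie outside the
    field of view.
    """
    rows, cols = ct.shape
    verts = np.asarray(roi_a, dtype=float)
    if (
        np.any(verts[:, 0] <= 0)
        or np.any(verts[:, 0] >= rows - 1)
        or np.any(verts[:, 1] <= 0)
        or np.any(verts[:, 1] >= cols - 1)
    ):
        return True
    mask = pixels_in_roi_mask(ct.shape, roi_a)
    return bool(
        mask[0, :].any() or mask[-1, :].any() or mask[:, 0].any() or mask[:, -1].any()
    )
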