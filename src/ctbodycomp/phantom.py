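"""Synthetic L3-level CT phantoms with exact rasterized ground truth.

The phantom emulates the anatomy the quantification protocol sees at the
L3-L4 intervertebral level: an elliptical body contour wrapped in a
subcutaneous fat ring, a muscular abdominal wall, a visceral compartment
mixing visceral fat and bowel gas, paired psoas muscles bridged across
the anterior spinal canal, a paraspinal muscle compartment and a
vertebral body.  Every compartment has a configurable (mean, sd) HU
distribution; with sd = 0 the raster is piecewise constant and threshold
segmentation must recover the ground-truth pixel counts exactly, because
phantom rasterization and ROI pixel membership share the same
pixel-center-inside rule.

Ground truth is defined *through the ROI polygons*: for each ROI the
truth counts the pixels (by the same membership test the segmenter uses)
whose noise-free tissue HU lies in the adipose or muscle window.  That
makes truth and measurement two paths over one discretization, which is
the property the test suite leans on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Polygon as _SPoly, box as _sbox
from shapely.ops import unary_union

from .segmentation import (
    HU_MAX,
    HU_MIN,
    CTSlice,
    ROISet,
    adipose_range,
    muscle_range,
    pixels_in_roi_mask,
)

DEFAULT_SEED = 20190427


class PhantomSpecError(ValueError):
    """Phantom geometry or HU parameterization is invalid."""


#: default per-tissue (mean HU, sd HU); means sit inside their nominal
#: detection windows so ground truth is well defined.
DEFAULT_TISSUE_HU: dict[str, tuple[float, float]] = {
    "air": (-1000.0, 0.0),
    "sat": (-95.0, 12.0),
    "visceral_fat": (-88.0, 12.0),
    "muscle_wall": (48.0, 10.0),
    "psoas": (52.0, 9.0),
    "paraspinal": (44.0, 9.0),
    "vertebra": (600.0, 120.0),
    "bowel_gas": (-650.0, 90.0),
    "ascites": (10.0, 5.0),
}

_FAT_TISSUES = ("sat", "visceral_fat")
_MUSCLE_TISSUES = ("muscle_wall", "psoas", "paraspinal")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometric and densitometric parameterization of one phantom slice.

    Lengths are mm; the body is centered on the raster with the posterior
    direction toward increasing row index.
    """

    image_size: tuple[int, int] = (256, 256)
    pixel_spacing: tuple[float, float] = (1.5, 1.5)
    slice_thickness: float = 5.0
    body_outline: tuple[float, float] = (160.0, 110.0)  # (half-width, half-height)
    sat_ring_thickness: float = 25.0
    muscle_wall_thickness: float = 10.0
    psoas_semi_axes: tuple[float, float] = (14.0, 18.0)
    paraspinal_extent: float = 55.0  # half-width; half-height is 0.3x
    vertebra_radius: float = 18.0
    visceral_fat_fraction: float = 0.55
    tissue_hu: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_HU)
    )
    ascites: bool = False
    truncate_fov: bool = False
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        hu = dict(DEFAULT_TISSUE_HU)
        hu.update(self.tissue_hu)
        object.__setattr__(self, "tissue_hu", hu)
        self._validate()

    def _validate(self) -> None:
        for name in (
            "sat_ring_thickness",
            "muscle_wall_thickness",
            "vertebra_radius",
            "paraspinal_extent",
            "slice_thickness",
        ):
            if getattr(self, name) <= 0:
                raise PhantomSpecError(f"{name} must be > 0")
        if min(self.body_outline) <= 0 or min(self.psoas_semi_axes) <= 0:
            raise PhantomSpecError("semi-axes must be > 0")
        if not 0.0 <= self.visceral_fat_fraction <= 1.0:
            raise PhantomSpecError("visceral_fat_fraction must lie in [0, 1]")
        interior = self.interior_semi_axes
        if min(interior) <= 0:
            raise PhantomSpecError(
                "nesting violation: sat ring + muscle wall vs body_outline "
                "(no interior left)"
            )
        fat = adipose_range()
        mus = muscle_range()
        for t in _FAT_TISSUES:
            if not fat.contains(np.array(self.tissue_hu[t][0])):
                raise PhantomSpecError(f"{t} mean HU outside adipose window")
        for t in _MUSCLE_TISSUES:
            if not mus.contains(np.array(self.tissue_hu[t][0])):
                raise PhantomSpecError(f"{t} mean HU outside muscle window")
        if self.tissue_hu["vertebra"][0] <= mus.hu_high:
            raise PhantomSpecError("vertebra mean HU must exceed the muscle window")
        if self.tissue_hu["bowel_gas"][0] >= fat.hu_low:
            raise PhantomSpecError("bowel_gas mean HU must lie below the adipose window")

    @property
    def interior_semi_axes(self) -> tuple[float, float]:
        a, b = self.body_outline
        d = self.sat_ring_thickness + self.muscle_wall_thickness
        return (a - d, b - d)


@dataclass(frozen=True)
class CompartmentTruth:
    fat_pixels: int
    fat_area_cm2: float
    muscle_pixels: int
    muscle_area_cm2: float


@dataclass(frozen=True)
class PhantomTruth:
    """Rasterized ground truth for one phantom.

    Pixel counts per ROI (A-D) for the adipose and muscle windows,
    their areas (count × pixel area / 100, cm²), the noise-free mean
    muscle HU over ROIs C∪D, and the ROI polygons themselves.
    """

    per_roi: dict[str, CompartmentTruth]
    ma_hu: float
    sat_quantifiable: bool
    roi_set: ROISet
    pixel_area_mm2: float

    def __post_init__(self):
        a, b = self.per_roi["A"], self.per_roi["B"]
        if b.fat_pixels > a.fat_pixels:
            raise PhantomSpecError("nesting violation: fat(B) > fat(A)")


def _ellipse_poly(cx, cy, a, b, n=256, margin=0.0) -> _SPoly:
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    return _SPoly(np.column_stack([cx + (a + margin) * np.cos(t), cy + (b + margin) * np.sin(t)]))


def _poly_to_vertices(poly: _SPoly, to_rc) -> list[tuple[float, float]]:
    xy = np.asarray(poly.exterior.coords)[:-1]  # drop closing vertex
    return [to_rc(x, y) for x, y in xy]


def _layout(spec: PhantomSpec):
    """Compartment centers/axes in body coordinates (x right, y posterior).

    The vertebral body sits near the middle of the cross-section with the
    psoas pair flanking it slightly posterolaterally and the paraspinal
    compartment wrapping behind; the compartments are laid out disjoint so
    muscle is never shared between ROIs C and D.
    """
    a_i, b_i = spec.interior_semi_axes
    vert_cy = 0.25 * b_i
    ps_a, ps_b = spec.psoas_semi_axes
    psoas_cx = spec.vertebra_radius + ps_a + 6.0
    psoas_cy = vert_cy + 3.0
    para_b = 0.3 * spec.paraspinal_extent
    para_cy = vert_cy + spec.vertebra_radius + para_b
    return {
        "vertebra": (0.0, vert_cy, spec.vertebra_radius, spec.vertebra_radius),
        "psoas_l": (-psoas_cx, psoas_cy, ps_a, ps_b),
        "psoas_r": (psoas_cx, psoas_cy, ps_a, ps_b),
        "paraspinal": (0.0, para_cy, spec.paraspinal_extent, para_b),
        "ascites": (0.0, -0.55 * b_i, 0.45 * a_i, 0.22 * b_i),
    }


def generate_phantom(spec: PhantomSpec) -> tuple[CTSlice, PhantomTruth]:
    """Rasterize the phantom and derive its ground truth.

    Returns the (noisy) HU slice at the spec's acquisition thickness and a
    :class:`PhantomTruth` computed from the same rasterization.  With all
    tissue sds at zero, threshold segmentation over the returned ROI
    polygons reproduces the truth exactly.
    """
    rows, cols = spec.image_size
    rs, cs = spec.pixel_spacing
    rng = np.random.default_rng(spec.seed)

    # pixel-center coordinates in body frame (mm); x = col axis, y = row axis
    cy0, cx0 = (rows - 1) / 2.0, (cols - 1) / 2.0
    yy = (np.arange(rows) - cy0)[:, None] * rs
    xx = (np.arange(cols) - cx0)[None, :] * cs

    a_body, b_body = spec.body_outline
    if spec.truncate_fov:
        # widen the trunk past the field of view so the contour exits the image
        a_body = cx0 * cs + 12.0

    def inside(cx, cy, a, b):
        return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0

    lay = _layout(spec)
    d_sat = spec.sat_ring_thickness
    d_wall = spec.muscle_wall_thickness
    body = inside(0, 0, a_body, b_body)
    sat_inner = inside(0, 0, a_body - d_sat, b_body - d_sat)
    wall_inner = inside(0, 0, a_body - d_sat - d_wall, b_body - d_sat - d_wall)

    vert = inside(*_xyab(lay["vertebra"]))
    psoas = inside(*_xyab(lay["psoas_l"])) | inside(*_xyab(lay["psoas_r"]))
    para = inside(*_xyab(lay["paraspinal"])) & ~vert

    for name, m in (("psoas", psoas), ("paraspinal", para), ("vertebra", vert)):
        if np.any(m & ~wall_inner):
            raise PhantomSpecError(
                f"nesting violation: {name} vs muscle-wall interior"
            )

    interior_free = wall_inner & ~vert & ~psoas & ~para
    vfat = interior_free & (rng.random((rows, cols)) < spec.visceral_fat_fraction)
    bowel = interior_free & ~vfat

    tissue = np.zeros((rows, cols), dtype=np.uint8)
    names = [
        "air", "sat", "muscle_wall", "visceral_fat", "bowel_gas",
        "psoas", "paraspinal", "vertebra", "ascites",
    ]
    code = {n: i for i, n in enumerate(names)}
    tissue[body & ~sat_inner] = code["sat"]
    tissue[sat_inner & ~wall_inner] = code["muscle_wall"]
    tissue[vfat] = code["visceral_fat"]
    tissue[bowel] = code["bowel_gas"]
    tissue[psoas] = code["psoas"]
    tissue[para] = code["paraspinal"]
    tissue[vert] = code["vertebra"]
    if spec.ascites:
        asc = inside(*_xyab(lay["ascites"])) & interior_free
        tissue[asc] = code["ascites"]

    mean_map = np.array([spec.tissue_hu[n][0] for n in names])
    sd_map = np.array([spec.tissue_hu[n][1] for n in names])
    hu0 = mean_map[tissue]
    sd = sd_map[tissue]
    pixels = hu0 + np.where(sd > 0, rng.standard_normal((rows, cols)) * sd, 0.0)
    np.clip(pixels, HU_MIN, HU_MAX, out=pixels)

    ct = CTSlice(
        pixels=pixels,
        pixel_spacing=spec.pixel_spacing,
        slice_thickness=spec.slice_thickness,
        patient_id=f"phantom-{spec.seed}",
        acquisition={"kind": "synthetic-phantom", "seed": spec.seed},
    )

    roi_set = _build_rois(spec, lay, a_body, b_body, (cx0, cy0))
    truth = _truth_from_raster(spec, ct, roi_set, hu0, mean_map, tissue, code)
    return ct, truth


def _xyab(t):
    return t


def _build_rois(spec, lay, a_body, b_body, origin) -> ROISet:
    cx0, cy0 = origin
    rs, cs = spec.pixel_spacing
    # ROI polygons are inscribed 256-gons, so a sub-micron sagitta is the
    # only gap to cover; muscle ROIs get a small fixed margin to stay clear
    # of the neighbouring compartment even on coarse grids
    margin = 0.8 * max(rs, cs)
    muscle_margin = 0.25

    def to_rc(x, y):
        return (y / rs + cy0, x / cs + cx0)

    a_i, b_i = spec.interior_semi_axes
    roi_a = _poly_to_vertices(_ellipse_poly(0, 0, a_body, b_body, margin=margin), to_rc)
    roi_b = _poly_to_vertices(_ellipse_poly(0, 0, a_i, b_i, margin=0.5), to_rc)

    # psoas pair joined by a bridge strip across the anterior spinal canal
    pl = _ellipse_poly(*lay["psoas_l"], margin=muscle_margin)
    pr = _ellipse_poly(*lay["psoas_r"], margin=muscle_margin)
    _, vy, vr, _ = lay["vertebra"]
    y_front = vy - vr  # anterior face of the vertebral body
    # strip from the anterior vertebral face back to the psoas centers, so
    # the union with both ellipses is a single simple polygon
    bridge = _sbox(lay["psoas_l"][0], y_front - 4.0, lay["psoas_r"][0], lay["psoas_l"][1])
    roi_c_poly = unary_union([pl, pr, bridge])
    if roi_c_poly.geom_type != "Polygon":
        raise PhantomSpecError("psoas bridge failed to join the pair into one polygon")
    roi_c = _poly_to_vertices(roi_c_poly, to_rc)

    roi_d = _poly_to_vertices(
        _ellipse_poly(*lay["paraspinal"], margin=muscle_margin), to_rc
    )
    return ROISet(roi_a=roi_a, roi_b=roi_b, roi_c=roi_c, roi_d=roi_d)


def _truth_from_raster(spec, ct, roi_set, hu0, mean_map, tissue, code) -> PhantomTruth:
    fat = adipose_range()
    mus = muscle_range()
    fat_nom = fat.contains(hu0)
    mus_nom = mus.contains(hu0)
    pa = ct.pixel_area_mm2
    per_roi = {}
    masks = {}
    for key, roi in (("A", roi_set.roi_a), ("B", roi_set.roi_b),
                     ("C", roi_set.roi_c), ("D", roi_set.roi_d)):
        m = pixels_in_roi_mask(ct.shape, roi)
        masks[key] = m
        nf = int(np.count_nonzero(fat_nom & m))
        nm = int(np.count_nonzero(mus_nom & m))
        per_roi[key] = CompartmentTruth(nf, nf * pa / 100.0, nm, nm * pa / 100.0)

    if np.any(masks["C"] & masks["D"] & mus_nom):
        raise PhantomSpecError(
            "nesting violation: ROIs C and D share muscle pixels"
        )
    cd = (masks["C"] | masks["D"]) & mus_nom
    if not cd.any():
        raise PhantomSpecError("phantom has no muscle pixels in ROIs C/D")
    ma_hu = float(hu0[cd].mean())

    from .segmentation import detect_fov_truncation

    truncated = detect_fov_truncation(ct, roi_set.roi_a)
    return PhantomTruth(
        per_roi=per_roi,
        ma_hu=ma_hu,
        sat_quantifiable=not truncated,
        roi_set=roi_set,
        pixel_area_mm2=pa,
    )
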