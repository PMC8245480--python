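"""Perspective-corrected area and percent-cover measurement for seafloor photos.

Oblique submersible photographs carry two 10-cm scale bars, one in the
foreground and one in the background. The cm-per-pixel scale is modeled as
a linear function of the image row (the point-slope line y - y1 = m(x - x1)
with x the row coordinate and y the linear scale), fitted from the two bars.
The area of a polygonal region of interest is then the sum over covered
pixels of scale(row)^2, the per-pixel patch area in cm^2.

Coverage statistics follow the field protocol: polygons outline the total
visible seafloor, each exposed carbonate rock, and "negative" mat-free
patches inside rock polygons; mat area is rock area minus the negatives,
and fractions (mat:rock, rock:total, mat:total) are reported in percent.

Coordinate convention: rows are 0-based from the image top; pixel (row r,
col c) has its center at continuous coordinates (x=c, y=r). A pixel belongs
to a polygon when its center is inside (even-odd rule), with boundary ties
broken toward inclusion on top/left edges.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import Polygon
from shapely.ops import unary_union

from .errors import (
    AssociationError,
    DegenerateDesignError,
    InvalidInputError,
    InvalidPolygonError,
)

#: The working resolution used for the published imagery (width, height).
STANDARD_IMAGE_SIZE = (1333, 750)

ROI_ROLES = ("total_visible", "rock", "negative")

#: Epsilon shift (px) applied to pixel centers before the point-in-polygon
#: test; breaks boundary ties toward inclusion on top/left edges.
_TIE_EPS = 1e-9

__all__ = [
    "STANDARD_IMAGE_SIZE",
    "ROI_ROLES",
    "ScaleBar",
    "PerspectiveScaleModel",
    "PolygonROI",
    "CoverageResult",
    "fit_perspective_scale",
    "measure_roi_area",
    "coverage_fractions",
]


@dataclass(frozen=True)
class ScaleBar:
    """An in-image scale bar: measured pixel length at a given image row."""

    pixel_length: float
    row: float
    true_length_cm: float = 10.0

    def __post_init__(self) -> None:
        if self.pixel_length <= 0 or self.true_length_cm <= 0:
            raise InvalidInputError("scale bar lengths must be > 0")

    @property
    def scale_cm_per_px(self) -> float:
        return self.true_length_cm / self.pixel_length


@dataclass(frozen=True)
class PerspectiveScaleModel:
    """Per-row linear scale model scale(r) = anchor_scale + m * (r - anchor_row)."""

    slope_m: float  # (cm/px) per pixel-row
    anchor_row: float  # x1: row of the background (distant) bar
    anchor_scale: float  # y1: cm/px at the anchor row
    image_size: tuple[int, int]  # (width, height) pixels

    def scale_at_row(self, row):
        """Linear cm/px scale at image row(s)."""
        return self.anchor_scale + self.slope_m * (np.asarray(row, dtype=float) - self.anchor_row)

    def validate(self) -> None:
        """Reject models whose scale is non-positive anywhere in the image."""
        height = self.image_size[1]
        edges = self.scale_at_row(np.array([0.0, height - 1.0]))
        if np.any(edges <= 0):
            raise InvalidInputError(
                "perspective model yields non-positive scale inside the image"
            )


@dataclass
class PolygonROI:
    """A region of interest in pixel coordinates with a protocol role."""

    vertices: list[tuple[float, float]]
    role: str = "rock"
    label: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROI_ROLES:
            raise InvalidInputError(f"role must be one of {ROI_ROLES}")
        if len(self.vertices) < 3:
            raise InvalidPolygonError("polygon needs >= 3 vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid or not poly.is_simple or poly.area == 0:
            raise InvalidPolygonError("polygon must be simple and non-degenerate")
        self._poly = poly

    @property
    def polygon(self) -> Polygon:
        return self._poly


@dataclass(frozen=True)
class CoverageResult:
    """Perspective-corrected areas (m^2) and percent-cover fractions."""

    total_area_m2: float
    rock_area_m2: float
    mat_area_m2: float
    mat_rock_fraction_pct: float
    rock_total_fraction_pct: float
    mat_total_fraction_pct: float


def fit_perspective_scale(
    foreground: ScaleBar,
    background: ScaleBar,
    image_size: tuple[int, int] = STANDARD_IMAGE_SIZE,
) -> PerspectiveScaleModel:
    """Fit the two-bar linear row-scale model.

    y2 = 10 cm / foreground pixel length, y1 = 10 cm / background pixel
    length, and m = (y2 - y1) / (x2 - x1) with x2, x1 the bars' rows. The
    background bar is the anchor (x1, y1).
    """
    if foreground.row == background.row:
        raise DegenerateDesignError(
            "scale bars at identical rows; perspective slope undefined"
        )
    y2 = foreground.scale_cm_per_px
    y1 = background.scale_cm_per_px
    m = (y2 - y1) / (foreground.row - background.row)
    model = PerspectiveScaleModel(
        slope_m=m,
        anchor_row=background.row,
        anchor_scale=y1,
        image_size=image_size,
    )
    model.validate()
    return model


def _rasterize_weighted_area(model: PerspectiveScaleModel, geom) -> float:
    """Sum of scale(row)^2 over pixels whose center lies in ``geom`` (cm^2)."""
    if geom.is_empty:
        return 0.0
    minx, miny, maxx, maxy = geom.bounds
    c0 = max(int(np.ceil(minx - 0.5 - _TIE_EPS)), 0)
    c1 = min(int(np.floor(maxx + 0.5)), model.image_size[0] - 1)
    r0 = max(int(np.ceil(miny - 0.5 - _TIE_EPS)), 0)
    r1 = min(int(np.floor(maxy + 0.5)), model.image_size[1] - 1)
    if c1 < c0 or r1 < r0:
        return 0.0
    cols = np.arange(c0, c1 + 1)
    rows = np.arange(r0, r1 + 1)
    X, Y = np.meshgrid(cols.astype(float), rows.astype(float))
    inside = shapely.contains_xy(geom, X + _TIE_EPS, Y + _TIE_EPS)
    weights = model.scale_at_row(rows.astype(float)) ** 2  # cm^2 per pixel
    return float((inside.sum(axis=1) * weights).sum())


def measure_roi_area(model: PerspectiveScaleModel, roi: PolygonROI) -> float:
    """Perspective-corrected area of one ROI in cm^2.

    Rasterizes the polygon at pixel resolution and sums the per-pixel area
    weight scale(row)^2 over covered pixels.
    """
    poly = roi.polygon
    w, h = model.image_size
    minx, miny, maxx, maxy = poly.bounds
    if minx < -0.5 or miny < -0.5 or maxx > w - 0.5 or maxy > h - 0.5:
        raise InvalidInputError(
            f"polygon bounds {poly.bounds} exceed image extent "
            f"[-0.5, {w - 0.5}] x [-0.5, {h - 0.5}]"
        )
    return _rasterize_weighted_area(model, poly)


def coverage_fractions(
    model: PerspectiveScaleModel,
    total: PolygonROI,
    rocks: list[PolygonROI],
    negatives: list[PolygonROI] | None = None,
) -> CoverageResult:
    """Mat/rock/total areas (m^2) and percent-cover fractions.

    Overlapping rock ROIs are unioned before measurement (no double
    counting), and the rock region is clipped to the total-visible ROI so
    the ordering mat <= rock <= total holds by construction. Each negative
    ROI must be contained in the rock region; mat area is the rock area
    minus the negatives.
    """
    negatives = negatives or []
    total_cm2 = measure_roi_area(model, total)
    if not rocks:
        if negatives:
            raise AssociationError("negative ROIs given but no rock ROIs")
        warnings.warn("no rock ROIs; coverage fractions reported as 0", stacklevel=2)
        return CoverageResult(total_cm2 * 1e-4, 0.0, 0.0, 0.0, 0.0, 0.0)

    rock_union = unary_union([r.polygon for r in rocks]).intersection(total.polygon)
    for neg in negatives:
        if not rock_union.covers(neg.polygon):
            raise AssociationError(
                f"negative ROI {neg.label or neg.vertices[:1]} is not contained "
                "in any rock ROI"
            )
    rock_cm2 = _rasterize_weighted_area(model, rock_union)
    neg_union = unary_union([n.polygon for n in negatives]) if negatives else None
    neg_cm2 = _rasterize_weighted_area(model, neg_union) if neg_union is not None else 0.0
    mat_cm2 = rock_cm2 - neg_cm2
    if mat_cm2 < 0:
        raise InvalidInputError(
            "negative ROI area exceeds rock area; inconsistent ROI set"
        )

    def pct(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else 0.0

    return CoverageResult(
        total_area_m2=total_cm2 * 1e-4,
        rock_area_m2=rock_cm2 * 1e-4,
        mat_area_m2=mat_cm2 * 1e-4,
        mat_rock_fraction_pct=pct(mat_cm2, rock_cm2),
        rock_total_fraction_pct=pct(rock_cm2, total_cm2),
        mat_total_fraction_pct=pct(mat_cm2, total_cm2),
    )
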