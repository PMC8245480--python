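"""Seeded synthetic-data generators mirroring each pipeline stage's inputs.

Every generator is a pure function of (spec, seed) and returns ground truth
alongside the data, so each analysis stage has a recovery test that needs
no external download. Defaults reproduce the experimental design constants:
a 21-day bioreactor run harvested every 96 h (6 harvests, 2 weighed coupons
each, 12.7 mm coupons), a biofilm pH profile dipping from ~7.65 at the
mineral to 7.33 mid-biofilm and relaxing toward bulk values, and seafloor
scenes with two 10-cm scale bars and rectangular ROIs whose
perspective-weighted areas are known in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator

from .constants import CONSTANTS
from .coupons import CouponRecord, estimate_coupon_surface_area
from .errors import InvalidInputError
from .phimaging import CalibrationCurve, DualChannelStack
from .seafloor import PerspectiveScaleModel, PolygonROI, ScaleBar

__all__ = [
    "CouponExperimentSpec",
    "PhSceneSpec",
    "SeafloorSceneSpec",
    "RectROISpec",
    "generate_coupon_experiment",
    "ph_depth_profile",
    "generate_ph_stack",
    "generate_seafloor_scene",
    "rect_weighted_area",
    "polygon_weighted_area_exact",
]


# --------------------------------------------------------------------------
# Coupon mass-loss experiments
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CouponExperimentSpec:
    """Design of a synthetic coupon dissolution experiment.

    The default schedule is one harvest every 96 h for 21 days (6 harvests,
    2 coupons each). ``mass_noise_sd_mg`` is the balance/handling noise on
    the final mass; 7 mg reproduces the ~18% relative standard error of the
    measured thiosulfate rate under this design (closed-form OLS error
    propagation on the 12-coupon schedule, Sxx = 322,560 h^2, at the mean
    coupon surface area).
    """

    true_rate: float = 1773.97  # umol CaCO3 cm^-2 yr^-1
    n_harvests: int = 6
    harvest_interval_h: float = 96.0
    coupons_per_harvest: int = 2
    mass_noise_sd_mg: float = 7.0
    initial_mass_range_mg: tuple[float, float] = (400.0, 1100.0)
    diameter_mm: float = 12.7
    condition: str = "thiosulfate"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_harvests < 1 or self.coupons_per_harvest < 1:
            raise InvalidInputError("counts must be >= 1")
        if self.mass_noise_sd_mg < 0:
            raise InvalidInputError("mass_noise_sd_mg must be >= 0")


def generate_coupon_experiment(
    spec: CouponExperimentSpec,
) -> tuple[list[CouponRecord], dict]:
    """Simulate coupon records with linear mass loss plus Gaussian noise.

    For a coupon harvested at time t, the expected areal loss is
    true_rate x t / 8760 (umol/cm^2); it is converted back to a mass loss
    through the coupon's (pre-dissolution) surface area, and Gaussian noise
    of sd ``mass_noise_sd_mg`` is added to the final mass. Returns the
    records and a ground-truth dict (true rate, slope, per-coupon noiseless
    losses).
    """
    rng = np.random.default_rng(spec.seed)
    slope_per_hour = spec.true_rate / CONSTANTS.hours_per_year
    records: list[CouponRecord] = []
    true_losses: list[float] = []
    for h in range(1, spec.n_harvests + 1):
        t = h * spec.harvest_interval_h
        for c in range(spec.coupons_per_harvest):
            m0 = rng.uniform(*spec.initial_mass_range_mg)
            area = estimate_coupon_surface_area(m0, spec.diameter_mm)
            loss_mg = (
                slope_per_hour * t * area * CONSTANTS.mg_per_umol_caco3
            )
            noise = rng.normal(0.0, spec.mass_noise_sd_mg) if spec.mass_noise_sd_mg else 0.0
            records.append(
                CouponRecord(
                    coupon_id=f"h{h:02d}c{c + 1}",
                    condition=spec.condition,
                    initial_mass_mg=m0,
                    final_mass_mg=m0 - loss_mg + noise,
                    hours_in_reactor=t,
                    diameter_mm=spec.diameter_mm,
                )
            )
            true_losses.append(loss_mg)
    truth = {
        "true_rate": spec.true_rate,
        "true_slope_per_hour": slope_per_hour,
        "true_losses_mg": true_losses,
    }
    return records, truth


# --------------------------------------------------------------------------
# Biofilm pH stacks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PhSceneSpec:
    """Forward model of a biofilm pH depth profile imaged ratiometrically.

    The prescribed profile starts at ``ph_mineral`` on the substratum
    (z = 0), dips monotonically to ``ph_min`` at ``min_depth_um`` and
    relaxes to ``ph_bulk`` by ``bulk_depth_um`` (shape-preserving cubic
    through the three control points, constant beyond). Intensities follow
    the dye model: the 561 nm channel is a flat reference signal, the
    488 nm channel is the reference times the calibration ratio, both with
    multiplicative Gaussian noise of CV ``noise_cv`` plus scalar
    backgrounds.
    """

    ph_mineral: float = 7.65
    ph_min: float = 7.33
    min_depth_um: float = 30.0
    ph_bulk: float = 7.76
    bulk_depth_um: float = 80.0
    calibration: CalibrationCurve = field(
        default_factory=lambda: CalibrationCurve(r_min=0.2, r_max=2.0, pka=7.5)
    )
    intensity_scale_561: float = 1000.0
    noise_cv: float = 0.02
    background_488: float = 100.0
    background_561: float = 100.0
    shape: tuple[int, int, int] = (40, 64, 128)  # (z, y, x)
    voxel_size_um: tuple[float, float, float] = (4.0, 4.0, 2.5)  # (x, y, z)
    noise_model: str = "gaussian"  # or "poisson"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_cv < 0:
            raise InvalidInputError("noise_cv must be >= 0")
        if self.noise_model not in ("gaussian", "poisson"):
            raise InvalidInputError("noise_model must be 'gaussian' or 'poisson'")
        lo, hi = self.calibration.ph_range
        for ph in (self.ph_mineral, self.ph_min, self.ph_bulk):
            if not lo <= ph <= hi:
                raise InvalidInputError(
                    f"pH {ph} outside calibration range ({lo}, {hi})"
                )


def ph_depth_profile(spec: PhSceneSpec):
    """Callable z (um) -> pH implementing the spec's piecewise-smooth profile."""
    zs = [0.0, spec.min_depth_um, spec.bulk_depth_um]
    phs = [spec.ph_mineral, spec.ph_min, spec.ph_bulk]
    interp = PchipInterpolator(zs, phs, extrapolate=False)

    def profile(z):
        z = np.asarray(z, dtype=float)
        out = interp(np.clip(z, 0.0, spec.bulk_depth_um))
        return out

    return profile


def generate_ph_stack(spec: PhSceneSpec) -> tuple[DualChannelStack, np.ndarray]:
    """Generate a dual-channel stack and its ground-truth 3-D pH field.

    Per voxel: true ratio R = R(pH) from the calibration; the 561 nm signal
    is intensity_scale_561 x (1 + noise) + background_561; the 488 nm
    signal is R x intensity_scale_561 x (1 + noise') + background_488, with
    independent channel noise. With noise_cv = 0, compute_ratio_image
    recovers R(pH) exactly.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    dz = spec.voxel_size_um[2]
    z_um = np.arange(nz) * dz
    ph_z = ph_depth_profile(spec)(z_um)
    ph_field = np.broadcast_to(ph_z[:, None, None], spec.shape).copy()
    true_ratio = spec.calibration.ratio(ph_field)

    signal_561 = np.full(spec.shape, spec.intensity_scale_561)
    signal_488 = true_ratio * spec.intensity_scale_561
    if spec.noise_cv > 0:
        if spec.noise_model == "gaussian":
            signal_488 = signal_488 * (1.0 + rng.normal(0.0, spec.noise_cv, spec.shape))
            signal_561 = signal_561 * (1.0 + rng.normal(0.0, spec.noise_cv, spec.shape))
        else:
            # Poisson shot noise with per-voxel expected counts chosen so the
            # relative fluctuation at the reference intensity equals noise_cv.
            counts = 1.0 / spec.noise_cv**2
            signal_488 = rng.poisson(signal_488 / spec.intensity_scale_561 * counts) * (
                spec.intensity_scale_561 / counts
            )
            signal_561 = rng.poisson(signal_561 / spec.intensity_scale_561 * counts) * (
                spec.intensity_scale_561 / counts
            )
    stack = DualChannelStack(
        intensities_488=signal_488 + spec.background_488,
        intensities_561=signal_561 + spec.background_561,
        voxel_size_um=spec.voxel_size_um,
        background_488=spec.background_488,
        background_561=spec.background_561,
    )
    return stack, ph_field


# --------------------------------------------------------------------------
# Seafloor scenes
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class RectROISpec:
    """Axis-aligned rectangular ROI covering whole pixels.

    ``rows`` and ``cols`` are inclusive 0-based pixel index ranges; the
    emitted polygon spans the covered pixel centers' cells, i.e. from
    (col0-0.5, row0-0.5) to (col1+0.5, row1+0.5).
    """

    rows: tuple[int, int]
    cols: tuple[int, int]
    role: str = "rock"
    label: str = ""


@dataclass(frozen=True)
class SeafloorSceneSpec:
    """A perspective scene with known scale model and rectangular ROIs."""

    true_model: PerspectiveScaleModel
    bar_rows: tuple[float, float] = (600.0, 150.0)  # (foreground, background)
    bar_true_length_cm: float = 10.0
    rois: tuple[RectROISpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for row in self.bar_rows:
            if self.true_model.scale_at_row(row) <= 0:
                raise InvalidInputError(f"scale non-positive at bar row {row}")


def rect_weighted_area(model: PerspectiveScaleModel, rect: RectROISpec) -> float:
    """Exact sum of scale(row)^2 over a rectangle of whole pixels (cm^2)."""
    r0, r1 = rect.rows
    ncols = rect.cols[1] - rect.cols[0] + 1
    rows = np.arange(r0, r1 + 1, dtype=float)
    return float(ncols * np.sum(model.scale_at_row(rows) ** 2))


def _rect_polygon(rect: RectROISpec) -> PolygonROI:
    r0, r1 = rect.rows
    c0, c1 = rect.cols
    verts = [
        (c0 - 0.5, r0 - 0.5),
        (c1 + 0.5, r0 - 0.5),
        (c1 + 0.5, r1 + 0.5),
        (c0 - 0.5, r1 + 0.5),
    ]
    return PolygonROI(vertices=verts, role=rect.role, label=rect.label)


def generate_seafloor_scene(
    spec: SeafloorSceneSpec,
) -> tuple[tuple[ScaleBar, ScaleBar], dict, dict[str, float]]:
    """Emit scale bars, GeoJSON ROIs, and the scene's true areas (cm^2).

    The bars' pixel lengths are exactly true_length / scale_at_row(bar_row)
    so that refitting the two-bar model recovers the true model. The truth
    dict maps each ROI label to its closed-form weighted area.
    """
    model = spec.true_model
    fg_row, bg_row = spec.bar_rows
    bars = (
        ScaleBar(
            pixel_length=spec.bar_true_length_cm / model.scale_at_row(fg_row),
            row=fg_row,
            true_length_cm=spec.bar_true_length_cm,
        ),
        ScaleBar(
            pixel_length=spec.bar_true_length_cm / model.scale_at_row(bg_row),
            row=bg_row,
            true_length_cm=spec.bar_true_length_cm,
        ),
    )
    features = []
    truth: dict[str, float] = {}
    for i, rect in enumerate(spec.rois):
        label = rect.label or f"roi{i}"
        poly = _rect_polygon(rect)
        features.append(
            {
                "type": "Feature",
                "properties": {"role": rect.role, "label": label},
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [list(map(list, poly.vertices)) + [list(poly.vertices[0])]],
                },
            }
        )
        truth[label] = rect_weighted_area(model, rect)
    geojson = {"type": "FeatureCollection", "features": features}
    return bars, geojson, truth


def polygon_weighted_area_exact(
    model: PerspectiveScaleModel, polygon
) -> float:
    """Analytic weighted area of an arbitrary polygon (cm^2).

    Computes the continuous integral of scale(y)^2 over the polygon by
    splitting [ymin, ymax] at vertex rows (the polygon's horizontal width
    is linear in y between vertices, so the integrand is cubic) and
    applying 2-point Gauss-Legendre quadrature, which is exact for cubics.
    Serves as the independent oracle for the pixel-sum measurement.
    """
    from shapely.geometry import LineString

    geom = polygon.polygon if isinstance(polygon, PolygonROI) else polygon
    ys = sorted({float(y) for _, y in np.asarray(geom.exterior.coords)})
    minx, _, maxx, _ = geom.bounds
    # Gauss-Legendre nodes on [-1, 1]
    g = 1.0 / math.sqrt(3.0)
    total = 0.0
    for y0, y1 in zip(ys[:-1], ys[1:]):
        half = 0.5 * (y1 - y0)
        mid = 0.5 * (y0 + y1)
        for node in (-g, g):
            y = mid + half * node
            cut = geom.intersection(
                LineString([(minx - 1.0, y), (maxx + 1.0, y)])
            )
            width = cut.length
            total += half * width * float(model.scale_at_row(y)) ** 2
    return total
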