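"""Ratiometric biofilm pH mapping from dual-excitation confocal stacks.

A pH-sensitive seminaphthofluorescein dye (C-SNAFL-1) is excited at 488 nm
and 561 nm with a single emission window; the background-subtracted ratio of
the two excitation intensities encodes local pH,

    ratio = (I488 - bkgd488) / (I561 - bkgd561).

A titration of buffered media at known pH yields calibration points that are
fitted with a single-pKa sigmoid

    R(pH) = r_min + (r_max - r_min) / (1 + 10**(pKa - pH)),

whose exact analytic inverse converts ratio images to pH. Depth profiles
("kymographs") through a biofilm average the ratio over a line x width band
at each z plane; z = 0 is the substratum (the mineral surface) and z
increases toward the bulk fluid.

Arrays are indexed (z, y, x); voxel (k, i, j) has its center at continuous
coordinates x = j * dx, y = i * dy, z = k * dz with (dx, dy, dz) from
``voxel_size_um``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from .errors import (
    InsufficientDataError,
    InvalidInputError,
    OutOfRangeError,
)

__all__ = [
    "DualChannelStack",
    "RatioImage",
    "CalibrationPoint",
    "CalibrationCurve",
    "PiecewiseLinearCalibration",
    "KymographSpec",
    "PhProfile",
    "compute_ratio_image",
    "fit_calibration",
    "ratio_to_ph",
    "extract_kymograph",
]


@dataclass
class DualChannelStack:
    """Paired 488/561 nm excitation-intensity voxel arrays.

    voxel_size_um is (x, y, z) in micrometers; arrays are (z, y, x).
    Backgrounds are scalar per-channel intensity offsets.
    """

    intensities_488: np.ndarray
    intensities_561: np.ndarray
    voxel_size_um: tuple[float, float, float]
    background_488: float = 0.0
    background_561: float = 0.0

    def __post_init__(self) -> None:
        self.intensities_488 = np.asarray(self.intensities_488, dtype=float)
        self.intensities_561 = np.asarray(self.intensities_561, dtype=float)
        if self.intensities_488.shape != self.intensities_561.shape:
            raise InvalidInputError(
                f"channel shapes differ: {self.intensities_488.shape} vs "
                f"{self.intensities_561.shape}"
            )
        if self.intensities_488.ndim != 3:
            raise InvalidInputError("stacks must be 3-D (z, y, x)")
        if any(v <= 0 for v in self.voxel_size_um):
            raise InvalidInputError("voxel_size_um components must be > 0")
        if self.background_488 < 0 or self.background_561 < 0:
            raise InvalidInputError("backgrounds must be >= 0")


@dataclass
class RatioImage:
    """Excitation-ratio image with an undefined-voxel mask.

    ``ratios`` holds NaN where masked; ``mask`` is True where the ratio is
    undefined (numerator or denominator <= 0 after background subtraction).
    """

    ratios: np.ndarray
    mask: np.ndarray
    provenance: DualChannelStack | None = None

    @property
    def n_unmasked(self) -> int:
        return int((~self.mask).sum())


@dataclass(frozen=True)
class CalibrationPoint:
    ph: float
    ratio: float

    def __post_init__(self) -> None:
        if not 0 < self.ph < 14:
            raise InvalidInputError(f"pH {self.ph} outside (0, 14)")
        if self.ratio <= 0:
            raise InvalidInputError("calibration ratio must be > 0")


def _sigmoid(ph, r_min, r_max, pka):
    return r_min + (r_max - r_min) / (1.0 + 10.0 ** (pka - ph))


@dataclass(frozen=True)
class CalibrationCurve:
    """Single-pKa sigmoid mapping between pH and excitation ratio.

    ``direction`` is "increasing" when ratio grows with pH (r_max > r_min).
    Inversion is defined only for ratios strictly between r_min and r_max.
    ``ph_range`` records the pH span of the titration points the curve was
    fitted on; conversions outside it are extrapolations.
    """

    r_min: float
    r_max: float
    pka: float
    fit_residual_rms: float = 0.0
    ph_range: tuple[float, float] = (6.8, 8.0)

    def __post_init__(self) -> None:
        if self.r_min == self.r_max:
            raise InvalidInputError("r_min and r_max must differ")

    @property
    def direction(self) -> str:
        return "increasing" if self.r_max > self.r_min else "decreasing"

    def ratio(self, ph):
        """Forward model R(pH); accepts scalars or arrays."""
        return _sigmoid(np.asarray(ph, dtype=float), self.r_min, self.r_max, self.pka)

    def ph(self, ratio):
        """Exact analytic inverse pH(R) = pKa + log10((R - r_min)/(r_max - R))."""
        r = np.asarray(ratio, dtype=float)
        lo, hi = sorted((self.r_min, self.r_max))
        if np.any((r <= lo) | (r >= hi)):
            raise OutOfRangeError(
                f"ratio outside open interval ({lo:.6g}, {hi:.6g})"
            )
        out = self.pka + np.log10((r - self.r_min) / (self.r_max - r))
        return float(out) if np.isscalar(ratio) else out


@dataclass(frozen=True)
class PiecewiseLinearCalibration:
    """Monotone piecewise-linear interpolation of titration points.

    Alternative calibration form; same .ratio()/.ph() interface as
    CalibrationCurve.
    """

    phs: tuple[float, ...]
    ratios: tuple[float, ...]

    def __post_init__(self) -> None:
        diffs = np.diff(self.ratios)
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise InvalidInputError(
                "piecewise-linear calibration requires strictly monotone ratios"
            )

    @property
    def direction(self) -> str:
        return "increasing" if self.ratios[-1] > self.ratios[0] else "decreasing"

    @property
    def ph_range(self) -> tuple[float, float]:
        return (self.phs[0], self.phs[-1])

    def ratio(self, ph):
        return np.interp(np.asarray(ph, dtype=float), self.phs, self.ratios)

    def ph(self, ratio):
        r = np.asarray(ratio, dtype=float)
        lo, hi = sorted((self.ratios[0], self.ratios[-1]))
        if np.any((r <= lo) | (r >= hi)):
            raise OutOfRangeError(f"ratio outside open interval ({lo}, {hi})")
        xs = np.asarray(self.ratios, dtype=float)
        ys = np.asarray(self.phs, dtype=float)
        if xs[0] > xs[-1]:
            xs, ys = xs[::-1], ys[::-1]
        out = np.interp(r, xs, ys)
        return float(out) if np.isscalar(ratio) else out


@dataclass(frozen=True)
class KymographSpec:
    """Band through the image over which depth profiles are averaged.

    The line runs from ``start_um`` to ``end_um`` in the xy plane
    (micrometers); the band is ``width_um`` wide (13 um as used for biofilm
    transects). ``depth_range_um`` limits the z extent (None = full stack).
    """

    start_um: tuple[float, float]
    end_um: tuple[float, float]
    width_um: float = 13.0
    depth_range_um: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.width_um <= 0:
            raise InvalidInputError("width_um must be > 0")
        if math.dist(self.start_um, self.end_um) == 0:
            raise InvalidInputError("kymograph line has zero length")
        if self.depth_range_um is not None and (
            self.depth_range_um[1] < self.depth_range_um[0]
        ):
            raise InvalidInputError("depth_range_um must be (low, high)")


@dataclass
class PhProfile:
    """pH as a function of depth above the substratum.

    ``summary`` holds (ph_at_mineral, ph_min, ph_bulk): the pH at the
    shallowest valid plane, the profile minimum, and the pH at the deepest
    (most bulk-ward) valid plane. Missing planes are NaN.
    """

    depths_um: np.ndarray
    ph_values: np.ndarray
    summary: dict[str, float] = field(default_factory=dict)


def compute_ratio_image(stack: DualChannelStack) -> RatioImage:
    """Background-subtracted 488/561 excitation ratio per voxel.

    Voxels whose background-subtracted numerator or denominator is <= 0
    carry no ratio and are masked.
    """
    num = stack.intensities_488 - stack.background_488
    den = stack.intensities_561 - stack.background_561
    mask = (num <= 0) | (den <= 0)
    ratios = np.full(num.shape, np.nan)
    np.divide(num, den, out=ratios, where=~mask)
    return RatioImage(ratios=ratios, mask=mask, provenance=stack)


def fit_calibration(
    points: list[CalibrationPoint],
    form: str = "sigmoid",
    monotone_tol: float = 0.05,
) -> CalibrationCurve | PiecewiseLinearCalibration:
    """Fit a ratio-vs-pH titration curve.

    ``form="sigmoid"`` (default) fits the single-pKa sigmoid by nonlinear
    least squares; ``form="linear"`` returns a monotone piecewise-linear
    interpolator. At least 4 distinct pH points are required. Points that
    are non-monotone beyond ``monotone_tol`` (relative to the fitted ratio
    span) trigger a fit-quality warning.
    """
    if len({p.ph for p in points}) < 4:
        raise InsufficientDataError(
            "calibration needs >= 4 distinct pH points"
        )
    pts = sorted(points, key=lambda p: p.ph)
    phs = np.array([p.ph for p in pts])
    ratios = np.array([p.ratio for p in pts])

    if form == "linear":
        return PiecewiseLinearCalibration(tuple(phs), tuple(ratios))
    if form != "sigmoid":
        raise InvalidInputError(f"unknown calibration form {form!r}")

    # direction from the overall trend; seeds the fit
    increasing = ratios[-1] >= ratios[0]
    span = float(ratios.max() - ratios.min())
    diffs = np.diff(ratios) * (1 if increasing else -1)
    if span > 0 and np.any(diffs < -monotone_tol * span):
        warnings.warn(
            "titration points are non-monotone beyond tolerance; "
            "check calibration data quality",
            stacklevel=2,
        )
    pad = 0.05 * span if span > 0 else 0.1
    if increasing:
        p0 = (ratios.min() - pad, ratios.max() + pad, float(np.median(phs)))
    else:
        p0 = (ratios.max() + pad, ratios.min() - pad, float(np.median(phs)))
    popt, _ = curve_fit(_sigmoid, phs, ratios, p0=p0, maxfev=20000)
    resid = ratios - _sigmoid(phs, *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    return CalibrationCurve(
        r_min=float(popt[0]),
        r_max=float(popt[1]),
        pka=float(popt[2]),
        fit_residual_rms=rms,
        ph_range=(float(phs[0]), float(phs[-1])),
    )


def ratio_to_ph(curve, ratio, clamp: bool = False):
    """Convert ratio(s) to pH via the calibration curve's analytic inverse.

    Out-of-range ratios raise OutOfRangeError unless ``clamp=True``, in
    which case they are pulled just inside the open calibration interval
    (an explicit, opt-in extrapolation guard).
    """
    if clamp:
        lo, hi = sorted(
            (curve.r_min, curve.r_max)
            if isinstance(curve, CalibrationCurve)
            else (curve.ratios[0], curve.ratios[-1])
        )
        eps = 1e-9 * (hi - lo)
        ratio = np.clip(ratio, lo + eps, hi - eps)
        if np.isscalar(ratio):
            ratio = float(ratio)
    return curve.ph(ratio)


def _band_mask(shape_yx, voxel_size_um, spec: KymographSpec) -> np.ndarray:
    """Boolean (y, x) mask of pixel centers within the kymograph band."""
    dx, dy = voxel_size_um[0], voxel_size_um[1]
    ny, nx = shape_yx
    xs = np.arange(nx) * dx
    ys = np.arange(ny) * dy
    X, Y = np.meshgrid(xs, ys)
    (x0, y0), (x1, y1) = spec.start_um, spec.end_um
    vx, vy = x1 - x0, y1 - y0
    length2 = vx * vx + vy * vy
    t = ((X - x0) * vx + (Y - y0) * vy) / length2
    # perpendicular distance to the (infinite) line; band limited to segment
    dist = np.abs((X - x0) * vy - (Y - y0) * vx) / math.sqrt(length2)
    return (t >= 0.0) & (t <= 1.0) & (dist <= spec.width_um / 2.0)


def extract_kymograph(
    ratio_image: RatioImage,
    spec: KymographSpec,
    curve,
    averaging: str = "ratio",
) -> PhProfile:
    """Depth profile of pH averaged over a line x width band.

    At each z plane the unmasked ratios inside the band are averaged and
    converted to pH (``averaging="ratio"``, the default, which averages the
    ratio image); ``averaging="intensity"`` instead averages the
    background-subtracted intensities of each channel over the band first
    and ratios the two means (requires provenance stack). Planes whose band
    is entirely masked yield NaN but the profile is still returned.
    """
    stack = ratio_image.provenance
    if stack is None:
        raise InvalidInputError("ratio image lacks provenance stack (voxel size)")
    if averaging not in ("ratio", "intensity"):
        raise InvalidInputError("averaging must be 'ratio' or 'intensity'")
    dz = stack.voxel_size_um[2]
    nz, ny, nx = ratio_image.ratios.shape
    band = _band_mask((ny, nx), stack.voxel_size_um, spec)
    if not band.any():
        raise InvalidInputError("kymograph band lies outside the image bounds")

    depths = np.arange(nz) * dz
    if spec.depth_range_um is not None:
        lo, hi = spec.depth_range_um
        keep = (depths >= lo) & (depths <= hi)
        if not keep.any():
            raise InvalidInputError("depth_range_um selects no z planes")
    else:
        keep = np.ones(nz, dtype=bool)

    z_idx = np.nonzero(keep)[0]
    ph_values = np.full(z_idx.size, np.nan)
    for out_i, k in enumerate(z_idx):
        if averaging == "ratio":
            vals = ratio_image.ratios[k][band]
            vals = vals[np.isfinite(vals)]
            if vals.size == 0:
                continue
            mean_ratio = float(vals.mean())
        else:
            sel = band & ~ratio_image.mask[k]
            if not sel.any():
                continue
            num = (stack.intensities_488[k] - stack.background_488)[sel].mean()
            den = (stack.intensities_561[k] - stack.background_561)[sel].mean()
            if den <= 0:
                continue
            mean_ratio = float(num / den)
        try:
            ph_values[out_i] = ratio_to_ph(curve, mean_ratio)
        except OutOfRangeError:
            ph_values[out_i] = np.nan

    valid = np.isfinite(ph_values)
    summary: dict[str, float] = {}
    if valid.any():
        vi = np.nonzero(valid)[0]
        summary = {
            "ph_at_mineral": float(ph_values[vi[0]]),
            "ph_min": float(np.nanmin(ph_values)),
            "ph_bulk": float(ph_values[vi[-1]]),
        }
    return PhProfile(depths_um=depths[keep], ph_values=ph_values, summary=summary)
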