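"""Coupon mass-loss to areal dissolution amounts and annual dissolution rates.

Aragonite coupons (12.7 mm diameter disks) are incubated in continuous-flow
bioreactors and harvested on a fixed schedule; the mass lost by each coupon,
normalized by its estimated surface area, gives an areal dissolution amount
in umol CaCO3 cm^-2. An ordinary least-squares regression of areal amount
against residence time, annualized by 8,760 h/yr, yields the per-condition
dissolution rate reported in umol CaCO3 cm^-2 yr^-1.

The coupon is modeled as a closed right cylinder: its volume follows from
mass and density, its thickness from volume and the known diameter, and the
surface area is the sum of the two faces and the lateral wall.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .constants import CONSTANTS, PhysicalConstants
from .errors import DegenerateDesignError, InsufficientDataError, InvalidInputError

CONDITIONS = ("thiosulfate", "heterotrophic", "abiotic")

__all__ = [
    "CONDITIONS",
    "CouponRecord",
    "ArealDissolution",
    "DissolutionRate",
    "estimate_coupon_surface_area",
    "coupon_areal_dissolution",
    "fit_dissolution_rate",
    "condition_rate_ratio",
    "cells_per_ml_from_od",
]


@dataclass(frozen=True)
class CouponRecord:
    """One coupon's masses, geometry, residence time and test condition."""

    coupon_id: str
    condition: str
    initial_mass_mg: float
    final_mass_mg: float
    hours_in_reactor: float
    diameter_mm: float = 12.7

    def __post_init__(self) -> None:
        if self.condition not in CONDITIONS:
            raise InvalidInputError(
                f"condition must be one of {CONDITIONS}, got {self.condition!r}"
            )
        if self.diameter_mm <= 0:
            raise InvalidInputError("diameter_mm must be > 0")
        if self.initial_mass_mg <= 0:
            raise InvalidInputError("initial_mass_mg must be > 0")
        if self.final_mass_mg < 0:
            raise InvalidInputError("final_mass_mg must be >= 0")
        if self.hours_in_reactor < 0:
            raise InvalidInputError("hours_in_reactor must be >= 0")

    @property
    def mass_loss_mg(self) -> float:
        return self.initial_mass_mg - self.final_mass_mg


@dataclass(frozen=True)
class ArealDissolution:
    """Areal dissolution amount for one coupon.

    ``flagged`` is True when the coupon gained mass (negative dissolution);
    such records are retained, not rejected.
    """

    coupon_id: str
    condition: str
    areal_amount_umol_cm2: float
    surface_area_cm2: float
    hours: float
    flagged: bool = False

    def __post_init__(self) -> None:
        if self.surface_area_cm2 <= 0:
            raise InvalidInputError("surface_area_cm2 must be > 0")
        if not math.isfinite(self.areal_amount_umol_cm2):
            raise InvalidInputError("areal_amount_umol_cm2 must be finite")


@dataclass(frozen=True)
class DissolutionRate:
    """Annualized dissolution rate for one experimental condition."""

    condition: str
    rate: float  # umol CaCO3 cm^-2 yr^-1
    rate_se: float  # same units; annualized slope standard error
    n_coupons: int
    slope_per_hour: float  # umol cm^-2 h^-1
    intercept: float  # umol cm^-2
    hours_per_year: float = field(default=CONSTANTS.hours_per_year, repr=False)

    def __post_init__(self) -> None:
        if self.rate_se < 0:
            raise InvalidInputError("rate_se must be >= 0")


def estimate_coupon_surface_area(
    mass_mg: float,
    diameter_mm: float = 12.7,
    density_g_cm3: float = CONSTANTS.aragonite_density,
) -> float:
    """Surface area (cm^2) of a coupon modeled as a closed right cylinder.

    Volume comes from mass/density, thickness from volume over the face
    area, and the returned area is 2*pi*r^2 + 2*pi*r*thickness.

    Parameters
    ----------
    mass_mg : coupon mass in milligrams.
    diameter_mm : coupon diameter in millimeters (12.7 mm machined disks).
    density_g_cm3 : mineral density (aragonite, 2.93 g/cm^3).
    """
    if mass_mg <= 0 or diameter_mm <= 0 or density_g_cm3 <= 0:
        raise InvalidInputError(
            "mass, diameter and density must all be > 0 "
            f"(got {mass_mg}, {diameter_mm}, {density_g_cm3})"
        )
    radius_cm = diameter_mm / 10.0 / 2.0
    volume_cm3 = mass_mg / 1000.0 / density_g_cm3
    face_area = math.pi * radius_cm**2
    thickness_cm = volume_cm3 / face_area
    if thickness_cm > diameter_mm / 10.0:
        warnings.warn(
            f"implied thickness {thickness_cm:.3f} cm exceeds diameter "
            f"{diameter_mm / 10.0:.3f} cm; geometry implausible for a coupon",
            stacklevel=2,
        )
    return 2.0 * face_area + 2.0 * math.pi * radius_cm * thickness_cm


def coupon_areal_dissolution(
    record: CouponRecord,
    constants: PhysicalConstants = CONSTANTS,
    mass_for_area: str = "mean",
) -> ArealDissolution:
    """Convert one coupon's mass loss to umol CaCO3 per cm^2.

    ``mass_for_area`` selects which mass estimates the surface area:
    ``"initial"``, ``"final"`` or ``"mean"`` (default; the symmetric choice
    when area is derived from masses measured before and after incubation).
    Coupons that gained mass yield a negative areal amount and are flagged.
    """
    if mass_for_area not in ("initial", "final", "mean"):
        raise InvalidInputError(
            f"mass_for_area must be initial|final|mean, got {mass_for_area!r}"
        )
    mass = {
        "initial": record.initial_mass_mg,
        "final": record.final_mass_mg,
        "mean": 0.5 * (record.initial_mass_mg + record.final_mass_mg),
    }[mass_for_area]
    area = estimate_coupon_surface_area(
        mass, record.diameter_mm, constants.aragonite_density
    )
    umol = record.mass_loss_mg / constants.mg_per_umol_caco3
    return ArealDissolution(
        coupon_id=record.coupon_id,
        condition=record.condition,
        areal_amount_umol_cm2=umol / area,
        surface_area_cm2=area,
        hours=record.hours_in_reactor,
        flagged=record.mass_loss_mg < 0,
    )


def fit_dissolution_rate(
    dissolutions: list[ArealDissolution],
    condition: str | None = None,
    force_origin: bool = False,
    constants: PhysicalConstants = CONSTANTS,
) -> DissolutionRate:
    """OLS fit of areal dissolution against residence time, annualized.

    The slope (umol cm^-2 h^-1) and its standard error are multiplied by
    8,760 h/yr to give the annual rate and its uncertainty. The intercept is
    free by default (it absorbs batch-phase attachment effects); pass
    ``force_origin=True`` to regress through the origin instead.
    """
    pts = dissolutions
    if condition is not None:
        pts = [d for d in pts if d.condition == condition]
    if len(pts) < 2:
        raise InsufficientDataError(
            f"need >= 2 coupons to fit a rate, got {len(pts)}"
        )
    t = np.array([d.hours for d in pts], dtype=float)
    y = np.array([d.areal_amount_umol_cm2 for d in pts], dtype=float)
    if np.ptp(t) == 0.0:
        raise DegenerateDesignError("all residence times identical; slope undefined")

    if force_origin:
        sxx = float(np.sum(t * t))
        slope = float(np.sum(t * y)) / sxx
        resid = y - slope * t
        dof = len(pts) - 1
        sigma2 = float(np.sum(resid**2)) / dof if dof > 0 else 0.0
        slope_se = math.sqrt(sigma2 / sxx)
        intercept = 0.0
    else:
        res = stats.linregress(t, y)
        slope, intercept, slope_se = res.slope, res.intercept, res.stderr
    hpy = constants.hours_per_year
    cond = condition if condition is not None else pts[0].condition
    return DissolutionRate(
        condition=cond,
        rate=slope * hpy,
        rate_se=slope_se * hpy,
        n_coupons=len(pts),
        slope_per_hour=slope,
        intercept=intercept,
    )


def condition_rate_ratio(
    numerator: DissolutionRate, denominator: DissolutionRate
) -> float:
    """Ratio of two condition rates (e.g. thiosulfate vs heterotrophic)."""
    if denominator.rate == 0:
        raise InvalidInputError(
            "denominator rate is zero; the rate ratio is undefined"
        )
    return numerator.rate / denominator.rate


def cells_per_ml_from_od(od590: float) -> float:
    """Cell density (cells/mL) from optical density at 590 nm.

    Uses the strain growth-curve calibration y = 3e9 * OD590 + 2e7.
    """
    if od590 < 0:
        raise InvalidInputError("OD590 must be >= 0")
    return 3e9 * od590 + 2e7
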