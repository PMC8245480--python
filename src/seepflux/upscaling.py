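"""Per-seep and global carbonate-dissolution fluxes with uncertainty.

The experimentally derived dissolution rate (umol CaCO3 cm^-2 yr^-1,
equivalently x 1e-2 mol m^-2 yr^-1) is applied to each seep site's
rock-covered area, discounted by the fraction of rock surface colonized by
bacterial mats (the metabolically active surface). Rate uncertainty is
propagated multiplicatively (flux_se = flux x rate_se/rate). A global
estimate scales the mean per-site flux to an assumed number of seeps
worldwide (default 10,000), converts moles of CaCO3-carbon to kg C, and
expresses the flux as an annual "geological lability": the percentage of
the global methane-derived carbonate precipitation flux (1.7 Tmol/yr,
range 0.6-3.6) that is re-dissolved each year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constants import CONSTANTS, PhysicalConstants
from .errors import InsufficientDataError, InvalidInputError

#: Default mat coverage of exposed carbonates (92.77%, ground-truth imagery).
DEFAULT_MAT_FRACTION = 0.9277

#: Default number of cold seeps worldwide used in the extrapolation.
DEFAULT_N_SEEPS = 10_000

__all__ = [
    "DEFAULT_MAT_FRACTION",
    "DEFAULT_N_SEEPS",
    "SeepSite",
    "FluxEstimate",
    "GlobalEstimate",
    "PrecipitationFlux",
    "convert_rate_units",
    "site_flux",
    "propagate_rate_se",
    "global_extrapolation",
    "carbon_mass",
    "geological_lability",
    "summarize_global",
]


@dataclass(frozen=True)
class SeepSite:
    """One cold-seep site's mapped areas (m^2)."""

    name: str
    seep_area_m2: float
    rock_area_m2: float
    reference: str = ""

    def __post_init__(self) -> None:
        if not 0 < self.rock_area_m2 <= self.seep_area_m2:
            raise InvalidInputError(
                f"{self.name}: need 0 < rock_area ({self.rock_area_m2}) "
                f"<= seep_area ({self.seep_area_m2})"
            )

    @property
    def rock_fraction_pct(self) -> float:
        return 100.0 * self.rock_area_m2 / self.seep_area_m2


@dataclass(frozen=True)
class FluxEstimate:
    """Annual carbonate dissolution at one site, mol CaCO3 (= mol C) yr^-1."""

    site: str
    flux: float
    flux_se: float = 0.0

    def __post_init__(self) -> None:
        if self.flux < 0 or self.flux_se < 0:
            raise InvalidInputError("flux and flux_se must be >= 0")


@dataclass(frozen=True)
class PrecipitationFlux:
    """Global methane-derived carbonate precipitation flux (mol C yr^-1)."""

    central: float = 1.7e12
    low: float = 0.6e12
    high: float = 3.6e12

    def __post_init__(self) -> None:
        if not self.low <= self.central <= self.high:
            raise InvalidInputError("require low <= central <= high")


@dataclass
class GlobalEstimate:
    """Global dissolution flux, carbon mass and geological lability."""

    n_seeps: int
    global_flux: float  # mol C yr^-1
    global_flux_se: float  # mol C yr^-1
    global_mass_kg: float | None = None  # kg C yr^-1
    lability_pct: float | None = None
    lability_range: tuple[float, float] | None = None


def convert_rate_units(rate_umol_cm2_yr: float) -> float:
    """umol CaCO3 cm^-2 yr^-1 -> mol CaCO3 m^-2 yr^-1 (factor 1e-2)."""
    return rate_umol_cm2_yr * 1e-2


def site_flux(
    rate_mol_m2_yr: float,
    site: SeepSite,
    mat_fraction: float = DEFAULT_MAT_FRACTION,
) -> FluxEstimate:
    """Annual dissolution flux at a site: rate x rock area x mat fraction."""
    if not 0 <= mat_fraction <= 1:
        raise InvalidInputError(f"mat_fraction must be in [0, 1], got {mat_fraction}")
    return FluxEstimate(
        site=site.name, flux=rate_mol_m2_yr * site.rock_area_m2 * mat_fraction
    )


def propagate_rate_se(
    flux: FluxEstimate, rate: float, rate_se: float
) -> FluxEstimate:
    """Attach the rate's relative standard error to a site flux.

    flux_se = flux x (rate_se / rate): the flux is linear in the rate, so
    its relative uncertainty equals the rate's.
    """
    if rate <= 0:
        raise InvalidInputError("rate must be > 0 to propagate relative error")
    if rate_se < 0:
        raise InvalidInputError("rate_se must be >= 0")
    return FluxEstimate(
        site=flux.site, flux=flux.flux, flux_se=flux.flux * rate_se / rate
    )


def global_extrapolation(
    site_fluxes: list[FluxEstimate],
    n_seeps: int = DEFAULT_N_SEEPS,
    se_rule: str = "mean",
) -> GlobalEstimate:
    """Scale the mean per-site flux to ``n_seeps`` seeps worldwide.

    ``se_rule="mean"`` (default) scales the mean of the per-site standard
    errors by n_seeps; ``"quadrature"`` combines them as the standard error
    of the mean in quadrature before scaling.
    """
    if not site_fluxes:
        raise InsufficientDataError("need at least one site flux")
    if n_seeps < 1:
        raise InvalidInputError("n_seeps must be >= 1")
    fluxes = np.array([f.flux for f in site_fluxes], dtype=float)
    ses = np.array([f.flux_se for f in site_fluxes], dtype=float)
    if se_rule == "mean":
        se = float(ses.mean()) * n_seeps
    elif se_rule == "quadrature":
        se = float(np.sqrt(np.sum(ses**2))) / len(ses) * n_seeps
    else:
        raise InvalidInputError(f"unknown se_rule {se_rule!r}")
    return GlobalEstimate(
        n_seeps=n_seeps,
        global_flux=float(fluxes.mean()) * n_seeps,
        global_flux_se=se,
    )


def carbon_mass(
    global_flux_mol_yr: float, constants: PhysicalConstants = CONSTANTS
) -> float:
    """mol C yr^-1 -> kg C yr^-1 (x 12.011 g/mol / 1000)."""
    if global_flux_mol_yr < 0:
        raise InvalidInputError("global flux must be >= 0")
    return global_flux_mol_yr * constants.carbon_molar_mass / 1000.0


def geological_lability(
    global_est: GlobalEstimate,
    precip: PrecipitationFlux = PrecipitationFlux(),
) -> tuple[float, tuple[float, float]]:
    """Annual geological lability (%) and its extreme-ratio range.

    Lability = 100 x global flux / central precipitation flux. The range
    pairs (flux - se) with the high precipitation bound and (flux + se)
    with the low bound, bracketing the ratio at its extremes.
    """
    if precip.central <= 0 or precip.low <= 0:
        raise InvalidInputError("precipitation fluxes must be > 0")
    g, se = global_est.global_flux, global_est.global_flux_se
    lability = 100.0 * g / precip.central
    rng = (100.0 * (g - se) / precip.high, 100.0 * (g + se) / precip.low)
    return lability, rng


def summarize_global(
    site_fluxes: list[FluxEstimate],
    n_seeps: int = DEFAULT_N_SEEPS,
    precip: PrecipitationFlux = PrecipitationFlux(),
    se_rule: str = "mean",
    constants: PhysicalConstants = CONSTANTS,
) -> GlobalEstimate:
    """Convenience: extrapolate, convert to kg C, and attach lability."""
    est = global_extrapolation(site_fluxes, n_seeps, se_rule)
    est.global_mass_kg = carbon_mass(est.global_flux, constants)
    est.lability_pct, est.lability_range = geological_lability(est, precip)
    return est
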