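"""Physical constants used across the dissolution pipeline.

Aragonite density is the mineralogical standard 2.93 g/cm^3; molar masses
are CODATA-consistent standard atomic-weight values. A year is taken as
exactly 8,760 hours (365 x 24) for annualizing hourly dissolution slopes.
"""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """Read-only bundle of the constants entering unit conversions."""

    aragonite_density: float = 2.93  # g cm^-3
    caco3_molar_mass: float = 100.0869  # g mol^-1
    carbon_molar_mass: float = 12.011  # g mol^-1
    hours_per_year: float = 8760.0

    @property
    def mg_per_umol_caco3(self) -> float:
        """Milligrams of CaCO3 per micromole (= molar mass / 1000)."""
        return self.caco3_molar_mass / 1000.0


#: Module-level default constants instance.
CONSTANTS = PhysicalConstants()
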