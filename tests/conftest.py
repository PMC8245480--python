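import math

import pytest

from seepflux.io import load_table1


def sig3(x: float) -> float:
    """Round to 3 significant figures (the printed precision of the tables)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + 2)


@pytest.fixture(scope="session")
def table1():
    """Packaged six-site literature table (areas and published fluxes)."""
    return load_table1()


@pytest.fixture(scope="session")
def printed_fluxes(table1):
    """Published per-site fluxes and their +/- values, keyed by site name."""
    return {
        r["name"]: (float(r["printed_flux_mol_yr"]), float(r["printed_flux_se_mol_yr"]))
        for _, r in table1.iterrows()
    }
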