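"""Greenhouse-gas accounting: CO2-equivalents, NBE and country aggregation.

Canonical units: carbon stocks and harvested carbon in kgC ha^-1, carbon
fluxes (NEP/NEE) in gC m^-2 yr^-1, non-CO2 gas fluxes in g m^-2 yr^-1.  The
single conversion layer lives here: gC m^-2 -> kgC ha^-1 is a factor of 10,
carbon -> CO2 is 44/12, and CH4 / N2O are weighted by their global warming
potentials.  Negative NBE is a net GHG sink, positive a source.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GhgFactors", "FACTORS", "carbon_to_co2", "gwp_co2eq",
           "compute_nbe", "aggregate_country"]


@dataclass(frozen=True)
class GhgFactors:
    carbon_to_co2: float = 44.0 / 12.0
    gwp_n2o: float = 298.0
    gwp_ch4: float = 25.0
    g_m2_to_kg_ha: float = 10.0


FACTORS = GhgFactors()


def carbon_to_co2(mass_c):
    """Carbon mass to CO2 mass, sign-preserving (x 44/12)."""
    return np.multiply(mass_c, FACTORS.carbon_to_co2)


def gwp_co2eq(n2o_mass, ch4_mass):
    """CO2-equivalent of N2O and CH4 masses via global warming potentials."""
    n2o = np.asarray(n2o_mass, dtype=float)
    ch4 = np.asarray(ch4_mass, dtype=float)
    if (n2o < 0).any() or (ch4 < 0).any():
        raise ValueError("gas masses must be non-negative")
    out = FACTORS.gwp_n2o * n2o + FACTORS.gwp_ch4 * ch4
    return float(out) if out.ndim == 0 else out


def compute_nbe(nep, harvested_c, n2o=0.0, ch4=0.0, soil_class=None):
    """Net biome exchange, kgCO2eq ha^-1 yr^-1.

    NBE = NEE + harvested biomass + N2O + CH4 in CO2-equivalents, with
    NEE = -NEP.  Units in: NEP gC m^-2 yr^-1, harvested carbon kgC ha^-1
    yr^-1, gases g m^-2 yr^-1.  Gas fluxes are only defined for drained
    organic soil; passing nonzero gas fluxes for mineral-soil pixels is a
    contract error when ``soil_class`` is given (0 mineral, 1 organic).
    """
    nep = np.asarray(nep, dtype=float)
    harvested = np.asarray(harvested_c, dtype=float)
    n2o = np.asarray(n2o, dtype=float)
    ch4 = np.asarray(ch4, dtype=float)
    if soil_class is not None:
        mineral = np.asarray(soil_class) == 0
        if (np.broadcast_to(n2o, mineral.shape)[mineral] != 0).any() \
                or (np.broadcast_to(ch4, mineral.shape)[mineral] != 0).any():
            raise ValueError("gas fluxes supplied for mineral-soil pixels")
    f = FACTORS
    nbe = ((-nep * f.g_m2_to_kg_ha + harvested) * f.carbon_to_co2
           + (f.gwp_n2o * n2o + f.gwp_ch4 * ch4) * f.g_m2_to_kg_ha)
    return float(nbe) if nbe.ndim == 0 else nbe


def aggregate_country(region_values, region_areas, totals: bool = False):
    """Area-weighted country mean of per-area regional values.

    With ``totals=True`` returns (weighted mean, sum of value x area).
    """
    v = np.asarray(region_values, dtype=float)
    a = np.asarray(region_areas, dtype=float)
    if v.shape[-1] != a.shape[-1] or v.ndim < 1:
        raise ValueError("one value per region is required")
    if (a <= 0).any():
        raise ValueError("region areas must be > 0")
    total = (v * a).sum(axis=-1)
    mean = total / a.sum()
    if totals:
        return mean, total
    return mean
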