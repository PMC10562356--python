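"""Soil carbon and drained-organic-soil GHG emissions.

Mineral soils carry a three-pool (fast / slow / humus) first-order decay
model with transfers toward the slower pools; mass balance is exact on every
step.  Initial pools come from a spin-up that repeats a 7-year block of
historical forcing until the total soil carbon reaches a periodic steady
state.  Forests on drained organic (peat) soils instead use static,
per-simulation sampled emission coefficients for CO2, CH4 and N2O by site
fertility, and a constant sampled peat carbon stock.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet, SoilParams

__all__ = [
    "N_POOLS",
    "SoilPools",
    "EmissionCoefficientTable",
    "PeatCarbonStock",
    "mineral_soil_step",
    "spin_up_soil",
    "organic_soil_emissions",
    "sample_emission_coefficients",
    "sample_peat_stock",
    "PEAT_STOCK_MEAN",
    "PEAT_STOCK_SD",
]

N_POOLS = 3

# Emission-coefficient means and standard deviations by emission type:
# 1: CH4 all sites (gCH4 m^-2 yr^-1)
# 2: N2O site types 1-3, 3: N2O site types >3 (gN2O m^-2 yr^-1)
# 4: CO2 site types 1-3, 5: CO2 site types >3 (gCO2 m^-2 yr^-1)
EMISSION_COEFF_MEANS = {1: 0.34, 2: 0.23, 3: 0.077, 4: 240.0, 5: -70.0}
EMISSION_COEFF_SDS = {1: 0.12, 2: 0.04, 3: 0.004, 4: 70.0, 5: 30.0}

PEAT_STOCK_MEAN = 543_400.0  # kgC ha^-1
PEAT_STOCK_SD = 18_500.0


@dataclass
class SoilPools:
    """Per-pixel mineral soil pools, kgC ha^-1, fast / slow / humus."""

    pools: np.ndarray  # (n, 3)
    converged: bool = True

    @property
    def total(self) -> np.ndarray:
        return self.pools.sum(axis=1)

    def copy(self) -> "SoilPools":
        return SoilPools(pools=self.pools.copy(), converged=self.converged)

    def validate(self) -> None:
        if self.pools.ndim != 2 or self.pools.shape[1] != N_POOLS:
            raise ValueError(f"pools must be (n, {N_POOLS})")
        if (self.pools < 0).any():
            raise ValueError("soil pools must be non-negative")


@dataclass(frozen=True)
class EmissionCoefficientTable:
    """Static drained-organic-soil emission coefficients, one value per type."""

    ch4: float = EMISSION_COEFF_MEANS[1]        # all sites
    n2o_rich: float = EMISSION_COEFF_MEANS[2]   # site types 1-3
    n2o_poor: float = EMISSION_COEFF_MEANS[3]   # site types > 3
    co2_rich: float = EMISSION_COEFF_MEANS[4]
    co2_poor: float = EMISSION_COEFF_MEANS[5]

    def as_dict(self) -> dict[str, float]:
        return {"pECorg_ch4": self.ch4, "pECorg_n2o_rich": self.n2o_rich,
                "pECorg_n2o_poor": self.n2o_poor, "pECorg_co2_rich": self.co2_rich,
                "pECorg_co2_poor": self.co2_poor}


@dataclass(frozen=True)
class PeatCarbonStock:
    """Constant-per-simulation organic soil carbon stock, kgC ha^-1."""

    value: float = PEAT_STOCK_MEAN

    def __post_init__(self):
        if self.value <= 0:
            raise ValueError("peat carbon stock must be > 0")


def _decay_rates(soil: SoilParams, mean_annual_temp: float | None) -> np.ndarray:
    k = np.array([soil.k_fast, soil.k_slow, soil.k_humus])
    if mean_annual_temp is not None:
        k = k * soil.q10 ** ((mean_annual_temp - soil.temp_ref) / 10.0)
    return np.minimum(k, 0.999)  # annual discrete step stays positive


def mineral_soil_step(pools: SoilPools, litter_in: np.ndarray,
                      weather_summary: float | None = None,
                      params: ParameterSet | SoilParams | None = None,
                      ) -> tuple[SoilPools, np.ndarray]:
    """One annual step of the three-pool decay model.

    Litter enters the fast pool; each pool loses rate x stock, of which a
    transfer fraction moves to the next slower pool and the remainder is
    respired.  Mass balance is exact: delta(total) = litter - respiration.
    """
    litter = np.asarray(litter_in, dtype=float)
    if (litter < 0).any():
        raise ValueError("litter input must be non-negative")
    soil = params.soil if isinstance(params, ParameterSet) else (params or SoilParams())
    k = _decay_rates(soil, weather_summary)
    p = pools.pools
    loss = p * k[None, :]
    new = p - loss
    new[:, 0] += litter
    new[:, 1] += soil.t_fast_slow * loss[:, 0]
    new[:, 2] += soil.t_slow_humus * loss[:, 1]
    respiration = ((1.0 - soil.t_fast_slow) * loss[:, 0]
                   + (1.0 - soil.t_slow_humus) * loss[:, 1]
                   + loss[:, 2])
    return SoilPools(pools=new, converged=pools.converged), respiration


DEFAULT_SPINUP_TOLERANCE = 1e-4
DEFAULT_MAX_SPINUP_CYCLES = 300


def spin_up_soil(litter_block: np.ndarray,
                 temperature_block: np.ndarray | None = None,
                 params: ParameterSet | SoilParams | None = None,
                 tolerance: float = DEFAULT_SPINUP_TOLERANCE,
                 max_cycles: int = DEFAULT_MAX_SPINUP_CYCLES,
                 initial: SoilPools | None = None) -> SoilPools:
    """Iterate repeated blocks of historical forcing to a periodic steady state.

    ``litter_block`` is (n_years_block, n_pixels) annual litter inputs from
    the stand model run over the historical years (the stand is restarted
    from its sampled initial state each cycle, so the forcing is periodic).
    Convergence: relative change of summed total soil carbon between
    successive cycles < ``tolerance``.  Non-convergence sets
    ``converged=False`` on the result rather than raising.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    litter_block = np.atleast_2d(np.asarray(litter_block, dtype=float))
    n_years, n_pix = litter_block.shape
    temps = (list(temperature_block) if temperature_block is not None
             else [None] * n_years)
    if len(temps) != n_years:
        raise ValueError("temperature block must match the litter block length")
    pools = initial.copy() if initial is not None else SoilPools(
        pools=np.zeros((n_pix, N_POOLS)))
    prev_total = float(pools.total.sum())
    for _ in range(max_cycles):
        for y in range(n_years):
            pools, _resp = mineral_soil_step(pools, litter_block[y], temps[y], params)
        total = float(pools.total.sum())
        denom = max(abs(total), 1e-12)
        if abs(total - prev_total) / denom < tolerance:
            pools.converged = True
            return pools
        prev_total = total
    pools.converged = False
    return pools


def organic_soil_emissions(site_type: np.ndarray | int,
                           coefficients: EmissionCoefficientTable | None = None,
                           ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(CO2, CH4, N2O) annual fluxes, g m^-2 yr^-1, for drained organic soil.

    Site types 1-3 take the nutrient-rich coefficients, types >3 the
    nutrient-poor ones; CH4 applies to all.  Values are constant across
    years and pixels within a simulation by construction.
    """
    table = coefficients or EmissionCoefficientTable()
    site = np.asarray(site_type)
    if ((site < 1) | (site > 5)).any():
        raise ValueError("site_type must be in {1..5}")
    rich = site <= 3
    co2 = np.where(rich, table.co2_rich, table.co2_poor)
    ch4 = np.broadcast_to(np.float64(table.ch4), site.shape).copy()
    n2o = np.where(rich, table.n2o_rich, table.n2o_poor)
    return co2, ch4, n2o


def sample_emission_coefficients(rng: np.random.Generator,
                                 means: dict[int, float] | None = None,
                                 sds: dict[int, float] | None = None,
                                 ) -> EmissionCoefficientTable:
    """One per-simulation draw, EF_et ~ Normal(mu_et, sigma_et^2) independently.

    Strictly positive gases (CH4, N2O) are truncated at zero; the CO2
    coefficients may be negative (net uptake is meaningful).
    """
    mu = means or EMISSION_COEFF_MEANS
    sd = sds or EMISSION_COEFF_SDS
    draw = {et: rng.normal(mu[et], sd[et]) for et in sorted(mu)}
    return EmissionCoefficientTable(
        ch4=max(0.0, draw[1]), n2o_rich=max(0.0, draw[2]),
        n2o_poor=max(0.0, draw[3]), co2_rich=draw[4], co2_poor=draw[5])


def sample_peat_stock(rng: np.random.Generator,
                      mean: float = PEAT_STOCK_MEAN,
                      sd: float = PEAT_STOCK_SD) -> PeatCarbonStock:
    """One per-simulation draw of the constant organic soil carbon stock."""
    value = rng.normal(mean, sd)
    return PeatCarbonStock(value=float(max(value, 1.0)))
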