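"""Monte Carlo orchestration of the coupled stand/soil/management model.

Every uncertainty element is sampled once per simulation and held fixed
across regions and years (harvest-target deviates vary by year but not by
region): the GCM label, indices into the three parameter pools, the crown
height factor, the organic-soil emission-coefficient table, the peat carbon
stock and the harvest deviates.  Spatially distributed elements (pixel
sample, initial ages, site types) are drawn independently per region.

Seeding is hierarchical: master seed -> per-simulation stream -> per-region
substream, so results are bitwise reproducible and independent of execution
order.  Harvest-scenario and RCP labels never enter the seed path, which
makes 2015-2021 trajectories identical across harvest scenarios for matched
seeds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import xarray as xr

from . import accounting
from .landscape import (HarvestStatistics, Landscape, ParameterPools,
                        generate_harvest_statistics, generate_parameter_pools,
                        sample_pixels)
from .management import (SCENARIOS, HarvestRules, HarvestScenario,
                         allocate_regional_harvest)
from .params import ParameterSet
from .soil import (EmissionCoefficientTable, PeatCarbonStock,
                   mineral_soil_step, organic_soil_emissions,
                   sample_emission_coefficients, sample_peat_stock,
                   spin_up_soil)
from .stand import StandState, annual_gpp, grow_stand, initialize_stand
from .weather import GCMS, RCPS, WeatherSeries, generate_weather

logger = logging.getLogger("forcarb_uq")

__all__ = [
    "SimulationConfig", "UncertaintyDraw", "SiteTypeConfusionModel",
    "EnsembleResult", "sample_initial_age", "sample_site_type",
    "resample_site_types", "draw_simulation_settings", "run_monte_carlo",
    "run_scenario_grid",
]

OUTPUT_VARIABLES = ["nep", "nee", "ch4", "n2o", "tree_c", "gv_c", "soil_c",
                    "total_c", "harvested_c", "nbe", "round_wood_m3",
                    "energy_wood_m3", "target_m3", "shortfall_m3"]


@dataclass(frozen=True)
class SimulationConfig:
    """Monte Carlo study settings (test-scale defaults)."""

    n_sim: int = 50
    n_pixels: int = 500          # pixel sample of the largest region
    min_pixels: int = 25         # floor for the smallest region
    start_year: int = 2015
    end_year: int = 2050
    historical_end_year: int = 2021
    harvest_cv: float = 0.02     # sd of harvest-target deviates, share of mean
    crown_height_sd: float = 0.1
    age_cv: float = 0.1          # sd of initial age as share of the mean
    spinup_tolerance: float = 1e-4
    spinup_max_cycles: int = 300
    reference_area_ha: float = 20e6  # national forest area the statistics refer to
    harvest_deviates_per_year: bool = True
    stochastic_mortality: bool = False

    def __post_init__(self):
        if self.n_sim < 1:
            raise ValueError("n_sim must be >= 1")
        if self.end_year < self.start_year:
            raise ValueError("years must be a contiguous increasing span")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def sample_initial_age(mean_age, rng: np.random.Generator,
                       cv: float = 0.1) -> np.ndarray:
    """Initial age draw ~ Normal(mu, (cv x mu)^2), truncated at 0.

    The standard deviation scales with the mean: young stands are known more
    precisely than old ones.  mu = 0 always returns 0.
    """
    mu = np.asarray(mean_age, dtype=float)
    if (mu < 0).any():
        raise ValueError("mean age must be >= 0")
    draw = rng.normal(mu, cv * mu)
    return np.maximum(0.0, draw)


@dataclass(frozen=True)
class SiteTypeConfusionModel:
    """Site-type resampling model: a row-stochastic confusion matrix over the
    recorded class, optionally tilted by the sampled stand structure (taller
    stands than expected for their age shift probability toward fertile
    classes)."""

    matrix: tuple = None
    structure_tilt: float = 0.3

    def __post_init__(self):
        m = self._matrix()
        if m.shape != (5, 5) or (m < 0).any() \
                or np.abs(m.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("confusion matrix rows must be probability vectors over {1..5}")

    def _matrix(self) -> np.ndarray:
        if self.matrix is None:
            return _default_confusion_matrix()
        return np.asarray(self.matrix, dtype=float)

    @classmethod
    def identity(cls) -> "SiteTypeConfusionModel":
        return cls(matrix=tuple(map(tuple, np.eye(5))), structure_tilt=0.0)

    def probabilities(self, recorded: np.ndarray,
                      height: np.ndarray | None = None,
                      age: np.ndarray | None = None) -> np.ndarray:
        """Per-pixel probability rows conditioned on recorded type and structure."""
        rows = self._matrix()[np.asarray(recorded, dtype=int) - 1]
        if self.structure_tilt != 0.0 and height is not None and age is not None:
            h_exp = 22.0 * (1.0 - np.exp(-0.03 * np.maximum(age, 0.0)))
            resid = (height - h_exp) / np.maximum(h_exp, 1.0)
            classes = np.arange(1, 6)
            tilt = np.exp(-self.structure_tilt * resid[:, None] * (classes - 3.0))
            rows = rows * tilt
            rows = rows / rows.sum(axis=1, keepdims=True)
        return rows


def _default_confusion_matrix() -> np.ndarray:
    m = np.zeros((5, 5))
    for i in range(5):
        m[i, i] = 0.7
        spread = [j for j in (i - 1, i + 1) if 0 <= j < 5]
        for j in spread:
            m[i, j] = 0.3 / len(spread)
    return m


def sample_site_type(recorded, rng: np.random.Generator,
                     confusion_model: SiteTypeConfusionModel | None = None,
                     height=None, age=None) -> np.ndarray:
    """Draw new site types from the confusion model, one per pixel."""
    model = confusion_model or SiteTypeConfusionModel()
    recorded = np.atleast_1d(np.asarray(recorded, dtype=int))
    rows = model.probabilities(recorded,
                               None if height is None else np.atleast_1d(height),
                               None if age is None else np.atleast_1d(age))
    u = rng.random(recorded.size)
    return 1 + (rows.cumsum(axis=1) < u[:, None]).sum(axis=1).astype(int)


def resample_site_types(state: StandState, model: SiteTypeConfusionModel,
                        rng: np.random.Generator) -> None:
    """Resample and lock the state's site types (once per simulation).

    Re-drawing mid-simulation is a contract violation: site types are held
    constant over the whole simulation period.
    """
    if state.site_types_locked:
        raise RuntimeError("site types are locked for this simulation; "
                           "they are resampled only at simulation start")
    state.site_type = sample_site_type(state.site_type, rng, model,
                                       height=state.height, age=state.age)
    state.site_types_locked = True


@dataclass(frozen=True)
class UncertaintyDraw:
    """The per-simulation fixed bundle of sampled uncertainty elements."""

    simulation_id: int
    gcm: str
    pprel_id: int
    pcrob_id: int
    pyas_id: int
    crown_height_factor: float
    emission_table: EmissionCoefficientTable
    peat_stock: PeatCarbonStock
    round_wood_deviates: np.ndarray   # multiplicative, one per simulated year
    energy_wood_deviates: np.ndarray

    def feature_record(self, pools: ParameterPools,
                       years: np.ndarray) -> dict[str, float]:
        rec: dict[str, float] = {"GCM": self.gcm,
                                 "crown_factor": self.crown_height_factor,
                                 "peat_stock": self.peat_stock.value}
        for group, prefix, idx in [("photosynthesis", "pPrel", self.pprel_id),
                                   ("growth", "pCrob", self.pcrob_id),
                                   ("soil", "pYas", self.pyas_id)]:
            row = getattr(pools, group).iloc[idx]
            rec.update({f"{prefix}_{k}": float(v) for k, v in row.items()})
        rec.update(self.emission_table.as_dict())
        for y, rw, ew in zip(years, self.round_wood_deviates,
                             self.energy_wood_deviates):
            rec[f"pHarv_rw_{y}"] = float(rw)
            rec[f"pHarv_ew_{y}"] = float(ew)
        return rec


def draw_simulation_settings(pools: ParameterPools, scenario: HarvestScenario,
                             config: SimulationConfig, rng: np.random.Generator,
                             simulation_id: int = 0) -> UncertaintyDraw:
    """Sample all per-simulation uncertainty elements; fixed for simulation i.

    The GCM is uniform over the five models and shared by all regions;
    parameter vectors are resampled with replacement from each pool; the
    crown-height factor is Normal(1, 0.1^2); harvest-target deviates are
    drawn per year (shared across regions).
    """
    for group in ("photosynthesis", "growth", "soil"):
        if getattr(pools, group).empty:
            raise ValueError(f"parameter pool {group!r} is empty")
    gcm = GCMS[rng.integers(len(GCMS))]
    pprel = int(rng.integers(len(pools.photosynthesis)))
    pcrob = int(rng.integers(len(pools.growth)))
    pyas = int(rng.integers(len(pools.soil)))
    crown = float(max(0.01, rng.normal(1.0, config.crown_height_sd)))
    table = sample_emission_coefficients(rng)
    peat = sample_peat_stock(rng)
    n_years = config.years.size
    if config.harvest_deviates_per_year:
        rw = np.maximum(0.0, rng.normal(1.0, config.harvest_cv, size=n_years))
        ew = np.maximum(0.0, rng.normal(1.0, config.harvest_cv, size=n_years))
    else:
        rw = np.full(n_years, max(0.0, rng.normal(1.0, config.harvest_cv)))
        ew = np.full(n_years, max(0.0, rng.normal(1.0, config.harvest_cv)))
    return UncertaintyDraw(simulation_id=simulation_id, gcm=gcm,
                           pprel_id=pprel, pcrob_id=pcrob, pyas_id=pyas,
                           crown_height_factor=crown, emission_table=table,
                           peat_stock=peat, round_wood_deviates=rw,
                           energy_wood_deviates=ew)


@dataclass
class EnsembleResult:
    """Region x year x simulation output arrays plus per-simulation features."""

    data: xr.Dataset
    features: pd.DataFrame
    region_areas_km2: np.ndarray
    rcp: str
    harvest: str
    failed_simulations: list = field(default_factory=list)

    def country_mean(self, variable: str) -> xr.DataArray:
        """Area-weighted country mean, dims (year, sim)."""
        w = xr.DataArray(self.region_areas_km2, dims=["region"],
                         coords={"region": self.data.region})
        return (self.data[variable] * w).sum("region") / w.sum()


def _pixels_per_region(landscape: Landscape, config: SimulationConfig) -> np.ndarray:
    """Pixel sample sizes proportional to region area (the largest region gets
    ``config.n_pixels``), emulating that small regions carry fewer segments
    and hence noisier regional means."""
    areas = np.array([r.total_area_km2 for r in landscape.regions])
    n = np.round(config.n_pixels * areas / areas.max()).astype(int)
    return np.maximum(config.min_pixels, n)


def _weather_for(master_seed: int, region_idx: int, years, gcm: str,
                 rcp: str, cache: dict) -> WeatherSeries:
    key = (region_idx, gcm, rcp)
    if key not in cache:
        seed = int(np.random.SeedSequence([master_seed, 91, region_idx])
                   .generate_state(1)[0]) % (2 ** 31)
        cache[key] = generate_weather(years, gcm, rcp, seed=seed)
    return cache[key]


def _landscape_scale(landscape: Landscape, config: SimulationConfig) -> float:
    """Mm3 country statistics -> m3 on the synthetic landscape."""
    return 1e6 * landscape.total_area_ha / config.reference_area_ha


def _simulate_region(region, region_idx: int, draw: UncertaintyDraw,
                     params: ParameterSet, weather: WeatherSeries,
                     stats: HarvestStatistics, scenario: HarvestScenario,
                     config: SimulationConfig, rules: HarvestRules,
                     confusion: SiteTypeConfusionModel,
                     rng: np.random.Generator, n_pix: int,
                     region_targets_m3: np.ndarray,
                     ) -> tuple[dict[str, np.ndarray], float, float]:
    """Simulate one region for one draw; returns per-year outputs and
    (vol0, age0) initial means."""
    years = config.years
    idx = sample_pixels(region, n_pix, rng)
    seg = region.segments.iloc[idx].copy()
    seg["mean_age"] = sample_initial_age(seg["mean_age"].to_numpy(), rng,
                                         cv=config.age_cv)
    state = initialize_stand(seg, draw.crown_height_factor, params)
    resample_site_types(state, confusion, rng)
    rep_area_ha = region.total_area_km2 * 100.0 / n_pix

    organic = state.soil_class == 1
    mineral = ~organic
    co2_ef, ch4_ef, n2o_ef = organic_soil_emissions(state.site_type,
                                                    draw.emission_table)
    # per-pixel gas fluxes, zero on mineral soil
    ch4_px = np.where(organic, ch4_ef, 0.0)
    n2o_px = np.where(organic, n2o_ef, 0.0)
    co2_org_c = np.where(organic, co2_ef * 10.0 * (12.0 / 44.0), 0.0)  # kgC ha^-1

    # --- soil spin-up: 7-year historical block, randomly ordered, repeated
    hist_years = [y for y in years if y <= config.historical_end_year]
    order = rng.permutation(len(hist_years))
    spin_state = state.copy()
    litter_block = np.zeros((len(hist_years), n_pix))
    temp_block = np.zeros(len(hist_years))
    mat = weather.mean_annual_temperature()
    base_total = stats.round_wood.mean() + stats.energy_wood.mean()
    for step, oi in enumerate(order):
        y = hist_years[oi]
        yi = weather.year_index(y)
        wy = {"radiation": weather.radiation[yi], "temperature": weather.temperature[yi],
              "vpd": weather.vpd[yi], "precipitation": weather.precipitation[yi],
              "co2": weather.co2[yi]}
        gpp = annual_gpp(spin_state, wy, params)
        target = region_targets_m3[np.where(years == y)[0][0]]
        outcome = allocate_regional_harvest(spin_state, target, rules, rng,
                                            rep_area_ha, params.growth)
        spin_state, flux = grow_stand(spin_state, gpp, params, rng,
                                      harvest=outcome.application,
                                      stochastic_mortality=config.stochastic_mortality)
        litter_block[step] = flux.litter_to_soil
        temp_block[step] = mat[yi]
    del base_total
    pools0 = spin_up_soil(litter_block, temp_block, params,
                          tolerance=config.spinup_tolerance,
                          max_cycles=config.spinup_max_cycles)
    if not pools0.converged:
        logger.warning("soil spin-up did not converge (region %s, sim %d)",
                       region.region_id, draw.simulation_id)

    vol0 = float(state.volume.mean())
    age0 = float(state.age.mean())

    # --- main run
    soil_pools = pools0
    out = {v: np.zeros(years.size) for v in OUTPUT_VARIABLES}
    for t, y in enumerate(years):
        yi = weather.year_index(y)
        wy = {"radiation": weather.radiation[yi], "temperature": weather.temperature[yi],
              "vpd": weather.vpd[yi], "precipitation": weather.precipitation[yi],
              "co2": weather.co2[yi]}
        gpp = annual_gpp(state, wy, params)
        target = region_targets_m3[t]
        outcome = allocate_regional_harvest(state, target, rules, rng,
                                            rep_area_ha, params.growth)
        state, flux = grow_stand(state, gpp, params, rng,
                                 harvest=outcome.application,
                                 stochastic_mortality=config.stochastic_mortality)
        litter = flux.litter_to_soil
        soil_pools, rh_min = mineral_soil_step(
            soil_pools, np.where(mineral, litter, 0.0), mat[yi], params)
        # organic soils: litter decomposes without accumulation (stock held
        # constant); the sampled CO2 coefficient adds the net peat balance
        rh = np.where(mineral, rh_min, litter + co2_org_c)

        nep_px = 0.1 * (flux.gpp - flux.autotrophic_respiration - rh)  # gC m^-2
        soil_c_px = np.where(mineral, soil_pools.total, draw.peat_stock.value)

        nep = float(nep_px.mean())
        ch4 = float(ch4_px.mean())
        n2o = float(n2o_px.mean())
        harvested = float(flux.harvested_c.mean())
        out["nep"][t] = nep
        out["nee"][t] = -nep
        out["ch4"][t] = ch4
        out["n2o"][t] = n2o
        out["tree_c"][t] = float(state.tree_c.mean())
        out["gv_c"][t] = float(state.gv_c.mean())
        out["soil_c"][t] = float(soil_c_px.mean())
        out["total_c"][t] = out["tree_c"][t] + out["gv_c"][t] + out["soil_c"][t]
        out["harvested_c"][t] = harvested
        out["nbe"][t] = accounting.compute_nbe(nep, harvested, n2o, ch4)
        out["round_wood_m3"][t] = outcome.realized_round_wood
        out["energy_wood_m3"][t] = outcome.realized_energy_wood
        out["target_m3"][t] = outcome.target_volume
        out["shortfall_m3"][t] = outcome.shortfall
    return out, vol0, age0


def _country_targets_m3(stats: HarvestStatistics, scenario: HarvestScenario,
                        draw: UncertaintyDraw, config: SimulationConfig,
                        scale: float) -> np.ndarray:
    """Per-year combined (round + energy wood) landscape target volumes, m3.

    Historical years follow the realized statistics (identical across harvest
    scenarios); projection years use multiplier x historical mean.  Each
    yearly mean is perturbed by the simulation's 2% deviates.
    """
    years = config.years
    rw = np.empty(years.size)
    ew = np.empty(years.size)
    for t, y in enumerate(years):
        if y <= config.historical_end_year:
            j = np.where(stats.years == y)[0]
            rw_mean = float(stats.round_wood[j[0]]) if j.size else stats.base_round_wood
            ew_mean = float(stats.energy_wood[j[0]]) if j.size else stats.base_energy_wood
        else:
            rw_mean = scenario.multiplier * stats.base_round_wood
            ew_mean = scenario.multiplier * stats.base_energy_wood
        rw[t] = rw_mean * draw.round_wood_deviates[t]
        ew[t] = ew_mean * draw.energy_wood_deviates[t]
    return (rw + ew) * scale


def run_monte_carlo(landscape: Landscape, scenario: HarvestScenario | str,
                    config: SimulationConfig | None = None,
                    pools: ParameterPools | None = None,
                    stats: HarvestStatistics | None = None,
                    rcp: str = "RCP4.5", master_seed: int = 0,
                    rules: HarvestRules | None = None,
                    confusion: SiteTypeConfusionModel | None = None,
                    ) -> EnsembleResult:
    """Run the n_sim ensemble for one (RCP, harvest scenario) cell."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if rcp not in RCPS:
        raise ValueError(f"unknown RCP {rcp!r}")
    config = config or SimulationConfig()
    rules = rules or HarvestRules()
    confusion = confusion or SiteTypeConfusionModel()
    landscape.validate()
    if pools is None:
        pools = generate_parameter_pools(
            300, np.random.default_rng(np.random.SeedSequence([master_seed, 11])))
    if stats is None:
        stats = generate_harvest_statistics(
            np.random.default_rng(np.random.SeedSequence([master_seed, 12])))

    years = config.years
    n_regions = len(landscape.regions)
    areas = np.array([r.total_area_km2 for r in landscape.regions])
    shares = landscape.harvest_shares
    n_pix = _pixels_per_region(landscape, config)
    scale = _landscape_scale(landscape, config)
    weather_cache: dict = {}

    arrays = {v: np.full((n_regions, years.size, config.n_sim), np.nan)
              for v in OUTPUT_VARIABLES}
    vol0 = np.full((n_regions, config.n_sim), np.nan)
    age0 = np.full((n_regions, config.n_sim), np.nan)
    features: list[dict] = []
    failed: list[int] = []

    for i in range(config.n_sim):
        rng_sim = np.random.default_rng(np.random.SeedSequence([master_seed, 1, i]))
        draw = draw_simulation_settings(pools, scenario, config, rng_sim,
                                        simulation_id=i)
        params = pools.parameter_set(draw.pprel_id, draw.pcrob_id, draw.pyas_id)
        targets = _country_targets_m3(stats, scenario, draw, config, scale)
        rec = {"sim": i, "RCP": rcp, "Harv": scenario.label,
               **draw.feature_record(pools, years)}
        try:
            w_vol0 = np.zeros(n_regions)
            w_age0 = np.zeros(n_regions)
            for r, region in enumerate(landscape.regions):
                rng_region = np.random.default_rng(
                    np.random.SeedSequence([master_seed, 2, i, r]))
                weather = _weather_for(master_seed, r, years, draw.gcm, rcp,
                                       weather_cache)
                region_targets = targets * shares[r]
                out, v0, a0 = _simulate_region(
                    region, r, draw, params, weather, stats, scenario, config,
                    rules, confusion, rng_region, int(n_pix[r]), region_targets)
                for v in OUTPUT_VARIABLES:
                    arrays[v][r, :, i] = out[v]
                vol0[r, i], age0[r, i] = v0, a0
                w_vol0[r], w_age0[r] = v0, a0
            rec["vol0"] = accounting.aggregate_country(w_vol0, areas)
            rec["age0"] = accounting.aggregate_country(w_age0, areas)
        except Exception:
            logger.exception("simulation %d failed", i)
            failed.append(i)
        features.append(rec)

    region_ids = [r.region_id for r in landscape.regions]
    data = xr.Dataset(
        {v: (("region", "year", "sim"), arrays[v]) for v in OUTPUT_VARIABLES}
        | {"vol0": (("region", "sim"), vol0), "age0": (("region", "sim"), age0)},
        coords={"region": region_ids, "year": years,
                "sim": np.arange(config.n_sim)},
        attrs={"rcp": rcp, "harvest": scenario.label},
    )
    return EnsembleResult(data=data, features=pd.DataFrame(features).set_index("sim"),
                          region_areas_km2=areas, rcp=rcp, harvest=scenario.label,
                          failed_simulations=failed)


def run_scenario_grid(landscape: Landscape,
                      rcps=("RCP2.6", "RCP4.5", "RCP8.5"),
                      harvests=("NoHarv", "LowHarv", "BaseHarv", "MaxHarv"),
                      config: SimulationConfig | None = None,
                      pools: ParameterPools | None = None,
                      stats: HarvestStatistics | None = None,
                      master_seed: int = 0,
                      rules: HarvestRules | None = None,
                      ) -> list[EnsembleResult]:
    """Run the full scenario grid; one EnsembleResult per (RCP, harvest) cell."""
    results = []
    for rcp in rcps:
        for harv in harvests:
            results.append(run_monte_carlo(
                landscape, harv, config=config, pools=pools, stats=stats,
                rcp=rcp, master_seed=master_seed, rules=rules))
    return results
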