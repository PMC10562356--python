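"""Surrogate annual stand carbon model.

Pixel-level photosynthesis, allocation, litter production, crowding and
random mortality, and ground vegetation.  The model is a deliberately simple
surrogate with the same input/output contract as a full process-based stand
simulator: daily weather drives annual GPP through multiplicative modifiers,
GPP is split into autotrophic respiration and NPP, NPP is allocated to trees
and ground vegetation, turnover produces litter for the soil model, and the
annual carbon-flux identity

    delta(tree C + ground vegetation C) = NPP - litter - mortality litter - harvest

holds exactly on every step.  All state is vectorized over pixels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GrowthParams, ParameterSet

__all__ = [
    "StandState",
    "AnnualStandFlux",
    "HarvestApplication",
    "initialize_stand",
    "annual_gpp",
    "grow_stand",
    "ground_vegetation_biomass",
    "below_canopy_light",
]

SOIL_CODE = {"mineral": 0, "drained_organic": 1}
LAND_CODE = {"productive": 0, "poorly_productive": 1, "protected": 2}


@dataclass
class StandState:
    """Dynamic per-pixel state advanced annually. All stocks in kgC ha^-1."""

    tree_c: np.ndarray       # total tree carbon
    gv_c: np.ndarray         # ground vegetation carbon
    basal_area: np.ndarray   # m2 ha^-1
    dbh: np.ndarray          # cm
    height: np.ndarray       # m
    age: np.ndarray          # years
    species: np.ndarray      # (n, 3) proportions pine/spruce/birch
    volume: np.ndarray       # stem volume m3 ha^-1
    stems: np.ndarray        # stems ha^-1
    crown_height: np.ndarray  # m
    site_type: np.ndarray    # int 1..5
    soil_class: np.ndarray   # int codes, see SOIL_CODE
    land_class: np.ndarray   # int codes, see LAND_CODE
    crown_height_factor: float = 1.0
    site_types_locked: bool = False

    @property
    def n_pixels(self) -> int:
        return self.tree_c.size

    def copy(self) -> "StandState":
        return StandState(
            tree_c=self.tree_c.copy(), gv_c=self.gv_c.copy(),
            basal_area=self.basal_area.copy(), dbh=self.dbh.copy(),
            height=self.height.copy(), age=self.age.copy(),
            species=self.species.copy(), volume=self.volume.copy(),
            stems=self.stems.copy(), crown_height=self.crown_height.copy(),
            site_type=self.site_type.copy(), soil_class=self.soil_class.copy(),
            land_class=self.land_class.copy(),
            crown_height_factor=self.crown_height_factor,
            site_types_locked=self.site_types_locked)

    def validate(self) -> None:
        for name in ("tree_c", "gv_c", "basal_area", "dbh", "height",
                     "age", "volume", "stems"):
            if (getattr(self, name) < 0).any():
                raise ValueError(f"negative values in {name}")


@dataclass
class AnnualStandFlux:
    """Per-pixel annual fluxes, kgC ha^-1 yr^-1."""

    gpp: np.ndarray
    autotrophic_respiration: np.ndarray
    npp: np.ndarray
    litter: np.ndarray          # turnover + uncollected harvest residues, to soil
    mortality_litter: np.ndarray  # to soil
    harvested_c: np.ndarray     # leaves the ecosystem

    @property
    def litter_to_soil(self) -> np.ndarray:
        return self.litter + self.mortality_litter


@dataclass
class HarvestApplication:
    """Per-pixel harvest decided by the management stage for one year."""

    removal_frac: np.ndarray     # fraction of tree carbon removed, [0, 1]
    clearcut: np.ndarray         # bool, structure reset after removal
    harvested_c: np.ndarray      # kgC ha^-1 leaving the ecosystem
    residue_litter_c: np.ndarray  # kgC ha^-1 routed to soil litter

    @classmethod
    def none(cls, n: int) -> "HarvestApplication":
        z = np.zeros(n)
        return cls(removal_frac=z, clearcut=np.zeros(n, dtype=bool),
                   harvested_c=z.copy(), residue_litter_c=z.copy())


def _species_density(species: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """Basal-area-weighted wood density, kg dry m^-3."""
    return species @ np.asarray(growth.density)


def estimate_crown_height(height: np.ndarray, dbh: np.ndarray,
                          species: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """Empirical crown-base height: linear in height and diameter with a
    species-mixture offset, clamped to [0, 0.95 x height]."""
    offset = species @ np.asarray(growth.ch_species)
    raw = growth.ch_b * height + growth.ch_c * dbh + offset
    return np.clip(raw, 0.0, 0.95 * height)


def _form_factor(height: np.ndarray, crown_height: np.ndarray,
                 growth: GrowthParams) -> np.ndarray:
    """Stem form factor reduced as the live crown shortens."""
    with np.errstate(invalid="ignore", divide="ignore"):
        crown_ratio = np.where(height > 0, 1.0 - crown_height / np.maximum(height, 1e-9), 1.0)
    return growth.form_base * (1.0 - growth.form_crown * (1.0 - crown_ratio))


def below_canopy_light(basal_area: np.ndarray, growth: GrowthParams) -> np.ndarray:
    """Below-canopy light fraction, Beer-law decline with basal area."""
    return np.exp(-growth.light_k * np.asarray(basal_area, dtype=float))


def ground_vegetation_biomass(site_type: np.ndarray | int,
                              light: np.ndarray | float,
                              growth: GrowthParams | None = None) -> np.ndarray:
    """Ground vegetation carbon (kgC ha^-1) by site fertility and light.

    Monotone non-decreasing in light; fertile site types support at least as
    much biomass as poor ones at equal light.
    """
    growth = growth or GrowthParams()
    site = np.asarray(site_type)
    light_arr = np.asarray(light, dtype=float)
    if (light_arr < 0).any() or (light_arr > 1).any():
        raise ValueError("below-canopy light fraction must lie in [0, 1]")
    if ((site < 1) | (site > 5)).any():
        raise ValueError("site_type must be in {1..5}")
    base = np.asarray(growth.gv_base)[site - 1]
    return base * (growth.gv_min_frac + (1.0 - growth.gv_min_frac) * light_arr)


def initialize_stand(segments, crown_height_factor: float,
                     params: ParameterSet) -> StandState:
    """Initialize pixel states from sampled segment records.

    ``segments`` is a pandas DataFrame slice of the segment table (one row
    per sampled pixel).  Stem volume is basal area x height x form factor
    (form adjusted for crown ratio); tree carbon follows from volume through
    species-weighted wood density, carbon fraction and a whole-tree
    expansion factor.
    """
    if crown_height_factor <= 0:
        raise ValueError("crown_height_factor must be > 0")
    g = params.growth
    ba = segments["basal_area"].to_numpy(dtype=float).copy()
    dbh = segments["mean_dbh"].to_numpy(dtype=float).copy()
    height = segments["mean_height"].to_numpy(dtype=float).copy()
    age = np.maximum(segments["mean_age"].to_numpy(dtype=float), 0.0).copy()
    species = segments[["prop_pine", "prop_spruce", "prop_birch"]].to_numpy(dtype=float)
    site = segments["site_type"].to_numpy(dtype=int).copy()
    soil = np.array([SOIL_CODE[s] for s in segments["soil_class"]], dtype=np.int8)
    land = np.array([LAND_CODE[s] for s in segments["land_class"]], dtype=np.int8)

    crown = crown_height_factor * estimate_crown_height(height, dbh, species, g)
    form = _form_factor(height, crown, g)
    volume = ba * height * form
    density = _species_density(species, g)
    stem_c = volume * density * g.carbon_frac
    tree_c = stem_c * g.bef

    with np.errstate(divide="ignore", invalid="ignore"):
        stems = np.where(dbh > 0, ba / (np.pi * (dbh / 200.0) ** 2), 0.0)

    light = below_canopy_light(ba, g)
    gv_c = ground_vegetation_biomass(site, light, g)

    state = StandState(
        tree_c=tree_c, gv_c=gv_c, basal_area=ba, dbh=dbh, height=height,
        age=age, species=species.copy(), volume=volume, stems=stems,
        crown_height=crown, site_type=site, soil_class=soil, land_class=land,
        crown_height_factor=float(crown_height_factor))
    state.validate()
    return state


def annual_gpp(state: StandState, weather_year: dict | None = None,
               params: ParameterSet | None = None, *,
               radiation: np.ndarray | None = None,
               temperature: np.ndarray | None = None,
               vpd: np.ndarray | None = None,
               precipitation: np.ndarray | None = None,
               co2: float | np.ndarray | None = None) -> np.ndarray:
    """Annual per-pixel GPP, kgC ha^-1 yr^-1.

    GPP = LUE x fAPAR x sum_d radiation_d x prod(modifiers_d), with all daily
    modifiers in [0, 1].  The weather photosynthesis index (the sum over
    days) is shared by all pixels; fAPAR varies by pixel with basal area.
    """
    params = params or ParameterSet()
    if weather_year is not None:
        radiation = weather_year["radiation"]
        temperature = weather_year["temperature"]
        vpd = weather_year["vpd"]
        precipitation = weather_year["precipitation"]
        co2 = weather_year["co2"]
    index = weather_photosynthesis_index(radiation, temperature, vpd,
                                         precipitation, co2, params)
    p = params.photosynthesis
    fapar = np.maximum(p.fapar_min, 1.0 - np.exp(-p.fapar_k * state.basal_area))
    # gC m^-2 -> kgC ha^-1 is a factor of 10
    return 10.0 * p.lue * fapar * index


def weather_photosynthesis_index(radiation, temperature, vpd, precipitation,
                                 co2, params: ParameterSet) -> float:
    """Sum over days of radiation x daily modifiers (MJ m^-2)."""
    p = params.photosynthesis
    rad = np.asarray(radiation, dtype=float)
    temp = np.asarray(temperature, dtype=float)
    vpd_a = np.asarray(vpd, dtype=float)
    prec = np.asarray(precipitation, dtype=float)
    if not (rad.size == temp.size == vpd_a.size == prec.size == 365):
        raise ValueError("a full 365-day weather year is required")
    f_temp = np.clip((temp - p.t_min) / (p.t_opt - p.t_min), 0.0, 1.0)
    f_vpd = np.exp(-p.vpd_coef * vpd_a)
    # soft water modifier from a trailing 30-day precipitation sum
    kernel = np.ones(30) / 30.0
    rolling = np.convolve(prec, kernel, mode="full")[:365] * 30.0
    f_water = np.clip(rolling / p.water_ref, 0.0, 1.0)
    co2_arr = np.broadcast_to(np.asarray(co2, dtype=float), rad.shape)
    f_co2 = co2_arr / (co2_arr + p.co2_half)  # saturating, in (0, 1)
    return float(np.sum(rad * f_temp * f_vpd * f_water * f_co2))


def grow_stand(state: StandState, gpp: np.ndarray, params: ParameterSet,
               rng: np.random.Generator | None = None,
               harvest: HarvestApplication | None = None,
               stochastic_mortality: bool = False,
               ) -> tuple[StandState, AnnualStandFlux]:
    """Advance the stand one year; returns the new state and annual fluxes.

    Order of events: harvest removal (decided upstream), crowding + random
    mortality, turnover litter, NPP allocation to ground vegetation and
    trees, structural update, ageing.  Carbon is conserved exactly.
    """
    gpp = np.asarray(gpp, dtype=float)
    if (gpp < 0).any():
        raise ValueError("gpp must be non-negative")
    g = params.growth
    n = state.n_pixels
    harvest = harvest or HarvestApplication.none(n)
    new = state.copy()

    ra = g.resp_frac * gpp
    npp = gpp - ra

    # --- harvest removal (fractions and carbon splits decided by management)
    keep = 1.0 - harvest.removal_frac
    removed_c = harvest.removal_frac * state.tree_c
    t1 = state.tree_c - removed_c
    v1 = state.volume * keep
    s1 = state.stems * keep

    # --- mortality: crowding above the Reineke maximum density + random loss
    with np.errstate(divide="ignore", invalid="ignore"):
        max_stems = np.where(state.dbh > 0,
                             g.reineke_k * (state.dbh / g.reineke_ref_dbh)
                             ** (-g.reineke_slope), np.inf)
    crowd_frac = np.where(s1 > max_stems, 1.0 - max_stems / np.maximum(s1, 1e-9), 0.0)
    if stochastic_mortality and rng is not None:
        rand_frac = (rng.random(n) < g.mort_rate).astype(float) * 0.5
    else:
        rand_frac = np.full(n, g.mort_rate)
    mort_frac = np.clip(crowd_frac + rand_frac, 0.0, 0.95)
    mort_litter = mort_frac * t1
    t2 = t1 - mort_litter
    v2 = v1 * (1.0 - mort_frac)
    s2 = s1 * (1.0 - mort_frac)

    # --- turnover litter
    litter_tree = g.tree_turnover * t2
    t3 = t2 - litter_tree

    # --- NPP allocation: ground vegetation first (capped), remainder to trees
    ba_post = state.basal_area * keep * (1.0 - mort_frac)
    light = below_canopy_light(ba_post, g)
    gv_target = ground_vegetation_biomass(state.site_type, light, g)
    gv_litter = g.gv_turnover * state.gv_c
    npp_gv = np.clip(gv_target - state.gv_c + gv_litter, 0.0, g.gv_frac_cap * npp)
    npp_tree = npp - npp_gv

    new.gv_c = state.gv_c + npp_gv - gv_litter
    new.tree_c = t3 + npp_tree

    # --- structure: stem volume proportional to tree carbon; diameter from
    # volume and surviving stem count, height from the allometric curve
    density = _species_density(state.species, g)
    new.volume = new.tree_c / (g.bef * density * g.carbon_frac)
    cleared = harvest.clearcut
    s2 = np.where(cleared, g.regen_stems, s2)
    s2 = np.where((s2 <= 0) & (new.volume > 0), g.regen_stems, s2)
    c_geom = g.form_base * (np.pi / 40000.0) * g.h_a
    with np.errstate(divide="ignore", invalid="ignore"):
        dbh = np.where((new.volume > 0) & (s2 > 0),
                       (new.volume / (c_geom * np.maximum(s2, 1e-9)))
                       ** (1.0 / (2.0 + g.h_b)), 0.0)
    new.dbh = dbh
    new.height = g.h_a * dbh ** g.h_b
    new.stems = s2
    new.basal_area = s2 * np.pi * (dbh / 200.0) ** 2
    new.crown_height = state.crown_height_factor * estimate_crown_height(
        new.height, new.dbh, state.species, g)
    new.age = np.where(cleared, 0.0, state.age + 1.0)

    flux = AnnualStandFlux(
        gpp=gpp, autotrophic_respiration=ra, npp=npp,
        litter=litter_tree + gv_litter + harvest.residue_litter_c,
        mortality_litter=mort_litter,
        harvested_c=harvest.harvested_c)
    return new, flux
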