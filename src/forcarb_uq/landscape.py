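"""Synthetic forest landscapes emulating segmented national forest inventories.

Segments are homogeneous forest units (structure, age, fertility, soil and
land class, area) treated as exchangeable within a region.  The generator
targets regional summary statistics typical of boreal inventories — mean
basal area 11-18 m2/ha, mean age 44-91 y, right-skewed segment areas
0.026-540 ha — so that every downstream stage of the uncertainty pipeline
can be exercised without any external data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .params import PARAM_SUPPORTS, ParameterSet, params_from_row

__all__ = [
    "SPECIES",
    "SOIL_CLASSES",
    "LAND_CLASSES",
    "Segment",
    "Region",
    "Landscape",
    "RegionConfig",
    "LandscapeConfig",
    "HarvestStatistics",
    "ParameterPools",
    "generate_region",
    "generate_landscape",
    "generate_harvest_statistics",
    "generate_parameter_pools",
    "sample_pixels",
]

SPECIES = ("pine", "spruce", "birch")
SOIL_CLASSES = ("mineral", "drained_organic")
LAND_CLASSES = ("productive", "poorly_productive", "protected")

SEGMENT_COLUMNS = [
    "segment_id", "area_ha", "basal_area", "mean_dbh", "mean_height",
    "mean_age", "prop_pine", "prop_spruce", "prop_birch", "site_type",
    "soil_class", "land_class",
]


@dataclass(frozen=True)
class Segment:
    """One homogeneous forest unit — the Monte Carlo sampling population element."""

    segment_id: str
    area_ha: float
    basal_area: float           # m2 ha^-1
    mean_dbh: float             # cm
    mean_height: float          # m
    mean_age: float             # years
    species_proportions: tuple[float, float, float]  # pine, spruce, birch
    site_type: int              # ordinal fertility 1 (rich) .. 5 (poor)
    soil_class: str
    land_class: str

    def validate(self) -> None:
        if self.area_ha <= 0:
            raise ValueError("segment area must be > 0")
        for v, name in [(self.basal_area, "basal_area"), (self.mean_dbh, "mean_dbh"),
                        (self.mean_height, "mean_height"), (self.mean_age, "mean_age")]:
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        props = np.asarray(self.species_proportions, dtype=float)
        if props.min() < 0 or props.max() > 1 or abs(props.sum() - 1.0) > 1e-9:
            raise ValueError("species proportions must lie in [0,1] and sum to 1")
        if int(self.site_type) != self.site_type or not 1 <= self.site_type <= 5:
            raise ValueError("site_type must be an integer in [1, 5]")
        if self.soil_class not in SOIL_CLASSES:
            raise ValueError(f"unknown soil_class {self.soil_class!r}")
        if self.land_class not in LAND_CLASSES:
            raise ValueError(f"unknown land_class {self.land_class!r}")


@dataclass
class Region:
    """A collection of segments with a share of the country harvest."""

    region_id: str
    name: str
    segments: pd.DataFrame
    harvest_share: float = 1.0

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    @property
    def total_area_km2(self) -> float:
        return float(self.segments["area_ha"].sum()) / 100.0

    def validate(self) -> None:
        if self.segments.empty:
            raise ValueError(f"region {self.region_id} has no segments")
        missing = set(SEGMENT_COLUMNS) - set(self.segments.columns)
        if missing:
            raise ValueError(f"segment table missing columns {sorted(missing)}")
        seg = self.segments
        if (seg["area_ha"] <= 0).any():
            raise ValueError("all segment areas must be > 0")
        props = seg[["prop_pine", "prop_spruce", "prop_birch"]].to_numpy()
        if np.abs(props.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("species proportions must sum to 1")
        if not seg["site_type"].isin([1, 2, 3, 4, 5]).all():
            raise ValueError("site_type must be in {1..5}")
        if not 0.0 <= self.harvest_share <= 1.0:
            raise ValueError("harvest_share must lie in [0, 1]")


@dataclass
class Landscape:
    regions: list[Region]

    @property
    def harvest_shares(self) -> np.ndarray:
        return np.array([r.harvest_share for r in self.regions])

    @property
    def total_area_ha(self) -> float:
        return sum(r.total_area_km2 for r in self.regions) * 100.0

    def validate(self) -> None:
        if not self.regions:
            raise ValueError("landscape has no regions")
        for r in self.regions:
            r.validate()
        if abs(self.harvest_shares.sum() - 1.0) > 1e-9:
            raise ValueError("regional harvest shares must sum to 1")


@dataclass(frozen=True)
class RegionConfig:
    """Targets for one synthetic region."""

    n_segments: int = 1000
    mean_basal_area: float = 16.0   # m2 ha^-1
    mean_age: float = 56.0          # years
    species_mixture: tuple[float, float, float] = (0.5, 0.3, 0.2)
    organic_fraction: float = 0.10  # drained organic soil share
    protected_fraction: float = 0.05
    poorly_productive_fraction: float = 0.05
    area_median_ha: float = 0.8     # log-normal median segment area
    area_sigma: float = 1.0         # log-scale sd
    area_bounds: tuple[float, float] = (0.026, 540.0)
    fixed_area_ha: float | None = None
    site_type_probs: tuple[float, ...] = (0.10, 0.25, 0.35, 0.20, 0.10)
    dirichlet_concentration: float = 12.0
    mean_dbh_at_ref: float = 19.0   # cm at the reference basal area / age


@dataclass(frozen=True)
class LandscapeConfig:
    """A small multi-region layout; region sizes vary to probe area effects."""

    regions: tuple[RegionConfig, ...] = (
        RegionConfig(n_segments=300, mean_basal_area=17.0, mean_age=50.0,
                     species_mixture=(0.35, 0.45, 0.20), organic_fraction=0.08),
        RegionConfig(n_segments=1000, mean_basal_area=16.0, mean_age=56.0,
                     species_mixture=(0.45, 0.35, 0.20), organic_fraction=0.10),
        RegionConfig(n_segments=2500, mean_basal_area=14.0, mean_age=70.0,
                     species_mixture=(0.55, 0.25, 0.20), organic_fraction=0.15),
        RegionConfig(n_segments=6000, mean_basal_area=12.0, mean_age=85.0,
                     species_mixture=(0.65, 0.15, 0.20), organic_fraction=0.20),
    )


def _truncated_lognormal(rng: np.random.Generator, n: int, median: float,
                         sigma: float, bounds: tuple[float, float]) -> np.ndarray:
    """Right-skewed segment areas; out-of-range values are redrawn."""
    lo, hi = bounds
    out = np.exp(rng.normal(np.log(median), sigma, size=n))
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = np.exp(rng.normal(np.log(median), sigma, size=int(bad.sum())))
        bad = (out < lo) | (out > hi)
    return out


def generate_region(config: RegionConfig, seed: int | np.random.Generator,
                    region_id: str = "R1", name: str = "Region 1") -> Region:
    """Generate one synthetic region of exchangeable segments."""
    rng = np.random.default_rng(seed)
    n = int(config.n_segments)
    if n <= 0:
        raise ValueError("cannot generate a region with zero segments")
    mixture = np.asarray(config.species_mixture, dtype=float)
    if mixture.min() < 0 or abs(mixture.sum() - 1.0) > 1e-9:
        raise ValueError("species mixture proportions must sum to 1")

    if config.fixed_area_ha is not None:
        area = np.full(n, float(config.fixed_area_ha))
    else:
        area = _truncated_lognormal(rng, n, config.area_median_ha,
                                    config.area_sigma, config.area_bounds)

    # Age and basal area mildly correlated; both gamma-shaped with the
    # configured means so regional summaries hit the targets.
    age = rng.gamma(shape=6.25, scale=config.mean_age / 6.25, size=n)
    rel_age = age / config.mean_age
    ba = rng.gamma(shape=4.0, scale=config.mean_basal_area / 4.0, size=n) \
        * (0.5 + 0.5 * rel_age)
    ba /= (0.5 + 0.5 * rel_age).mean()  # keep the target mean exact in expectation
    dbh = config.mean_dbh_at_ref * np.sqrt(
        np.maximum(ba, 0.1) / config.mean_basal_area) * np.maximum(rel_age, 0.05) ** 0.3
    dbh *= np.exp(rng.normal(0.0, 0.08, size=n))
    height = 2.2 * dbh ** 0.68 * np.exp(rng.normal(0.0, 0.05, size=n))

    props = rng.dirichlet(config.dirichlet_concentration * np.maximum(mixture, 1e-8), size=n)
    site = rng.choice(np.arange(1, 6), size=n, p=np.asarray(config.site_type_probs))
    soil = np.where(rng.random(n) < config.organic_fraction,
                    "drained_organic", "mineral")
    u = rng.random(n)
    land = np.where(u < config.protected_fraction, "protected",
                    np.where(u < config.protected_fraction + config.poorly_productive_fraction,
                             "poorly_productive", "productive"))

    seg = pd.DataFrame({
        "segment_id": [f"{region_id}-{i:06d}" for i in range(n)],
        "area_ha": area,
        "basal_area": ba,
        "mean_dbh": dbh,
        "mean_height": height,
        "mean_age": age,
        "prop_pine": props[:, 0],
        "prop_spruce": props[:, 1],
        "prop_birch": props[:, 2],
        "site_type": site.astype(int),
        "soil_class": soil,
        "land_class": land,
    })
    region = Region(region_id=region_id, name=name, segments=seg, harvest_share=1.0)
    region.validate()
    return region


def generate_landscape(config: LandscapeConfig | None = None,
                       seed: int | np.random.Generator = 0) -> Landscape:
    """Generate a multi-region landscape; harvest shares follow region areas."""
    config = config or LandscapeConfig()
    rng = np.random.default_rng(seed)
    regions = []
    for i, rc in enumerate(config.regions):
        rid = f"{i + 1:02d}"
        regions.append(generate_region(rc, rng, region_id=rid, name=f"Region {rid}"))
    areas = np.array([r.total_area_km2 for r in regions])
    shares = areas / areas.sum()
    for r, s in zip(regions, shares):
        r.harvest_share = float(s)
    scape = Landscape(regions=regions)
    scape.validate()
    return scape


@dataclass
class HarvestStatistics:
    """Country-level realized harvest volumes, 2015-2021, plus regional shares."""

    years: np.ndarray                  # calendar years
    round_wood: np.ndarray             # Mm3 yr^-1
    energy_wood: np.ndarray            # Mm3 yr^-1
    regional_shares: np.ndarray | None = None

    @property
    def base_round_wood(self) -> float:
        """Projection-period base level: mean of the historical years."""
        return float(self.round_wood.mean())

    @property
    def base_energy_wood(self) -> float:
        return float(self.energy_wood.mean())


def generate_harvest_statistics(
        seed: int | np.random.Generator = 0,
        round_wood_bounds: tuple[float, float] = (68.0, 78.0),
        energy_wood_bounds: tuple[float, float] = (7.2, 10.2),
        years: Sequence[int] = range(2015, 2022),
        regional_shares: Sequence[float] | None = None) -> HarvestStatistics:
    """Emulated national harvest statistics, uniform within the observed bounds."""
    rng = np.random.default_rng(seed)
    years = np.asarray(list(years))
    rw = rng.uniform(*round_wood_bounds, size=len(years))
    ew = rng.uniform(*energy_wood_bounds, size=len(years))
    shares = None
    if regional_shares is not None:
        shares = np.asarray(regional_shares, dtype=float)
        shares = shares / shares.sum()
    return HarvestStatistics(years=years, round_wood=rw, energy_wood=ew,
                             regional_shares=shares)


@dataclass
class ParameterPools:
    """Posterior-like pools of parameter vectors for the three sub-models."""

    photosynthesis: pd.DataFrame
    growth: pd.DataFrame
    soil: pd.DataFrame

    def validate(self) -> None:
        for group in ("photosynthesis", "growth", "soil"):
            df = getattr(self, group)
            if df.empty:
                raise ValueError(f"parameter pool {group!r} is empty")
            for col, (lo, hi) in PARAM_SUPPORTS[group].items():
                v = df[col]
                if (v < lo).any() or (v > hi).any():
                    raise ValueError(f"pool {group}.{col} outside support [{lo}, {hi}]")

    def parameter_set(self, pprel_id: int, pcrob_id: int, pyas_id: int) -> ParameterSet:
        return ParameterSet(
            photosynthesis=params_from_row("photosynthesis",
                                           self.photosynthesis.iloc[pprel_id]),
            growth=params_from_row("growth", self.growth.iloc[pcrob_id]),
            soil=params_from_row("soil", self.soil.iloc[pyas_id]),
            pprel_id=pprel_id, pcrob_id=pcrob_id, pyas_id=pyas_id,
        )


#: Relative sd of the emulated posteriors around the default parameter values.
POOL_SPREAD = 0.04
#: Correlation induced by one shared latent factor per pool.
POOL_CORRELATION = 0.3


def generate_parameter_pools(n_per_pool: int = 300,
                             seed: int | np.random.Generator = 0,
                             spread: float = POOL_SPREAD) -> ParameterPools:
    """Correlated multivariate draws around the default parameter values."""
    if n_per_pool < 1:
        raise ValueError("n_per_pool must be >= 1")
    rng = np.random.default_rng(seed)
    from . import params as _p
    defaults = {
        "photosynthesis": _p.PhotosynthesisParams(),
        "growth": _p.GrowthParams(),
        "soil": _p.SoilParams(),
    }
    tables = {}
    for group, supp in PARAM_SUPPORTS.items():
        latent = rng.normal(size=n_per_pool)
        cols = {}
        for name, (lo, hi) in supp.items():
            mu = float(getattr(defaults[group], name))
            eps = (np.sqrt(POOL_CORRELATION) * latent
                   + np.sqrt(1.0 - POOL_CORRELATION) * rng.normal(size=n_per_pool))
            scale = spread * (abs(mu) if abs(mu) > 1e-12 else (hi - lo) / 10.0)
            cols[name] = np.clip(mu + scale * eps, lo, hi)
        tables[group] = pd.DataFrame(cols)
    pools = ParameterPools(photosynthesis=tables["photosynthesis"],
                           growth=tables["growth"], soil=tables["soil"])
    pools.validate()
    return pools


def sample_pixels(region: Region, n_pixels: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Area-weighted bootstrap of segment indices (pixels).

    Each segment's selection probability is proportional to its area, so a
    sample of ``n_pixels`` pixels of equal representative area is a
    representative sample of the region's forest area.
    """
    if n_pixels < 0:
        raise ValueError("n_pixels must be >= 0")
    if n_pixels == 0:
        return np.empty(0, dtype=np.int64)
    if region.n_segments == 0:
        raise ValueError("cannot sample pixels from an empty region")
    w = region.segments["area_ha"].to_numpy(dtype=float)
    return rng.choice(region.n_segments, size=n_pixels, replace=True, p=w / w.sum())
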