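"""Harvest rules, scenario targets and stochastic regional allocation.

Stand-level silvicultural triggers (species-specific clearcut diameter /
dominant height / age, a basal-area thinning trigger) decide which pixels
are eligible each year.  Eligible pixels are visited in a uniformly random
order and their triggered action executed in full until the regional target
volume is met; if eligibles run out first the remainder is an explicit
shortfall and no further harvesting happens that year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import GrowthParams
from .stand import LAND_CODE, HarvestApplication, StandState, _species_density

__all__ = [
    "ACTION_NONE", "ACTION_THIN", "ACTION_CLEARCUT",
    "SpeciesTriggers", "HarvestRules", "HarvestScenario", "SCENARIOS",
    "RegionalHarvestOutcome",
    "eligible_action", "scenario_targets", "sample_country_target",
    "allocate_country_to_regions", "allocate_regional_harvest",
]

ACTION_NONE, ACTION_THIN, ACTION_CLEARCUT = 0, 1, 2


@dataclass(frozen=True)
class SpeciesTriggers:
    """Clearcut triggers for one species (any one met triggers, by default)."""

    clearcut_dbh: float     # cm
    clearcut_height: float  # m
    clearcut_age: float     # years
    thinning_basal_area: float  # m2 ha^-1


# Default rule file: representative managed-boreal guideline numbers,
# fully configurable.  Order: pine, spruce, birch.
DEFAULT_TRIGGERS = (
    SpeciesTriggers(clearcut_dbh=26.0, clearcut_height=24.0,
                    clearcut_age=80.0, thinning_basal_area=26.0),
    SpeciesTriggers(clearcut_dbh=25.0, clearcut_height=23.0,
                    clearcut_age=70.0, thinning_basal_area=28.0),
    SpeciesTriggers(clearcut_dbh=24.0, clearcut_height=22.0,
                    clearcut_age=60.0, thinning_basal_area=24.0),
)


@dataclass(frozen=True)
class HarvestRules:
    triggers: tuple[SpeciesTriggers, SpeciesTriggers, SpeciesTriggers] = DEFAULT_TRIGGERS
    thinning_removal_frac: float = 0.35   # fraction of standing stock removed
    energy_wood_frac: float = 0.5         # collected fraction of residues
    clearcut_combinator: str = "or"       # "or": any trigger met, "and": all

    def __post_init__(self):
        if not 0.0 < self.thinning_removal_frac < 1.0:
            raise ValueError("thinning removal fraction must be in (0, 1)")
        if not 0.0 <= self.energy_wood_frac <= 1.0:
            raise ValueError("energy wood fraction must be in [0, 1]")
        if self.clearcut_combinator not in ("or", "and"):
            raise ValueError("clearcut_combinator must be 'or' or 'and'")


@dataclass(frozen=True)
class HarvestScenario:
    """Projection-period harvest intensity relative to the historical base."""

    label: str
    multiplier: float

    _ALLOWED = {"NoHarv": 0.0, "LowHarv": 0.6, "BaseHarv": 1.0, "MaxHarv": 1.2}

    def __post_init__(self):
        if self.label not in self._ALLOWED:
            raise ValueError(f"unknown harvest scenario {self.label!r}")
        if self.multiplier != self._ALLOWED[self.label]:
            raise ValueError(
                f"scenario {self.label} requires multiplier {self._ALLOWED[self.label]}")

    @classmethod
    def from_label(cls, label: str) -> "HarvestScenario":
        return cls(label=label, multiplier=cls._ALLOWED[label])


SCENARIOS = {name: HarvestScenario.from_label(name)
             for name in ("NoHarv", "LowHarv", "BaseHarv", "MaxHarv")}


@dataclass
class RegionalHarvestOutcome:
    """One region-year harvest bookkeeping record."""

    target_volume: float          # m3
    realized_round_wood: float    # m3
    realized_energy_wood: float   # m3
    shortfall: float              # m3, >= 0
    harvested_pixels: np.ndarray  # indices
    actions: np.ndarray           # per-pixel action codes
    application: HarvestApplication  # per-pixel carbon removals

    @property
    def realized_total(self) -> float:
        return self.realized_round_wood + self.realized_energy_wood


def eligible_action(state: StandState, rules: HarvestRules) -> np.ndarray:
    """Per-pixel action codes: clearcut beats thinning; protected and poorly
    productive land always gets none."""
    dom = state.species.argmax(axis=1)
    cc_dbh = np.array([t.clearcut_dbh for t in rules.triggers])[dom]
    cc_h = np.array([t.clearcut_height for t in rules.triggers])[dom]
    cc_age = np.array([t.clearcut_age for t in rules.triggers])[dom]
    thin_ba = np.array([t.thinning_basal_area for t in rules.triggers])[dom]

    hits = np.stack([state.dbh >= cc_dbh, state.height >= cc_h,
                     state.age >= cc_age])
    clearcut = hits.any(axis=0) if rules.clearcut_combinator == "or" else hits.all(axis=0)
    thinning = state.basal_area >= thin_ba

    action = np.where(clearcut, ACTION_CLEARCUT,
                      np.where(thinning, ACTION_THIN, ACTION_NONE))
    action = np.where(state.land_class != LAND_CODE["productive"], ACTION_NONE, action)
    # nothing to cut in an empty pixel
    return np.where(state.tree_c > 0, action, ACTION_NONE).astype(np.int8)


def scenario_targets(base_level: float, scenario: HarvestScenario) -> float:
    """Projection-period target: multiplier x historical base level."""
    if base_level < 0:
        raise ValueError("base level must be >= 0")
    return scenario.multiplier * base_level


def sample_country_target(mean_level: float, rng: np.random.Generator,
                          cv: float = 0.02) -> float:
    """Country target draw ~ Normal(mean, (cv x mean)^2), truncated at 0."""
    if mean_level < 0:
        raise ValueError("mean level must be >= 0")
    if mean_level == 0:
        return 0.0
    return float(max(0.0, rng.normal(mean_level, cv * mean_level)))


def allocate_country_to_regions(country_target: float,
                                shares: np.ndarray) -> np.ndarray:
    """Split a country target by historical regional shares."""
    shares = np.asarray(shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("regional shares must sum to 1")
    return country_target * shares


def pixel_harvest_yields(state: StandState, rules: HarvestRules,
                         actions: np.ndarray, rep_area_ha: float,
                         growth: GrowthParams) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(round wood m3, energy wood m3, removal fraction) per pixel if harvested.

    Clearcut removes the whole stock, thinning the configured fraction.
    Removed stem carbon becomes round wood; the collected share of residues
    (branches, tops) becomes energy wood, the rest falls as litter.
    """
    frac = np.where(actions == ACTION_CLEARCUT, 1.0,
                    np.where(actions == ACTION_THIN, rules.thinning_removal_frac, 0.0))
    density = _species_density(state.species, growth)
    removed_c = frac * state.tree_c                       # kgC ha^-1
    stem_c = removed_c / growth.bef
    residue_c = removed_c - stem_c
    round_m3 = stem_c / (density * growth.carbon_frac) * rep_area_ha
    energy_m3 = (rules.energy_wood_frac * residue_c
                 / (density * growth.carbon_frac)) * rep_area_ha
    return round_m3, energy_m3, frac


def allocate_regional_harvest(state: StandState, region_target_m3: float,
                              rules: HarvestRules, rng: np.random.Generator,
                              rep_area_ha: float,
                              growth: GrowthParams | None = None,
                              ) -> RegionalHarvestOutcome:
    """Visit eligible pixels in random order until the target volume is met.

    The marginal pixel's action is executed in full (overshoot bounded by its
    yield).  If the eligibles are exhausted first, the remainder is shortfall.
    """
    if region_target_m3 < 0:
        raise ValueError("region target must be >= 0")
    growth = growth or GrowthParams()
    n = state.n_pixels
    actions = eligible_action(state, rules)
    app = HarvestApplication.none(n)

    eligible = np.nonzero(actions != ACTION_NONE)[0]
    order = rng.permutation(eligible)

    if region_target_m3 == 0 or order.size == 0:
        realized_rw = realized_ew = 0.0
        chosen = np.empty(0, dtype=np.int64)
    else:
        round_m3, energy_m3, frac = pixel_harvest_yields(
            state, rules, actions, rep_area_ha, growth)
        totals = (round_m3 + energy_m3)[order]
        cum = np.cumsum(totals)
        stop = int(np.searchsorted(cum, region_target_m3, side="left"))
        chosen = order[:min(stop + 1, order.size)]
        realized_rw = float(round_m3[chosen].sum())
        realized_ew = float(energy_m3[chosen].sum())
        app.removal_frac[chosen] = frac[chosen]
        app.clearcut[chosen] = actions[chosen] == ACTION_CLEARCUT
        removed_c = frac[chosen] * state.tree_c[chosen]
        stem_c = removed_c / growth.bef
        residue_c = removed_c - stem_c
        app.harvested_c[chosen] = stem_c + rules.energy_wood_frac * residue_c
        app.residue_litter_c[chosen] = (1.0 - rules.energy_wood_frac) * residue_c

    realized = realized_rw + realized_ew
    shortfall = max(0.0, region_target_m3 - realized)
    out_actions = np.zeros(n, dtype=np.int8)
    out_actions[chosen] = actions[chosen]
    return RegionalHarvestOutcome(
        target_volume=float(region_target_m3),
        realized_round_wood=realized_rw, realized_energy_wood=realized_ew,
        shortfall=shortfall, harvested_pixels=chosen, actions=out_actions,
        application=app)
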