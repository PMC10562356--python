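"""Surrogate process-model parameters.

Three parameter groups mirror the three sub-models of the coupled stand
simulator: photosynthesis (light-use-efficiency model with daily weather
modifiers), structural growth/allocation, and soil-carbon decay.  Posterior
parameter pools are emulated by correlated multivariate draws around these
defaults, truncated to the stated supports.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from typing import Mapping

__all__ = [
    "PhotosynthesisParams",
    "GrowthParams",
    "SoilParams",
    "ParameterSet",
    "PARAM_SUPPORTS",
    "default_parameter_set",
]


@dataclass(frozen=True)
class PhotosynthesisParams:
    """Light-use-efficiency photosynthesis parameters (pPrel group).

    GPP is LUE x fAPAR x sum over days of radiation x product of daily
    modifiers, each modifier in [0, 1].
    """

    lue: float = 1.45           # gC per MJ absorbed radiation
    t_min: float = 0.0          # degC, photosynthesis shut-off
    t_opt: float = 18.0         # degC, temperature ramp saturates
    vpd_coef: float = 0.4       # kPa^-1, exponential VPD decline
    water_ref: float = 30.0     # mm per 30 days saturating the water modifier
    co2_half: float = 300.0     # ppm, half-saturation of the CO2 modifier
    fapar_k: float = 0.09       # m^-2 ha, light capture vs basal area
    fapar_min: float = 0.05     # floor so clearcut stands can regrow


@dataclass(frozen=True)
class GrowthParams:
    """Allocation, turnover, mortality and allometry parameters (pCrob group)."""

    resp_frac: float = 0.50       # autotrophic respiration as fraction of GPP
    gv_frac_cap: float = 0.15     # max share of NPP available to ground vegetation
    tree_turnover: float = 0.04   # yr^-1 litter turnover of total tree carbon
    gv_turnover: float = 0.30     # yr^-1 ground vegetation turnover
    mort_rate: float = 0.005      # yr^-1 random (non-crowding) mortality fraction
    reineke_k: float = 2200.0     # max stems ha^-1 at reference dbh
    reineke_slope: float = 1.605  # density declines as dbh^-slope
    reineke_ref_dbh: float = 25.0  # cm
    form_base: float = 0.45       # stem form factor at full crown
    form_crown: float = 0.25      # form reduction per unit lost crown ratio
    ch_b: float = 0.45            # crown height vs tree height
    ch_c: float = 0.05            # crown height vs dbh (cm -> m)
    ch_species: tuple[float, float, float] = (0.5, -0.5, 0.0)  # pine, spruce, birch offsets (m)
    h_a: float = 2.2              # height allometry height = h_a * dbh^h_b
    h_b: float = 0.68
    bef: float = 1.55             # total tree carbon / stem carbon
    density: tuple[float, float, float] = (400.0, 385.0, 485.0)  # kg dry m^-3
    carbon_frac: float = 0.5      # kgC per kg dry biomass
    regen_stems: float = 2000.0   # stems ha^-1 planted after clearcut
    light_k: float = 0.06         # below-canopy light = exp(-light_k * BA)
    gv_base: tuple[float, float, float, float, float] = (
        2000.0, 1700.0, 1400.0, 1100.0, 800.0)  # kgC ha^-1 by site type 1..5
    gv_min_frac: float = 0.2      # ground vegetation floor at zero light


@dataclass(frozen=True)
class SoilParams:
    """Three-pool first-order soil decay parameters (pYas group)."""

    k_fast: float = 0.48      # yr^-1
    k_slow: float = 0.045     # yr^-1
    k_humus: float = 0.004    # yr^-1
    t_fast_slow: float = 0.30   # transfer fraction fast -> slow
    t_slow_humus: float = 0.15  # transfer fraction slow -> humus
    q10: float = 1.8
    temp_ref: float = 4.0     # degC mean annual reference temperature


@dataclass(frozen=True)
class ParameterSet:
    """One joint draw of the three sub-model parameter groups."""

    photosynthesis: PhotosynthesisParams = field(default_factory=PhotosynthesisParams)
    growth: GrowthParams = field(default_factory=GrowthParams)
    soil: SoilParams = field(default_factory=SoilParams)
    pprel_id: int = -1
    pcrob_id: int = -1
    pyas_id: int = -1

    def validate(self) -> None:
        p, g, s = self.photosynthesis, self.growth, self.soil
        if p.lue <= 0:
            raise ValueError("light-use efficiency must be > 0")
        for name, frac in [("resp_frac", g.resp_frac), ("gv_frac_cap", g.gv_frac_cap),
                           ("tree_turnover", g.tree_turnover), ("gv_turnover", g.gv_turnover),
                           ("mort_rate", g.mort_rate)]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"allocation fraction {name}={frac} outside [0, 1]")
        for name, k in [("k_fast", s.k_fast), ("k_slow", s.k_slow), ("k_humus", s.k_humus)]:
            if k <= 0:
                raise ValueError(f"decay rate {name}={k} must be > 0")


# Supports used to truncate the emulated posterior pools.  Only scalar
# parameters that are resampled per simulation appear here; structural
# constants (allometry, densities) stay fixed.
PARAM_SUPPORTS: dict[str, dict[str, tuple[float, float]]] = {
    "photosynthesis": {
        "lue": (0.5, 4.0),
        "t_min": (-3.0, 3.0),
        "t_opt": (10.0, 25.0),
        "vpd_coef": (0.05, 1.2),
        "water_ref": (10.0, 80.0),
        "co2_half": (100.0, 800.0),
    },
    "growth": {
        "resp_frac": (0.25, 0.65),
        "tree_turnover": (0.005, 0.08),
        "mort_rate": (0.0, 0.03),
        "reineke_k": (1200.0, 3500.0),
        "form_base": (0.30, 0.60),
    },
    "soil": {
        "k_fast": (0.1, 1.2),
        "k_slow": (0.01, 0.15),
        "k_humus": (0.0005, 0.02),
        "t_fast_slow": (0.05, 0.6),
        "t_slow_humus": (0.02, 0.4),
    },
}


def default_parameter_set() -> ParameterSet:
    return ParameterSet()


def params_from_row(group: str, row: Mapping[str, float]) -> object:
    """Build a parameter dataclass from a pool row, keeping defaults elsewhere."""
    base = {"photosynthesis": PhotosynthesisParams,
            "growth": GrowthParams,
            "soil": SoilParams}[group]()
    valid = {f.name for f in fields(base)}
    updates = {k: float(v) for k, v in row.items() if k in valid}
    return replace(base, **updates)
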