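"""Synthetic daily weather drivers for scenario simulations.

Emulates bias-corrected, downscaled GCM weather: a sinusoidal seasonal cycle
with AR(1) daily noise, plus RCP-specific warming and CO2 trends that start
at a configurable onset year.  Inter-GCM spread is realized as GCM-specific
temperature offsets and trend multipliers, which gives the attribution stage
a detectable climate-model signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import lfilter

__all__ = ["GCMS", "RCPS", "WeatherSeries", "WeatherConfig", "generate_weather"]

GCMS = ("CanESM2", "CNRM", "GFDL", "HadGEM2", "MIROC")
RCPS = ("RCP2.6", "RCP4.5", "RCP8.5")

DAYS = 365

# degC per year after the trend onset
_RCP_WARMING = {"RCP2.6": 0.010, "RCP4.5": 0.030, "RCP8.5": 0.060}
# ppm per year after the trend onset (non-negative, so CO2 is non-decreasing)
_RCP_CO2_RATE = {"RCP2.6": 0.5, "RCP4.5": 2.0, "RCP8.5": 3.5}
# GCM-specific mean temperature offsets (degC) and trend multipliers
_GCM_OFFSET = {"CanESM2": 0.8, "CNRM": -0.4, "GFDL": 0.0, "HadGEM2": 0.5, "MIROC": -0.6}
_GCM_TREND = {"CanESM2": 1.25, "CNRM": 0.85, "GFDL": 1.0, "HadGEM2": 1.15, "MIROC": 0.75}


@dataclass(frozen=True)
class WeatherConfig:
    mean_temp: float = 4.0        # degC annual mean before trends
    seasonal_amp: float = 13.0    # degC seasonal half-range
    temp_ar1: float = 0.7
    temp_noise_sd: float = 2.5    # degC daily innovation
    rad_peak: float = 17.0        # MJ m^-2 d^-1 midsummer mean
    rad_floor: float = 0.3        # MJ m^-2 d^-1 midwinter mean
    precip_mean: float = 1.8      # mm d^-1
    wet_day_prob: float = 0.45
    co2_base: float = 400.0       # ppm at the start year
    trend_onset_year: int = 2021  # trends apply after this year


@dataclass
class WeatherSeries:
    """Daily drivers for a span of years under one (GCM, RCP) labelling."""

    years: np.ndarray            # (n_years,)
    radiation: np.ndarray        # (n_years, 365) MJ m^-2 d^-1
    temperature: np.ndarray      # (n_years, 365) degC
    vpd: np.ndarray              # (n_years, 365) kPa
    precipitation: np.ndarray    # (n_years, 365) mm d^-1
    co2: np.ndarray              # (n_years,) ppm
    gcm: str = "GFDL"
    rcp: str = "RCP4.5"

    def year_index(self, year: int) -> int:
        idx = np.nonzero(self.years == year)[0]
        if idx.size == 0:
            raise KeyError(f"year {year} not in weather series")
        return int(idx[0])

    def mean_annual_temperature(self) -> np.ndarray:
        return self.temperature.mean(axis=1)


def generate_weather(years: Sequence[int], gcm: str, rcp: str,
                     seed: int | np.random.SeedSequence = 0,
                     config: WeatherConfig | None = None) -> WeatherSeries:
    """Deterministic synthetic weather for fixed (seed, gcm, rcp)."""
    years = np.asarray(list(years), dtype=int)
    if years.size == 0:
        raise ValueError("years must be non-empty")
    if gcm not in GCMS:
        raise ValueError(f"unknown GCM {gcm!r}; expected one of {GCMS}")
    if rcp not in RCPS:
        raise ValueError(f"unknown RCP {rcp!r}; expected one of {RCPS}")
    cfg = config or WeatherConfig()

    if isinstance(seed, np.random.SeedSequence):
        entropy = [int(e) for e in np.atleast_1d(seed.generate_state(1))]
    else:
        entropy = [int(seed)]
    # The label indices enter the seed so each (gcm, rcp) stream is distinct
    # yet reproducible from the same integer seed.
    rng = np.random.default_rng(
        np.random.SeedSequence([*entropy, GCMS.index(gcm), RCPS.index(rcp)]))

    n_years = years.size
    doy = np.arange(DAYS)
    season = -np.cos(2.0 * np.pi * (doy - 15) / DAYS)  # peaks in July

    years_after_onset = np.maximum(0, years - cfg.trend_onset_year)
    warming = _RCP_WARMING[rcp] * _GCM_TREND[gcm] * years_after_onset
    base_temp = cfg.mean_temp + _GCM_OFFSET[gcm]

    # AR(1) daily temperature noise, continuous across year boundaries
    innov = rng.normal(0.0, cfg.temp_noise_sd, size=n_years * DAYS)
    noise = lfilter([1.0], [1.0, -cfg.temp_ar1], innov).reshape(n_years, DAYS)

    temperature = (base_temp + warming[:, None]
                   + cfg.seasonal_amp * season[None, :] + noise)

    rad_season = cfg.rad_floor + (cfg.rad_peak - cfg.rad_floor) * (season + 1.0) / 2.0
    radiation = np.maximum(
        0.0, rad_season[None, :] * np.exp(rng.normal(0.0, 0.25, size=(n_years, DAYS))))

    # VPD rises with warm, dry days; kept non-negative by construction
    vpd = np.maximum(0.0, 0.05 + 0.035 * np.maximum(temperature, 0.0)
                     + rng.normal(0.0, 0.08, size=(n_years, DAYS)))

    wet = rng.random((n_years, DAYS)) < cfg.wet_day_prob
    amounts = rng.gamma(shape=0.9, scale=cfg.precip_mean / (0.9 * cfg.wet_day_prob),
                        size=(n_years, DAYS))
    precipitation = np.where(wet, amounts, 0.0)

    co2 = cfg.co2_base + _RCP_CO2_RATE[rcp] * np.maximum(0, years - years[0])
    co2 = np.maximum.accumulate(co2)  # non-decreasing by construction

    return WeatherSeries(years=years, radiation=radiation, temperature=temperature,
                         vpd=vpd, precipitation=precipitation, co2=co2,
                         gcm=gcm, rcp=rcp)
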