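"""Seeded synthetic daily weather for a temperate continental monsoon station.

Temperature follows an annual sinusoid peaking in July (Northern
Hemisphere) with AR(1) noise; sunshine is a noisy fraction of the
astronomical day length; rainfall occurrence is concentrated in summer
with amounts scaled so the expected annual total equals the requested
mean.  Everything derives from a single seed, so a spec generates
byte-identical series across runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atmosphere import extraterrestrial_radiation
from .et0_models import ET0Series, ModelParams, fr_driver
from .weather_io import WEATHER_COLUMNS, DailyWeatherSeries, StationMeta

#: AR(1) coefficient of the daily temperature anomaly
AR1_PHI = 0.7


@dataclass(frozen=True)
class ClimateSpec:
    """Parameters of the synthetic climate."""

    latitude: float = 38.85
    elevation: float = 17.0
    tmean_annual: float = 13.0        # degC
    tmean_amplitude: float = 14.0     # degC, half peak-to-trough
    diurnal_range_mean: float = 10.0  # degC
    rh_mean: float = 62.0             # percent
    wind_mean: float = 2.2            # m s-1
    sunshine_fraction_mean: float = 0.55
    annual_precip_mean: float = 500.0  # mm
    precip_summer_fraction: float = 0.7  # share falling in Jun-Sep
    noise_sd_t: float = 2.0           # degC
    seed: int = 0

    def __post_init__(self):
        for name in ("tmean_amplitude", "diurnal_range_mean", "rh_mean",
                     "wind_mean", "annual_precip_mean", "noise_sd_t"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("sunshine_fraction_mean", "precip_summer_fraction"):
            if not 0.0 < getattr(self, name) < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")

    def station(self, station_id: str = "synthetic") -> StationMeta:
        return StationMeta(station_id=station_id, latitude=self.latitude,
                           elevation=self.elevation, anemometer_height=10.0)


def _seasonal_cycle(doy: np.ndarray, spec: ClimateSpec) -> np.ndarray:
    # peak near 15 July (doy 196) in the Northern Hemisphere, 15 Jan south
    phase = 196.0 if spec.latitude >= 0 else 15.0
    return spec.tmean_annual + spec.tmean_amplitude * np.cos(
        2.0 * np.pi * (doy - phase) / 365.25)


def _summer_weight(doy: np.ndarray, spec: ClimateSpec) -> np.ndarray:
    # daily rainfall weights: Jun-Sep (doy 152-273) carries the summer share
    in_summer = (doy >= 152) & (doy <= 273)
    n_summer = 122.0
    n_rest = 365.25 - n_summer
    w = np.where(in_summer,
                 spec.precip_summer_fraction / n_summer,
                 (1.0 - spec.precip_summer_fraction) / n_rest)
    return w


def generate_station_weather(spec: ClimateSpec, n_years: int,
                             start_year: int = 1991) -> DailyWeatherSeries:
    """Generate ``n_years`` calendar years of daily weather."""
    if n_years < 1:
        raise ValueError("n_years must be >= 1")
    rng = np.random.default_rng(spec.seed)
    streams = {name: np.random.default_rng(s) for name, s in zip(
        ("temp", "range", "sun", "rh", "wind", "rain"),
        rng.integers(0, 2**63 - 1, size=6))}

    dates = pd.date_range(f"{start_year}-01-01",
                          f"{start_year + n_years - 1}-12-31", freq="D")
    doy = dates.dayofyear.to_numpy().astype(float)
    n = len(dates)

    # AR(1) anomaly with stationary marginal sd = noise_sd_t
    innov_sd = spec.noise_sd_t * np.sqrt(1.0 - AR1_PHI ** 2)
    eps = streams["temp"].normal(0.0, innov_sd, size=n)
    anomaly = np.empty(n)
    anomaly[0] = streams["temp"].normal(0.0, spec.noise_sd_t)
    for i in range(1, n):
        anomaly[i] = AR1_PHI * anomaly[i - 1] + eps[i]
    tmean = _seasonal_cycle(doy, spec) + anomaly

    half_range = 0.5 * spec.diurnal_range_mean * np.clip(
        streams["range"].normal(1.0, 0.15, size=n), 0.2, 2.0)
    tmax = tmean + half_range
    tmin = tmean - half_range

    _, daylength = extraterrestrial_radiation(spec.latitude, doy)
    sun_frac = np.clip(
        streams["sun"].normal(spec.sunshine_fraction_mean, 0.2, size=n), 0.0, 1.0)
    sunshine = sun_frac * daylength

    rh = np.clip(streams["rh"].normal(spec.rh_mean, 8.0, size=n), 5.0, 99.0)
    wind = spec.wind_mean * streams["wind"].lognormal(-0.08, 0.4, size=n)

    weight = _summer_weight(doy, spec)  # per-day weights summing to ~1 per year
    p_wet = np.where((doy >= 152) & (doy <= 273), 0.35, 0.15)
    expected = spec.annual_precip_mean * weight
    wet = streams["rain"].random(n) < p_wet
    amounts = streams["rain"].exponential(1.0, size=n) * (expected / p_wet)
    precip = np.where(wet, amounts, 0.0)

    frame = pd.DataFrame({
        "tmax_c": tmax, "tmin_c": tmin, "tmean_c": tmean,
        "rh_pct": rh, "vp_kpa": np.nan, "pressure_kpa": np.nan,
        "wind_ms": wind, "sunshine_h": sunshine, "precip_mm": precip,
    }, index=dates, columns=WEATHER_COLUMNS[1:])
    frame.index.name = "date"
    return DailyWeatherSeries(station=spec.station(), frame=frame)


def generate_fr_truth(weather: DailyWeatherSeries, a_true: float, b_true: float,
                      noise_sd: float, seed: int = 0,
                      params: ModelParams | None = None) -> ET0Series:
    """Planted-truth daily ET0: a_true + b_true * driver + N(0, noise_sd^2).

    Stands in for the Penman-Monteith standard in calibration-recovery
    tests; clamped at zero like every model output.
    """
    driver = fr_driver(weather, params)
    rng = np.random.default_rng(seed)
    noise = rng.normal(0.0, noise_sd, size=len(driver)) if noise_sd > 0 else 0.0
    values = np.maximum(a_true + b_true * driver.to_numpy() + noise, 0.0)
    return ET0Series(model="fr", scale="daily",
                     values=pd.Series(values, index=driver.index, name="et0_mm"))
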