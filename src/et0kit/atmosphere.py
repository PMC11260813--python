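"""Psychrometric and radiation quantities for daily ET0 computation.

All functions follow the FAO-56 daily chain and accept scalars or numpy
arrays (they broadcast).  Units are fixed: temperatures in degrees Celsius,
pressures in kPa, radiation in MJ m-2 day-1, wind in m s-1, day length and
sunshine in hours.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: solar constant, MJ m-2 min-1
SOLAR_CONSTANT = 0.0820
#: Stefan-Boltzmann constant, MJ K-4 m-2 day-1
STEFAN_BOLTZMANN = 4.903e-9
#: grass reference albedo
ALBEDO = 0.23
#: latent-heat conversion, mm of evaporated water per MJ m-2
MM_PER_MJ = 0.408
#: Angstrom-Prescott coefficients for Rs = (AS + BS * n/N) * Ra
ANGSTROM_AS = 0.25
ANGSTROM_BS = 0.50


@dataclass(frozen=True)
class AtmosphericState:
    """Per-day derived quantities consumed by the ET0 models."""

    es: np.ndarray       # saturation vapour pressure, kPa
    ea: np.ndarray       # actual vapour pressure, kPa
    delta: np.ndarray    # slope of the vapour-pressure curve, kPa degC-1
    gamma: np.ndarray    # psychrometric constant, kPa degC-1
    ra: np.ndarray       # extraterrestrial radiation, MJ m-2 day-1
    daylength: np.ndarray  # astronomical day length, h
    rs: np.ndarray       # incoming shortwave radiation, MJ m-2 day-1
    rn: np.ndarray       # net radiation, MJ m-2 day-1
    g: np.ndarray        # soil heat flux (0 at daily scale), MJ m-2 day-1
    u2: np.ndarray       # wind speed at 2 m, m s-1


def saturation_vapour_pressure(t):
    """Saturation vapour pressure es(T) in kPa at air temperature ``t`` (degC)."""
    t = np.asarray(t, dtype=float)
    if np.any(t <= -100.0):
        raise ValueError("temperature below physical range (<= -100 degC)")
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def daily_saturation_vapour_pressure(tmax, tmin):
    """Daily es as the mean of es(tmax) and es(tmin)."""
    return 0.5 * (saturation_vapour_pressure(tmax) + saturation_vapour_pressure(tmin))


def slope_vapour_pressure_curve(t):
    """Slope of the saturation vapour-pressure curve at ``t`` (kPa degC-1)."""
    t = np.asarray(t, dtype=float)
    return 4098.0 * saturation_vapour_pressure(t) / (t + 237.3) ** 2


def pressure_from_elevation(z):
    """Standard-atmosphere barometric pressure (kPa) at elevation ``z`` (m)."""
    z = np.asarray(z, dtype=float)
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def psychrometric_constant(pressure):
    """Psychrometric constant gamma = 0.665e-3 * P (kPa degC-1)."""
    pressure = np.asarray(pressure, dtype=float)
    if np.any(pressure <= 0):
        raise ValueError("barometric pressure must be positive")
    return 0.665e-3 * pressure


def actual_vapour_pressure(tmax, tmin, rh_mean=None, vapour_pressure=None):
    """Actual vapour pressure ea (kPa).

    Measured vapour pressure takes precedence; otherwise ea is derived from
    mean relative humidity as (RH/100) * es_day.  The result is clamped to
    [0, es_day].  Array inputs may mix the two sources element-wise (NaN
    marks a missing value).
    """
    es_day = daily_saturation_vapour_pressure(tmax, tmin)
    vp = np.full_like(es_day, np.nan) if vapour_pressure is None else \
        np.asarray(vapour_pressure, dtype=float)
    rh = np.full_like(es_day, np.nan) if rh_mean is None else \
        np.asarray(rh_mean, dtype=float)
    vp, rh, es_day = np.broadcast_arrays(vp, rh, es_day)
    from_rh = rh / 100.0 * es_day
    ea = np.where(np.isnan(vp), from_rh, vp)
    if np.any(np.isnan(ea)):
        raise ValueError("both vapour pressure and relative humidity missing")
    return np.clip(ea, 0.0, es_day)


def extraterrestrial_radiation(latitude, day_of_year):
    """Extraterrestrial radiation Ra (MJ m-2 day-1) and day length N (h).

    Standard daily solar geometry: inverse relative Earth-Sun distance,
    solar declination, and sunset hour angle.  The hour-angle argument is
    clamped so polar latitudes return 0 <= N <= 24 instead of NaN.
    """
    lat = np.deg2rad(np.asarray(latitude, dtype=float))
    j = np.asarray(day_of_year, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * j / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * j / 365.0 - 1.39)
    cos_ws = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    ra = np.maximum(ra, 0.0)
    daylength = 24.0 * ws / np.pi
    return ra, daylength


def shortwave_from_sunshine(ra, n, daylength):
    """Incoming shortwave Rs from sunshine duration (Angstrom-Prescott).

    ``n`` is clipped into [0, N]; a zero day length forces Rs = AS * Ra
    (polar-night guard).
    """
    ra = np.asarray(ra, dtype=float)
    n = np.asarray(n, dtype=float)
    daylength = np.asarray(daylength, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(daylength > 0, np.clip(n, 0.0, daylength) / np.where(daylength > 0, daylength, 1.0), 0.0)
    return (ANGSTROM_AS + ANGSTROM_BS * frac) * ra


def net_radiation(rs, ra, ea, tmax, tmin, elevation):
    """Daily net radiation Rn = Rns - Rnl (MJ m-2 day-1).

    Net shortwave uses the fixed grass albedo; net longwave follows the
    Stefan-Boltzmann law with humidity and cloudiness corrections, with the
    clear-sky ratio Rs/Rso clamped to [0.3, 1.0] and Rnl floored at 0.
    """
    rs = np.asarray(rs, dtype=float)
    ra = np.asarray(ra, dtype=float)
    ea = np.asarray(ea, dtype=float)
    tmax_k = np.asarray(tmax, dtype=float) + 273.16
    tmin_k = np.asarray(tmin, dtype=float) + 273.16
    rns = (1.0 - ALBEDO) * rs
    rso = (0.75 + 2e-5 * np.asarray(elevation, dtype=float)) * ra
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rso > 0, rs / np.where(rso > 0, rso, 1.0), 0.3)
    ratio = np.clip(ratio, 0.3, 1.0)
    rnl = (
        STEFAN_BOLTZMANN
        * 0.5 * (tmax_k ** 4 + tmin_k ** 4)
        * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0)))
        * (1.35 * ratio - 0.35)
    )
    rnl = np.maximum(rnl, 0.0)
    return rns - rnl


def wind_at_2m(u, z):
    """Wind speed at 2 m from a measurement at height ``z`` (log profile)."""
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0.08):
        raise ValueError("anemometer height must exceed 0.08 m")
    u = np.asarray(u, dtype=float)
    return np.where(z == 2.0, u, u * 4.87 / np.log(67.8 * z - 5.42))


def atmospheric_state(series, params=None) -> AtmosphericState:
    """Evaluate the full daily chain for a weather series.

    ``series`` is a :class:`et0kit.weather_io.DailyWeatherSeries`; returns
    one entry per record.  Measured barometric pressure is used where
    present, the standard-atmosphere value elsewhere.
    """
    frame = series.frame
    meta = series.station
    doy = frame.index.dayofyear.to_numpy()
    tmax = frame["tmax_c"].to_numpy()
    tmin = frame["tmin_c"].to_numpy()

    ra, daylength = extraterrestrial_radiation(meta.latitude, doy)
    rs = shortwave_from_sunshine(ra, frame["sunshine_h"].to_numpy(), daylength)
    es = daily_saturation_vapour_pressure(tmax, tmin)
    ea = actual_vapour_pressure(
        tmax, tmin,
        rh_mean=frame["rh_pct"].to_numpy(),
        vapour_pressure=frame["vp_kpa"].to_numpy(),
    )
    pressure = frame["pressure_kpa"].to_numpy()
    pressure = np.where(np.isnan(pressure), pressure_from_elevation(meta.elevation), pressure)
    gamma = psychrometric_constant(pressure)
    delta = slope_vapour_pressure_curve(frame["tmean_c"].to_numpy())
    rn = net_radiation(rs, ra, ea, tmax, tmin, meta.elevation)
    u2 = wind_at_2m(frame["wind_ms"].to_numpy(), meta.anemometer_height)
    g = np.zeros_like(rn)
    return AtmosphericState(es=es, ea=ea, delta=delta, gamma=gamma, ra=ra,
                            daylength=daylength, rs=rs, rn=rn, g=g, u2=u2)
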