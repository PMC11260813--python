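"""Daily reference-evapotranspiration models.

Five formulations sharing one atmospheric backing chain:

* ``pm`` — Penman-Monteith combination equation (the benchmark).
* ``pt`` — Priestley-Taylor radiation model (alpha = 1.26).
* ``ha`` — Hargreaves-Samani temperature/extraterrestrial-radiation model.
* ``mc`` — McCloud exponential temperature model.
* ``fr`` — FAO-24 Radiation (Makkink-family) model, the calibration target.

Radiation-driven models multiply radiation terms by 0.408 mm per MJ m-2 so
output is in mm day-1; set ``radiation_in_mm=False`` on ``ModelParams`` to
evaluate the literal forms with radiation in MJ m-2 day-1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .atmosphere import MM_PER_MJ, AtmosphericState, atmospheric_state
from .weather_io import DailyWeatherSeries, StationMeta

MODEL_LABELS = ("pm", "pt", "ha", "mc", "fr")
SCALES = ("daily", "dekad", "monthly")


@dataclass(frozen=True)
class ModelParams:
    """Empirical coefficients of the non-benchmark models."""

    pt_alpha: float = 1.26     # Priestley-Taylor alpha
    ha_c0: float = 0.0023      # Hargreaves conversion factor
    mc_k: float = 0.254        # McCloud scale, mm day-1
    mc_w: float = 1.07         # McCloud base
    fr_a: float = 0.18         # FAO-24 Radiation intercept, mm day-1
    fr_b: float = 0.50         # FAO-24 Radiation slope
    radiation_in_mm: bool = True

    def __post_init__(self):
        for name in ("pt_alpha", "ha_c0", "mc_k", "mc_w", "fr_a", "fr_b"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")


@dataclass
class ET0Series:
    """Dated ET0 values for one model at one aggregation scale."""

    model: str
    scale: str
    values: pd.Series = field(repr=False)  # indexed by period start date, mm

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")

    def __len__(self) -> int:
        return len(self.values)


def _radiation_factor(params: ModelParams) -> float:
    return MM_PER_MJ if params.radiation_in_mm else 1.0


def et0_penman_monteith(state: AtmosphericState, tmean) -> np.ndarray:
    """Penman-Monteith daily ET0 (mm day-1), negatives clamped to 0."""
    tmean = np.asarray(tmean, dtype=float)
    num = (
        0.408 * state.delta * (state.rn - state.g)
        + state.gamma * (900.0 / (tmean + 273.0)) * state.u2 * (state.es - state.ea)
    )
    den = state.delta + state.gamma * (1.0 + 0.34 * state.u2)
    return np.maximum(num / den, 0.0)


def et0_priestley_taylor(state: AtmosphericState, params: ModelParams) -> np.ndarray:
    """Priestley-Taylor ET0: alpha * Delta/(Delta+gamma) * (Rn - G)."""
    frac = state.delta / (state.delta + state.gamma)
    et0 = params.pt_alpha * frac * _radiation_factor(params) * (state.rn - state.g)
    return np.maximum(et0, 0.0)


def et0_hargreaves(state: AtmosphericState, tmean, tmax, tmin,
                   params: ModelParams) -> np.ndarray:
    """Hargreaves-Samani ET0 from temperature range and Ra."""
    tmax = np.asarray(tmax, dtype=float)
    tmin = np.asarray(tmin, dtype=float)
    if np.any(tmax < tmin):
        raise ValueError("tmax < tmin")
    ra = _radiation_factor(params) * state.ra
    et0 = params.ha_c0 * ra * (np.asarray(tmean, dtype=float) + 17.8) * np.sqrt(tmax - tmin)
    return np.maximum(et0, 0.0)


def et0_mccloud(tmean, params: ModelParams) -> np.ndarray:
    """McCloud ET0: K * W^(1.8 * Tmean)."""
    return params.mc_k * params.mc_w ** (1.8 * np.asarray(tmean, dtype=float))


def et0_fao24_radiation(state: AtmosphericState, params: ModelParams) -> np.ndarray:
    """FAO-24 Radiation ET0: a + b * Delta/(Delta+gamma) * Rs."""
    et0 = params.fr_a + params.fr_b * fr_driver_from_state(state, params)
    return np.maximum(et0, 0.0)


def fr_driver_from_state(state: AtmosphericState, params: ModelParams) -> np.ndarray:
    """The radiation driver Delta/(Delta+gamma) * Rs that the FR slope scales."""
    return state.delta / (state.delta + state.gamma) * _radiation_factor(params) * state.rs


def fr_driver(series: DailyWeatherSeries, params: Optional[ModelParams] = None) -> pd.Series:
    """Daily FR driver (mm day-1 equivalent) for a weather series."""
    params = params or ModelParams()
    state = atmospheric_state(series)
    return pd.Series(fr_driver_from_state(state, params), index=series.frame.index)


def compute_series(series: DailyWeatherSeries, model: str,
                   params: Optional[ModelParams] = None) -> ET0Series:
    """Daily ET0 for every record of ``series`` under one model."""
    model = model.lower()
    if model not in MODEL_LABELS:
        raise ValueError(f"unknown model {model!r}; expected one of {MODEL_LABELS}")
    params = params or ModelParams()
    frame = series.frame
    if frame.empty:
        return ET0Series(model=model, scale="daily",
                         values=pd.Series(dtype=float, index=frame.index))
    state = atmospheric_state(series)
    tmean = frame["tmean_c"].to_numpy()
    if model == "pm":
        et0 = et0_penman_monteith(state, tmean)
    elif model == "pt":
        et0 = et0_priestley_taylor(state, params)
    elif model == "ha":
        et0 = et0_hargreaves(state, tmean, frame["tmax_c"].to_numpy(),
                             frame["tmin_c"].to_numpy(), params)
    elif model == "mc":
        et0 = et0_mccloud(tmean, params)
    else:
        et0 = et0_fao24_radiation(state, params)
    return ET0Series(model=model, scale="daily",
                     values=pd.Series(et0, index=frame.index, name="et0_mm"))


def write_et0_table(series: ET0Series, path) -> None:
    """Write ``period,model,scale,et0_mm`` CSV."""
    out = pd.DataFrame({
        "period": series.values.index.strftime("%Y-%m-%d"),
        "model": series.model,
        "scale": series.scale,
        "et0_mm": series.values.to_numpy(),
    })
    out.to_csv(path, index=False, float_format="%.6f")


def read_et0_table(path) -> ET0Series:
    """Read a CSV written by :func:`write_et0_table`."""
    frame = pd.read_csv(path, parse_dates=["period"])
    if frame.empty:
        raise ValueError(f"empty ET0 table {path}")
    models = frame["model"].unique()
    scales = frame["scale"].unique()
    if len(models) != 1 or len(scales) != 1:
        raise ValueError("ET0 table must hold a single (model, scale)")
    values = pd.Series(frame["et0_mm"].to_numpy(),
                       index=pd.DatetimeIndex(frame["period"]), name="et0_mm")
    return ET0Series(model=models[0], scale=scales[0], values=values)
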