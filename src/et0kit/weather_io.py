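"""Reading, validating and writing daily station weather tables.

Canonical units are fixed at this boundary: temperatures in degC, vapour
and barometric pressure in kPa, wind in m s-1, sunshine in hours, rainfall
in mm, relative humidity in percent.  Downstream modules never convert
units on input.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

#: canonical column order of the weather CSV
WEATHER_COLUMNS = [
    "date", "tmax_c", "tmin_c", "tmean_c", "rh_pct", "vp_kpa",
    "pressure_kpa", "wind_ms", "sunshine_h", "precip_mm",
]

_NUMERIC_COLUMNS = WEATHER_COLUMNS[1:]
_OPTIONAL_COLUMNS = {"rh_pct", "vp_kpa", "pressure_kpa"}
_MISSING_TOKENS = ["", "NA", "NaN", "nan", "null"]


class WeatherValidationError(ValueError):
    """Raised when a weather table violates the series invariants.

    ``row_errors`` lists per-row diagnostics as (date-or-index, message).
    """

    def __init__(self, message: str, row_errors: Optional[Sequence[tuple]] = None):
        self.row_errors = list(row_errors or [])
        detail = "; ".join(f"{key}: {msg}" for key, msg in self.row_errors)
        super().__init__(message if not detail else f"{message}: {detail}")


@dataclass(frozen=True)
class StationMeta:
    """Station metadata driving radiation geometry and unit conversions."""

    station_id: str
    latitude: float
    elevation: float
    anemometer_height: float = 10.0

    def __post_init__(self):
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if self.elevation < -430.0:
            raise ValueError(f"elevation {self.elevation} below -430 m")
        if self.anemometer_height <= 0:
            raise ValueError("anemometer height must be positive")

    @classmethod
    def from_file(cls, path) -> "StationMeta":
        """Load metadata from a JSON or YAML config block."""
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(
            station_id=str(data["station_id"]),
            latitude=float(data["latitude_deg"]),
            elevation=float(data["elevation_m"]),
            anemometer_height=float(data.get("anemometer_height_m", 10.0)),
        )

    def to_file(self, path) -> None:
        payload = {
            "station_id": self.station_id,
            "latitude_deg": self.latitude,
            "elevation_m": self.elevation,
            "anemometer_height_m": self.anemometer_height,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")


@dataclass(frozen=True)
class DailyWeatherRecord:
    """One station-day of measured meteorology."""

    date: _dt.date
    tmax: float
    tmin: float
    tmean: float
    wind_speed: float
    sunshine_hours: float
    precip: float
    rh_mean: Optional[float] = None
    vapour_pressure: Optional[float] = None
    pressure: Optional[float] = None


@dataclass
class DailyWeatherSeries:
    """Validated daily weather for one station, ordered by date.

    Internally backed by a DataFrame indexed by date (missing values as
    NaN) so the atmosphere chain can run vectorised; ``records`` exposes
    the row-level dataclass view.
    """

    station: StationMeta
    frame: pd.DataFrame = field(repr=False)

    def __post_init__(self):
        self.frame = _validate_frame(self.frame)

    def __len__(self) -> int:
        return len(self.frame)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DailyWeatherSeries):
            return NotImplemented
        if self.station != other.station:
            return False
        try:
            pd.testing.assert_frame_equal(self.frame, other.frame, atol=1e-9,
                                          rtol=0, check_freq=False)
        except AssertionError:
            return False
        return True

    @property
    def records(self) -> Iterator[DailyWeatherRecord]:
        for date, row in self.frame.iterrows():
            yield DailyWeatherRecord(
                date=date.date(),
                tmax=row["tmax_c"], tmin=row["tmin_c"], tmean=row["tmean_c"],
                wind_speed=row["wind_ms"], sunshine_hours=row["sunshine_h"],
                precip=row["precip_mm"],
                rh_mean=None if np.isnan(row["rh_pct"]) else row["rh_pct"],
                vapour_pressure=None if np.isnan(row["vp_kpa"]) else row["vp_kpa"],
                pressure=None if np.isnan(row["pressure_kpa"]) else row["pressure_kpa"],
            )

    @classmethod
    def from_records(cls, station: StationMeta,
                     records: Sequence[DailyWeatherRecord]) -> "DailyWeatherSeries":
        rows = [
            {
                "date": pd.Timestamp(r.date),
                "tmax_c": r.tmax, "tmin_c": r.tmin, "tmean_c": r.tmean,
                "rh_pct": np.nan if r.rh_mean is None else r.rh_mean,
                "vp_kpa": np.nan if r.vapour_pressure is None else r.vapour_pressure,
                "pressure_kpa": np.nan if r.pressure is None else r.pressure,
                "wind_ms": r.wind_speed, "sunshine_h": r.sunshine_hours,
                "precip_mm": r.precip,
            }
            for r in records
        ]
        frame = pd.DataFrame(rows, columns=WEATHER_COLUMNS)
        if rows:
            frame = frame.set_index("date")
        else:
            frame = frame.set_index(pd.DatetimeIndex([], name="date"))
        return cls(station=station, frame=frame)

    def annual_precip(self) -> pd.Series:
        """Annual precipitation totals (mm) indexed by calendar year."""
        return self.frame["precip_mm"].groupby(self.frame.index.year).sum()

    def window(self, start_year: int, end_year: int) -> "DailyWeatherSeries":
        """Sub-series covering calendar years [start_year, end_year]."""
        mask = (self.frame.index.year >= start_year) & (self.frame.index.year <= end_year)
        sub = self.frame.loc[mask]
        if sub.empty:
            raise WeatherValidationError(
                f"no weather records in window {start_year}-{end_year}")
        return DailyWeatherSeries(station=self.station, frame=sub.copy())


def _validate_frame(frame: pd.DataFrame) -> pd.DataFrame:
    if not isinstance(frame.index, pd.DatetimeIndex):
        raise WeatherValidationError("weather frame must be indexed by date")
    missing = [c for c in WEATHER_COLUMNS[1:] if c not in frame.columns]
    if missing:
        raise WeatherValidationError(f"missing columns {missing}")
    extra = [c for c in frame.columns if c not in WEATHER_COLUMNS]
    if extra:
        raise WeatherValidationError(f"unknown columns {extra}")
    frame = frame[WEATHER_COLUMNS[1:]].astype(float).sort_index()

    if frame.index.has_duplicates:
        dups = frame.index[frame.index.duplicated()].unique()
        raise WeatherValidationError(
            "duplicate dates", [(d.date().isoformat(), "duplicated") for d in dups])

    errors = []
    for date, row in frame.iterrows():
        key = date.date().isoformat()
        if not (row["tmin_c"] <= row["tmean_c"] <= row["tmax_c"]):
            errors.append((key, f"requires tmin <= tmean <= tmax, got "
                                f"{row['tmin_c']}/{row['tmean_c']}/{row['tmax_c']}"))
        if np.isnan(row["rh_pct"]) and np.isnan(row["vp_kpa"]):
            errors.append((key, "needs rh_pct or vp_kpa"))
        if not np.isnan(row["rh_pct"]) and not (0.0 < row["rh_pct"] <= 100.0):
            errors.append((key, f"rh_pct {row['rh_pct']} outside (0, 100]"))
        for col in ("wind_ms", "sunshine_h", "precip_mm"):
            if np.isnan(row[col]) or row[col] < 0:
                errors.append((key, f"{col} must be >= 0, got {row[col]}"))
        if not np.isnan(row["vp_kpa"]) and row["vp_kpa"] < 0:
            errors.append((key, f"vp_kpa must be >= 0, got {row['vp_kpa']}"))
        for col in ("tmax_c", "tmin_c", "tmean_c"):
            if np.isnan(row[col]):
                errors.append((key, f"{col} missing"))
    if errors:
        raise WeatherValidationError("invalid weather rows", errors)
    return frame


def read_weather_table(path, station: StationMeta) -> DailyWeatherSeries:
    """Read a delimited weather table into a validated series.

    Unknown columns and empty files are hard errors; rows violating the
    record invariants raise :class:`WeatherValidationError` with the
    offending dates.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, na_values=_MISSING_TOKENS, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise WeatherValidationError(f"empty weather file {path}") from None
    if raw.empty:
        raise WeatherValidationError(f"weather file {path} has no data rows")
    if "date" not in raw.columns:
        raise WeatherValidationError("weather table must have a 'date' column")
    frame = raw.assign(date=pd.to_datetime(raw["date"])).set_index("date")
    return DailyWeatherSeries(station=station, frame=frame)


def write_weather_table(series: DailyWeatherSeries, path) -> None:
    """Write the canonical CSV: fixed column order, ISO dates.

    Values are written with 12 significant digits so read(write(s)) == s
    within 1e-9.
    """
    out = series.frame.copy()
    out.insert(0, "date", out.index.strftime("%Y-%m-%d"))
    out.to_csv(Path(path), index=False, float_format="%.12g", na_rep="NA")
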