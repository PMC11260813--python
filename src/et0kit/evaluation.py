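"""Multi-scale aggregation and model-agreement statistics.

Daily ET0 is summed into dekads (days 1-10, 11-20, 21-end of month) and
calendar months.  Agreement between a simulated series P and the
Penman-Monteith standard Q is scored with four statistics:

* R2   — squared Pearson correlation,
* RMSE — sqrt(mean((P-Q)^2)),
* MAE  — mean(|P-Q|),
* WI   — 1 - sum((Q-P)^2) / sum((|Q-c| + |P-c|)^2),

where the WI centring constant c is the simulated mean (``wi_convention=
"simulated"``, the default, matching the source formulation) or the
standard mean (``"willmott"``, the conventional index of agreement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from .et0_models import ET0Series, ModelParams, compute_series
from .weather_io import DailyWeatherSeries

WI_CONVENTIONS = ("simulated", "willmott")


@dataclass(frozen=True)
class MetricReport:
    """Agreement statistics for one (model, station, year, scale) cell."""

    model: str
    station: str
    year: int
    scale: str
    r2: Optional[float]
    rmse: float
    mae: float
    wi: float
    n: int


@dataclass(frozen=True)
class ImprovementSummary:
    """Before/after percent change of one metric at one scale.

    ``mean_per_row_pct_change`` averages the per-row percent changes;
    ``pct_change_of_means`` compares the row-means.  Error metrics count
    reductions as positive, WI counts increases as positive.
    """

    scale: str
    metric: str
    mean_per_row_pct_change: float
    pct_change_of_means: float
    n_rows: int


def dekad_index(dates: pd.DatetimeIndex) -> pd.PeriodIndex:
    """Label each date with its dekad start (1st, 11th, 21st of the month)."""
    start_day = np.minimum((dates.day - 1) // 10, 2) * 10 + 1
    return pd.DatetimeIndex(
        [d.replace(day=s) for d, s in zip(dates, start_day)])


def aggregate(series: ET0Series, scale: str) -> ET0Series:
    """Sum a daily series into dekad or monthly totals.

    Periods with incomplete daily coverage are dropped (flagged missing),
    so partial months at the edges of a record never bias totals.
    """
    if series.scale != "daily":
        raise ValueError("aggregation starts from a daily series")
    if scale == "daily":
        return series
    if scale not in ("dekad", "monthly"):
        raise ValueError(f"unknown scale {scale!r}")
    values = series.values
    if values.empty:
        return ET0Series(model=series.model, scale=scale,
                         values=pd.Series(dtype=float, index=values.index))
    dates = values.index
    keys = dekad_index(dates)
    month_len = keys.days_in_month
    expected = np.where(keys.day == 21, month_len - 20, 10)
    frame = pd.DataFrame({"key": keys, "value": values.to_numpy(),
                          "expected": expected})
    grouped = frame.groupby("key").agg(total=("value", "sum"),
                                       count=("value", "size"),
                                       expected=("expected", "first"))
    complete = grouped[grouped["count"] == grouped["expected"]]
    dekads = pd.Series(complete["total"].to_numpy(),
                       index=pd.DatetimeIndex(complete.index), name="et0_mm")
    if scale == "dekad":
        return ET0Series(model=series.model, scale=scale, values=dekads)
    # monthly totals as sums of complete dekads: a month needs all three,
    # and monthly == sum-of-dekads holds exactly (identical float order)
    months = dekads.groupby(dekads.index.to_period("M"))
    monthly = months.sum()[months.size() == 3]
    return ET0Series(model=series.model, scale=scale,
                     values=pd.Series(monthly.to_numpy(),
                                      index=monthly.index.to_timestamp(),
                                      name="et0_mm"))


def agreement_metrics(simulated: ET0Series, standard: ET0Series,
                      station: str = "", year: int = 0,
                      wi_convention: str = "simulated") -> MetricReport:
    """Score a simulated series against the standard over shared periods."""
    if wi_convention not in WI_CONVENTIONS:
        raise ValueError(f"unknown WI convention {wi_convention!r}")
    if simulated.scale != standard.scale:
        raise ValueError("series scales differ")
    joined = pd.concat([simulated.values.rename("p"),
                        standard.values.rename("q")], axis=1, join="inner")
    if len(joined) < 2:
        raise ValueError("need at least 2 aligned periods")
    p = joined["p"].to_numpy()
    q = joined["q"].to_numpy()
    diff = p - q
    rmse = float(np.sqrt(np.mean(diff ** 2)))
    mae = float(np.mean(np.abs(diff)))
    if np.std(p) == 0 or np.std(q) == 0:
        r2 = None
    else:
        r2 = float(np.corrcoef(p, q)[0, 1] ** 2)
    centre = p.mean() if wi_convention == "simulated" else q.mean()
    denom = np.sum((np.abs(q - centre) + np.abs(p - centre)) ** 2)
    wi = 1.0 if denom == 0 else float(1.0 - np.sum(diff ** 2) / denom)
    wi = min(1.0, max(0.0, wi))  # bounds hold exactly; trim float noise
    return MetricReport(model=simulated.model, station=station, year=year,
                        scale=simulated.scale, r2=r2, rmse=rmse, mae=mae,
                        wi=wi, n=len(joined))


def comparison_table(weather: DailyWeatherSeries, years: Sequence[int],
                     models: Sequence[str] = ("pt", "ha", "mc", "fr"),
                     scales: Sequence[str] = ("daily", "dekad", "monthly"),
                     params: Optional[ModelParams] = None,
                     wi_convention: str = "simulated") -> List[MetricReport]:
    """One MetricReport per (model, year, scale), PM as the standard."""
    reports = []
    for year in years:
        annual = weather.window(year, year)
        daily = {m: compute_series(annual, m, params)
                 for m in set(models) | {"pm"}}
        for scale in scales:
            std = aggregate(daily["pm"], scale)
            for model in models:
                reports.append(agreement_metrics(
                    aggregate(daily[model], scale), std,
                    station=weather.station.station_id, year=year,
                    wi_convention=wi_convention))
    return reports


def summarize_improvement(before: Sequence[MetricReport],
                          after: Sequence[MetricReport],
                          scale: str, metric: str) -> ImprovementSummary:
    """Percent improvement of one metric between row-aligned report lists."""
    rows_b = [r for r in before if r.scale == scale]
    rows_a = [r for r in after if r.scale == scale]
    if len(rows_b) != len(rows_a) or not rows_b:
        raise ValueError("before/after reports are not row-aligned")
    for rb, ra in zip(rows_b, rows_a):
        if (rb.station, rb.year) != (ra.station, ra.year):
            raise ValueError(
                f"row mismatch: {(rb.station, rb.year)} vs {(ra.station, ra.year)}")
    b = np.array([getattr(r, metric) for r in rows_b], dtype=float)
    a = np.array([getattr(r, metric) for r in rows_a], dtype=float)
    sign = 1.0 if metric in ("rmse", "mae") else -1.0  # reductions positive for errors
    per_row = float(np.mean(sign * 100.0 * (b - a) / b))
    of_means = float(sign * 100.0 * (b.mean() - a.mean()) / b.mean())
    return ImprovementSummary(scale=scale, metric=metric,
                              mean_per_row_pct_change=per_row,
                              pct_change_of_means=of_means, n_rows=len(b))


def reports_to_frame(reports: Sequence[MetricReport]) -> pd.DataFrame:
    """Long-format metric table ``station,year,scale,model,r2,rmse,mae,wi``."""
    return pd.DataFrame([
        {"station": r.station, "year": r.year, "scale": r.scale,
         "model": r.model,
         "r2": math.nan if r.r2 is None else r.r2,
         "rmse": r.rmse, "mae": r.mae, "wi": r.wi, "n": r.n}
        for r in reports
    ])


def frame_to_reports(frame: pd.DataFrame) -> List[MetricReport]:
    """Inverse of :func:`reports_to_frame` (n optional, defaults to 0)."""
    return [
        MetricReport(model=str(row["model"]), station=str(row["station"]),
                     year=int(row["year"]), scale=str(row["scale"]),
                     r2=None if pd.isna(row["r2"]) else float(row["r2"]),
                     rmse=float(row["rmse"]), mae=float(row["mae"]),
                     wi=float(row["wi"]), n=int(row.get("n", 0)))
        for _, row in frame.iterrows()
    ]
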