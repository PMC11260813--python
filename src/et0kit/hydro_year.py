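"""Typical-hydrological-year selection from annual precipitation.

Annual totals are ranked in descending order, empirical cumulative
frequencies computed as p = m/(N+1), a Pearson Type III distribution fitted
by the method of moments, and for each design exceedance probability
(25% high flow, 50% median, 75% low flow, 90% special dry) the observed
year whose total is nearest the design rainfall is selected.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

#: design exceedance probabilities and their conventional labels
DESIGN_LEVELS: Mapping[float, str] = {
    0.25: "high flow",
    0.50: "median water",
    0.75: "low flow",
    0.90: "special dry",
}

_CS_FLOOR = 1e-6


@dataclass(frozen=True)
class PearsonIIIParams:
    """Moment parameterisation: mean, coefficient of variation, skew."""

    mean: float
    cv: float
    cs: float

    def __post_init__(self):
        if self.mean <= 0:
            raise ValueError("mean must be positive")
        if self.cv <= 0:
            raise ValueError("cv must be positive")


@dataclass(frozen=True)
class YearPick:
    design_mm: float
    year: int
    observed_mm: float
    label: str


#: mapping from exceedance probability to the selected year
HydroYearAssignment = Dict[float, YearPick]


def cumulative_frequency(m: int, n_years: int) -> float:
    """Empirical cumulative frequency p = m/(N+1) for descending rank m."""
    if not 1 <= m <= n_years:
        raise ValueError(f"rank {m} outside [1, {n_years}]")
    return m / (n_years + 1)


def ranked_frequencies(series: pd.Series) -> pd.DataFrame:
    """Annual totals ranked descending with their cumulative frequencies."""
    _check_series(series)
    ordered = series.sort_values(ascending=False, kind="stable")
    n = len(ordered)
    return pd.DataFrame({
        "year": ordered.index.to_numpy(),
        "precip_mm": ordered.to_numpy(),
        "rank": np.arange(1, n + 1),
        "p": [cumulative_frequency(m, n) for m in range(1, n + 1)],
    })


def fit_pearson3(series: pd.Series) -> PearsonIIIParams:
    """Method-of-moments Pearson III fit (bias-corrected skew).

    A skew of exactly zero is floored at 1e-6 in magnitude to keep the
    gamma reparameterisation non-degenerate.
    """
    _check_series(series)
    x = series.to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError("need at least 3 distinct annual totals")
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    if sd == 0:
        raise ValueError("zero variance in annual totals")
    cs = float(stats.skew(x, bias=False))
    if abs(cs) < _CS_FLOOR:
        cs = _CS_FLOOR if cs >= 0 else -_CS_FLOOR
    return PearsonIIIParams(mean=mean, cv=sd / mean, cs=cs)


def design_rainfall(params: PearsonIIIParams, p: float) -> float:
    """Design rainfall x_p with exceedance probability P(X >= x_p) = p.

    Uses the shifted-gamma reparameterisation alpha = 4/cs^2,
    beta = 2/(sd*cs), x0 = mean - 2*sd/cs; negative skew mirrors the
    distribution.  For |cs| below the floor this reduces to the normal
    quantile mean * (1 + cv * z_{1-p}).
    """
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability {p} outside (0, 1)")
    mean, cv, cs = params.mean, params.cv, params.cs
    sd = cv * mean
    if abs(cs) <= _CS_FLOOR:
        return mean + sd * stats.norm.ppf(1.0 - p)
    alpha = 4.0 / cs ** 2
    scale = abs(sd * cs) / 2.0
    if cs > 0:
        x0 = mean - 2.0 * sd / cs
        return x0 + stats.gamma.ppf(1.0 - p, alpha, scale=scale)
    x0 = mean - 2.0 * sd / cs  # cs < 0: upper bound of support
    return x0 - stats.gamma.ppf(p, alpha, scale=scale)


def select_typical_years(series: pd.Series,
                         p_levels: Sequence[float] = tuple(DESIGN_LEVELS),
                         ) -> HydroYearAssignment:
    """Assign an observed year to each design exceedance probability.

    ``series`` maps calendar year -> annual precipitation (mm).  Ties on
    distance to the design value resolve to the earlier year.
    """
    params = fit_pearson3(series)
    assignment: HydroYearAssignment = {}
    for p in p_levels:
        design = design_rainfall(params, p)
        ordered = series.sort_index()
        dist = (ordered - design).abs()
        year = int(dist.idxmin())  # idxmin on sorted index -> earliest tie
        assignment[p] = YearPick(
            design_mm=float(design),
            year=year,
            observed_mm=float(ordered.loc[year]),
            label=DESIGN_LEVELS.get(p, f"p={p:g}"),
        )
    return assignment


def assignment_to_frame(assignment: HydroYearAssignment) -> pd.DataFrame:
    rows = [
        {"p": p, "label": pick.label, "design_mm": pick.design_mm,
         "year": pick.year, "observed_mm": pick.observed_mm}
        for p, pick in sorted(assignment.items())
    ]
    return pd.DataFrame(rows)


def read_annual_precip(path) -> pd.Series:
    """Read a ``year,precip_mm`` CSV into a year-indexed series."""
    frame = pd.read_csv(path)
    if not {"year", "precip_mm"} <= set(frame.columns):
        raise ValueError("annual precipitation CSV needs columns year,precip_mm")
    series = pd.Series(frame["precip_mm"].to_numpy(dtype=float),
                       index=frame["year"].to_numpy(dtype=int))
    _check_series(series)
    return series


def _check_series(series: pd.Series) -> None:
    if series.index.has_duplicates:
        raise ValueError("duplicate years in annual precipitation series")
    if (series < 0).any():
        raise ValueError("negative annual precipitation total")
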