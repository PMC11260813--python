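# et0kit

A toolkit for reference-crop evapotranspiration (ET₀) analysis from daily
station weather:

* **Five daily ET₀ models** sharing one FAO-56 atmospheric backing chain:
  Penman–Monteith (the benchmark), Priestley–Taylor, Hargreaves–Samani,
  McCloud, and FAO-24 Radiation.
* **Typical-hydrological-year selection** — annual rainfall ranked by
  empirical cumulative frequency p = m/(N+1), Pearson Type III fitted by
  the method of moments, and observed years matched to the design
  rainfall at exceedance probabilities 25/50/75/90 %.
* **Iterative Bayesian recalibration** of the FAO-24 Radiation
  coefficients (a, b) against Penman–Monteith standard values, using
  per-day implied coefficient samples and a variance-weighted
  posterior-mean update.
* **Multi-scale evaluation** — daily, dekad (days 1–10 / 11–20 / 21–end)
  and monthly aggregation with R², RMSE, MAE and Willmott's index.
* **Seeded synthetic weather** for a temperate continental monsoon
  station, so the whole pipeline is testable without external data.

## CLI

The `et0` command groups the pipeline stages:

```sh
et0 simulate --years 29 --seed 1 --out weather.csv          # synthetic station
et0 compute --model pm --weather weather.csv --station station.json --out pm.csv
et0 hydroyear --annual-precip annual.csv --out assignment.json
et0 calibrate --weather weather.csv --station station.json --out calib.json
et0 evaluate --standard pm.csv --candidate fr.csv --out metrics.csv
et0 summarize --before t_before.csv --after t_after.csv --out summary.json
et0 run --config run.yaml                                    # full pipeline
```

Station metadata is a JSON/YAML block
`{station_id, latitude_deg, elevation_m, anemometer_height_m}`; weather
tables are CSV with columns
`date,tmax_c,tmin_c,tmean_c,rh_pct,vp_kpa,pressure_kpa,wind_ms,sunshine_h,precip_mm`
(units °C, kPa, m s⁻¹, h, mm; `NA` marks missing values).

The `run` config (YAML) names the station and weather files, disjoint
training/validation year windows, output directory, and optional model /
calibration parameter overrides; it emits the hydrological-year
assignment, model-comparison metric tables, the calibration trace, the
before/after validation metrics, an improvement summary and a run log,
each stamped with a config hash for reproducibility.

## Layout

```
src/et0kit/
  weather_io.py         # station metadata, weather table I/O + validation
  atmosphere.py         # psychrometric & radiation chain (es, Δ, γ, Ra, Rs, Rn, u2)
  et0_models.py         # the five daily ET0 models
  hydro_year.py         # Pearson III frequency analysis, typical-year picks
  bayes_calibration.py  # iterative posterior-mean recalibration of (a, b)
  evaluation.py         # dekad/monthly aggregation, R²/RMSE/MAE/WI, summaries
  synthetic_weather.py  # seeded synthetic station weather + planted truths
  pipeline.py           # end-to-end orchestration from one config
  cli.py                # `et0` command group
data/                   # benchmark metric tables used by acceptance checks
tests/                  # unit + property + acceptance suites
scripts/acceptance.py   # acceptance report generator
```
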