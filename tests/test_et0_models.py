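import numpy as np
import pandas as pd
import pytest

from et0kit import (ClimateSpec, ModelParams, compute_series,
                    generate_station_weather)
from et0kit.atmosphere import AtmosphericState
from et0kit.et0_models import (et0_fao24_radiation, et0_hargreaves,
                               et0_mccloud, et0_penman_monteith,
                               et0_priestley_taylor, read_et0_table,
                               write_et0_table)
from et0kit.evaluation import aggregate

DEFAULTS = ModelParams()


def make_state(es=2.0, ea=1.0, delta=0.15, gamma=0.067, ra=30.0, daylength=12.0,
               rs=20.0, rn=10.0, g=0.0, u2=2.0):
    as_arr = {k: np.asarray(v, dtype=float) for k, v in locals().items()}
    return AtmosphericState(**as_arr)


class TestModelParams:
    def test_defaults_match_published_coefficients(self):
        assert (DEFAULTS.pt_alpha, DEFAULTS.ha_c0) == (1.26, 0.0023)
        assert (DEFAULTS.mc_k, DEFAULTS.mc_w) == (0.254, 1.07)
        assert (DEFAULTS.fr_a, DEFAULTS.fr_b) == (0.18, 0.50)

    def test_positivity_enforced(self):
        with pytest.raises(ValueError):
            ModelParams(pt_alpha=-1.0)


class TestPenmanMonteith:
    def test_zero_when_both_terms_vanish(self):
        state = make_state(rn=5.0, g=5.0, es=1.5, ea=1.5)
        assert et0_penman_monteith(state, 20.0) == 0.0

    def test_radiative_only_when_calm(self):
        state = make_state(u2=0.0)
        expected = 0.408 * 0.15 * 10.0 / (0.15 + 0.067)
        assert et0_penman_monteith(state, 20.0) == pytest.approx(expected)

    def test_tropical_day_pinned(self, ):
        # frozen from an independent step-by-step evaluation of the chain:
        # tmax=34.8, tmin=25.6, rh=70%, u10=2.3, n=8.5 h, lat=13.73 N,
        # z=2 m, mid-April
        from et0kit import atmosphere as atm
        ra, n_day = atm.extraterrestrial_radiation(13.73, 105)
        rs = atm.shortwave_from_sunshine(ra, 8.5, n_day)
        tmean = 0.5 * (34.8 + 25.6)
        state = AtmosphericState(
            es=atm.daily_saturation_vapour_pressure(34.8, 25.6),
            ea=atm.actual_vapour_pressure(34.8, 25.6, rh_mean=70.0),
            delta=atm.slope_vapour_pressure_curve(tmean),
            gamma=atm.psychrometric_constant(atm.pressure_from_elevation(2.0)),
            ra=ra, daylength=n_day, rs=rs,
            rn=atm.net_radiation(rs, ra,
                                 atm.actual_vapour_pressure(34.8, 25.6, rh_mean=70.0),
                                 34.8, 25.6, 2.0),
            g=np.float64(0.0), u2=atm.wind_at_2m(2.3, 10.0))
        assert et0_penman_monteith(state, tmean) == pytest.approx(5.4562, abs=1e-3)

    def test_negative_clamped(self):
        state = make_state(rn=-5.0, es=1.0, ea=1.0, u2=0.0)
        assert et0_penman_monteith(state, 5.0) == 0.0


class TestPriestleyTaylor:
    def test_zero_when_rn_equals_g(self):
        assert et0_priestley_taylor(make_state(rn=3.0, g=3.0), DEFAULTS) == 0.0

    def test_linear_in_available_energy(self):
        one = et0_priestley_taylor(make_state(rn=5.0), DEFAULTS)
        two = et0_priestley_taylor(make_state(rn=10.0), DEFAULTS)
        assert two == pytest.approx(2 * one)

    def test_hand_value(self):
        # Delta/(Delta+gamma) = 0.5, Rn - G = 10 MJ
        state = make_state(delta=0.067, gamma=0.067, rn=10.0)
        assert et0_priestley_taylor(state, DEFAULTS) == pytest.approx(2.5704)

    def test_literal_form_without_mm_conversion(self):
        state = make_state(delta=0.067, gamma=0.067, rn=10.0)
        literal = ModelParams(radiation_in_mm=False)
        assert et0_priestley_taylor(state, literal) == pytest.approx(1.26 * 0.5 * 10)


class TestHargreaves:
    def test_zero_range(self):
        assert et0_hargreaves(make_state(), 20.0, 25.0, 25.0, DEFAULTS) == 0.0

    def test_zero_offset_temperature(self):
        assert et0_hargreaves(make_state(), -17.8, -10.0, -25.0, DEFAULTS) == 0.0

    def test_hand_value(self):
        state = make_state(ra=30.0)
        et0 = et0_hargreaves(state, 20.0, 25.0, 15.0, DEFAULTS)
        assert et0 == pytest.approx(0.0023 * 0.408 * 30 * 37.8 * np.sqrt(10), rel=1e-9)
        assert et0 == pytest.approx(3.365, abs=1e-3)

    def test_inverted_range_raises(self):
        with pytest.raises(ValueError):
            et0_hargreaves(make_state(), 20.0, 15.0, 25.0, DEFAULTS)


class TestMcCloud:
    def test_at_zero_celsius(self):
        assert et0_mccloud(0.0, DEFAULTS) == pytest.approx(0.254)

    def test_at_10c(self):
        assert et0_mccloud(10.0, DEFAULTS) == pytest.approx(0.254 * 1.07 ** 18)
        assert et0_mccloud(10.0, DEFAULTS) == pytest.approx(0.8585, abs=1e-4)

    def test_strictly_increasing(self):
        t = np.linspace(-20.0, 40.0, 61)
        assert (np.diff(et0_mccloud(t, DEFAULTS)) > 0).all()


class TestFao24Radiation:
    def test_intercept_at_zero_radiation(self):
        assert et0_fao24_radiation(make_state(rs=0.0), DEFAULTS) == pytest.approx(0.18)

    def test_linear_in_radiation(self):
        state1 = make_state(delta=0.067, gamma=0.067, rs=10.0)
        state2 = make_state(delta=0.067, gamma=0.067, rs=20.0)
        slope = (et0_fao24_radiation(state2, DEFAULTS)
                 - et0_fao24_radiation(state1, DEFAULTS)) / 10.0
        assert slope == pytest.approx(0.5 * 0.5 * 0.408)

    def test_hand_value(self):
        # Delta/(Delta+gamma) = 0.7, Rs_mm = 10
        state = make_state(delta=0.7, gamma=0.3, rs=10.0 / 0.408)
        assert et0_fao24_radiation(state, DEFAULTS) == pytest.approx(0.18 + 0.5 * 7)


class TestComputeSeries:
    def test_mccloud_pointwise(self, one_year_weather):
        series = compute_series(one_year_weather, "mc")
        assert len(series) == 365
        tmean = one_year_weather.frame["tmean_c"].to_numpy()
        np.testing.assert_allclose(series.values.to_numpy(),
                                   0.254 * 1.07 ** (1.8 * tmean))

    def test_empty_series(self):
        from et0kit.weather_io import DailyWeatherSeries
        empty = DailyWeatherSeries.from_records(
            ClimateSpec(seed=0).station(), [])
        assert len(compute_series(empty, "pm")) == 0

    def test_constant_weather_pm_varies_with_solar_geometry_only(self):
        from et0kit.weather_io import WEATHER_COLUMNS, DailyWeatherSeries
        dates = pd.date_range("2005-06-01", periods=20, freq="D")
        frame = pd.DataFrame({
            "tmax_c": 28.0, "tmin_c": 16.0, "tmean_c": 22.0, "rh_pct": 60.0,
            "vp_kpa": np.nan, "pressure_kpa": np.nan, "wind_ms": 2.0,
            "sunshine_h": 8.0, "precip_mm": 0.0,
        }, index=dates, columns=WEATHER_COLUMNS[1:])
        series = DailyWeatherSeries(station=ClimateSpec(seed=0).station(),
                                    frame=frame)
        et0 = compute_series(series, "pm").values
        assert et0.std() < 0.05 * et0.mean()  # only Ra drift remains

    def test_unknown_model_rejected(self, one_year_weather):
        with pytest.raises(ValueError, match="unknown model"):
            compute_series(one_year_weather, "makkink")

    def test_deterministic(self, one_year_weather):
        a = compute_series(one_year_weather, "pm").values
        b = compute_series(one_year_weather, "pm").values
        assert (a == b).all()

    def test_all_nonnegative(self, one_year_weather):
        for model in ("pm", "pt", "ha", "mc", "fr"):
            assert (compute_series(one_year_weather, model).values >= 0).all()


class TestSeasonalityAndOrdering:
    def test_monthly_peak_in_june_or_july(self, one_year_weather):
        for model in ("pm", "pt", "ha", "mc", "fr"):
            monthly = aggregate(compute_series(one_year_weather, model), "monthly")
            assert monthly.values.idxmax().month in (6, 7), model

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_hargreaves_exceeds_pm_on_most_days(self, seed):
        # calm, humid continental setting: the aerodynamic term is small
        spec = ClimateSpec(seed=seed, diurnal_range_mean=13.0,
                           wind_mean=1.5, rh_mean=70.0)
        weather = generate_station_weather(spec, 1, start_year=2005)
        ha = compute_series(weather, "ha").values
        pm = compute_series(weather, "pm").values
        assert (ha > pm).mean() > 0.70


def test_et0_table_roundtrip(tmp_path, one_year_weather):
    series = compute_series(one_year_weather, "fr")
    path = tmp_path / "et0.csv"
    write_et0_table(series, path)
    back = read_et0_table(path)
    assert back.model == "fr" and back.scale == "daily"
    np.testing.assert_allclose(back.values.to_numpy(),
                               series.values.to_numpy(), atol=1e-6)
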