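from pathlib import Path

import pytest

from et0kit import ClimateSpec, generate_station_weather

DATA_DIR = Path(__file__).resolve().parents[1] / "data"


@pytest.fixture(scope="session")
def data_dir() -> Path:
    return DATA_DIR


@pytest.fixture(scope="session")
def one_year_weather():
    """One seeded synthetic calendar year of daily weather."""
    return generate_station_weather(ClimateSpec(seed=101), 1, start_year=2005)


@pytest.fixture(scope="session")
def multi_year_weather():
    """Ten seeded synthetic years (hydro-year and pipeline tests)."""
    return generate_station_weather(ClimateSpec(seed=202), 10, start_year=2001)
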