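import pytest

from utciclim import GeneratorConfig, StationMeta, generate_station_series
from utciclim.pipeline import prepare_station_frame


@pytest.fixture(scope="session")
def meta():
    return StationMeta("MIDLAT", latitude=40.0, longitude=116.0,
                       altitude=50.0, climate_zone="temperate")


@pytest.fixture(scope="session")
def series(meta):
    """Five years of synthetic weather at 40N, fixed seed."""
    return generate_station_series(meta, GeneratorConfig(years=5, seed=42))


@pytest.fixture(scope="session")
def frame(meta, series):
    """Series with derived columns (Re, S0, V, dT, elev ...)."""
    return prepare_station_frame(meta, series)
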