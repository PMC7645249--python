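import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from swiburden import (
    CountryDataset,
    CountryInputRecord,
    GlobalParams,
    generate_country_table,
    jena_fixture,
)
from swiburden.synthetic import SyntheticSpec

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_globals() -> GlobalParams:
    return GlobalParams()


@pytest.fixture
def jena():
    """Published single-hospital validation record and overrides."""
    record, overrides = jena_fixture()
    return record, GlobalParams(**overrides)


@pytest.fixture
def complete_record() -> CountryInputRecord:
    """A mid-sized country with all ten inputs observed."""
    return CountryInputRecord(
        country_id="DEMO",
        population=10_000_000,
        cabg_rate_per_100k=60.0,
        mean_los_days=12.0,
        icu_day_cost=1500.0,
        gw_day_cost=600.0,
        swi_incidence=0.039,
        surveillance_days=30.0,
        sswi_share=0.6,
        sswi_extra_los_days=4.0,
        dswi_extra_los_days=25.0,
    )


@pytest.fixture
def synth_complete() -> CountryDataset:
    """26 synthetic countries, no missing data."""
    return generate_country_table(
        SyntheticSpec(n_countries=26, missingness=0.0, seed=7)
    )


@pytest.fixture
def synth_missing() -> CountryDataset:
    """15 synthetic countries with per-field missingness."""
    return generate_country_table(
        SyntheticSpec(n_countries=15, missingness=0.25, seed=11)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
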