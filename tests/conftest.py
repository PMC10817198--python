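import pytest

from cherisk.io import CountryRecord
from cherisk.synth import SyntheticConfig, generate_countries

SMALL_ROSTER = {"LIC": 5, "LMIC": 5, "UMIC": 5, "HIC": 5}


@pytest.fixture(scope="session")
def synthetic_set():
    """Default-sized synthetic roster with the default observation noise."""
    return generate_countries(SyntheticConfig(seed=42))


@pytest.fixture(scope="session")
def noise_free_set():
    """Small noise-free roster: observed poverty stats equal the closed forms."""
    return generate_countries(
        SyntheticConfig(seed=7, n_per_group=SMALL_ROSTER, noise_sd=0.0)
    )


@pytest.fixture
def tiny_countries():
    """Three handmade valid records spanning income groups and regions."""
    return [
        CountryRecord(
            iso3="ZZA", name="Alpha", income_group="LIC", who_region="AFR",
            population=1e7, gini=0.45, hepc=600.0, gdp_pc=1000.0,
            oop_share=0.50, pov_headcount_190=0.4, pov_headcount_320=0.6,
            pov_gap_215=0.2, pct_urban=0.3, data_year=2020,
        ),
        CountryRecord(
            iso3="ZZB", name="Beta", income_group="UMIC", who_region="AMR",
            population=5e7, gini=0.40, hepc=5000.0, gdp_pc=9000.0,
            oop_share=0.30, pov_headcount_190=0.05, pov_headcount_320=0.12,
            pov_gap_215=0.02, pct_urban=0.7, data_year=2020,
        ),
        CountryRecord(
            iso3="ZZC", name="Gamma", income_group="HIC", who_region="EUR",
            population=2e7, gini=0.30, hepc=20000.0, gdp_pc=35000.0,
            oop_share=0.15, pov_headcount_190=0.001, pov_headcount_320=0.005,
            pov_gap_215=0.0005, pct_urban=0.9, data_year=2020,
        ),
    ]
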