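import pytest

from wwcea import bundled_life_table, default_parameters


@pytest.fixture(scope="session")
def base_params():
    return default_parameters()


@pytest.fixture(scope="session")
def life_table():
    return bundled_life_table()


@pytest.fixture()
def short_params(base_params):
    """Base-case parameters on a 2-year horizon for cheap cohort runs."""
    p = base_params.copy()
    p.settings.horizon_years = 2
    return p
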