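import pytest
from hypothesis import settings

import paddyval as pv
from paddyval import data as data_pkg

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def hani_config_path():
    return data_pkg.fixture_path(data_pkg.HANI_2020)


@pytest.fixture(scope="session")
def hani_config(hani_config_path):
    return pv.load_config(hani_config_path)


@pytest.fixture(scope="session")
def hani_valuation(hani_config):
    return pv.run_valuation(hani_config)


@pytest.fixture(scope="session")
def monoculture_valuation():
    return pv.load_printed_valuation(data_pkg.fixture_path(data_pkg.MONOCULTURE_2020))


@pytest.fixture(scope="session")
def hani_site(hani_config):
    return hani_config.site.to_domain()


def rel_err(got: float, want: float) -> float:
    return abs(got - want) / abs(want)
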