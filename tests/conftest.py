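import pytest

from cantrend import load_fixture, table1_inputs
from cantrend.synthetic import SyntheticConfig, generate


@pytest.fixture(scope="session")
def table1():
    return load_fixture("table1_2017")


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2_2018_2020")


@pytest.fixture(scope="session")
def table1_model_inputs(table1):
    return table1_inputs(table1)


@pytest.fixture(scope="session")
def zero_noise_run():
    """Exact proportional coupling: continuous index, no noise anywhere."""
    config = SyntheticConfig(
        n_regions=20,
        years=(2016, 2020),
        annual_trend=0.02,
        trend_sd=0.03,
        incidence_noise_sd=0.0,
        coupling_exponent=1.0,
        rsvi_noise_sd=0.0,
        integer_rescale=False,
        seed=7,
    )
    return config, generate(config)
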