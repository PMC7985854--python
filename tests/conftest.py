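import pytest

from cariesim import default_cost_schedule, load_table1
from cariesim.fixtures import build_table1_config


@pytest.fixture(scope="session")
def model():
    """Default packaged parameter set (attained-age hazard argument)."""
    return load_table1()


@pytest.fixture(scope="session")
def model_doubled_age():
    """Same coefficients evaluated with the doubled-age hazard argument."""
    cfg = build_table1_config()
    cfg["age_factor"] = 2.0
    return load_table1(cfg)


@pytest.fixture(scope="session")
def schedule():
    return default_cost_schedule()
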