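import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("default")


@pytest.fixture
def default_inputs():
    from trioxy.steady_budget import BudgetInputs
    return BudgetInputs()


@pytest.fixture
def taipei_table():
    """Synthetic Taipei-like station table (fixed seed)."""
    from trioxy.synthetic_data import StationConfig, generate_station
    return generate_station(StationConfig(n=200, seed=42))


@pytest.fixture
def four_site_suite():
    from trioxy.synthetic_data import generate_four_site_suite
    return generate_four_site_suite(seed=3)
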