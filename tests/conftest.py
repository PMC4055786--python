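import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from pmxsim.engine import DoseRegimen, SolverConfig

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def default_config():
    """RK4 over [-1, 100] at dt = 0.02 — the conventional starting setup."""
    return SolverConfig(start_time=-1.0, stop_time=100.0, method="rk4", dt=0.02)


@pytest.fixture
def single_oral_dose():
    return DoseRegimen(amount=100.0, first_time=0.0, interval=24.0,
                       n_doses=1, target="depot")


@pytest.fixture
def rng():
    return np.random.default_rng(20240528)
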