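import numpy as np
import pytest
from hypothesis import settings, HealthCheck

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from capnoflow.params import ModelParams
from capnoflow.grid import grid_from_params
from capnoflow.workbench import run_step_study


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def device_grid(params):
    """The 13-state device discretization (3 interior points/compartment)."""
    return grid_from_params(params)


@pytest.fixture(scope="session")
def step_study():
    """The capnia-step experiment at all three observation-noise levels.

    Run once per session: direct simulation of the 40 -> 50 mmHg step,
    noise injection, Kalman inversion and the metrics suite.
    """
    return run_step_study()
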