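import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from gapdyn.circuit import AxisGrid, simulate
from gapdyn.perturb import trajectory_profiles
from gapdyn.synth import (make_maternal_inputs, make_reference_circuit,
                          reference_initial_state)
from gapdyn.timeline import IlluminationScenario

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


@pytest.fixture(scope="session")
def grid():
    return AxisGrid()


@pytest.fixture(scope="session")
def maternal(grid):
    return make_maternal_inputs(grid)


@pytest.fixture(scope="session")
def reference_params():
    return make_reference_circuit()


@pytest.fixture(scope="session")
def dark_trajectory(grid, maternal, reference_params):
    """Dark-control simulation of the shipped fixture over the full window."""
    return simulate(reference_params, maternal, None, grid,
                    v0=reference_initial_state(grid))


@pytest.fixture(scope="session")
def scenario5_trajectory(grid, maternal, reference_params):
    """Bcd off from the start of n.c. 13 until gastrulation."""
    scen = IlluminationScenario(id="5", windows=((-60.0, 0.0),))
    return simulate(reference_params, maternal, scen, grid,
                    v0=reference_initial_state(grid))


@pytest.fixture(scope="session")
def dark_profiles(dark_trajectory):
    return trajectory_profiles(dark_trajectory)


@pytest.fixture(scope="session")
def scenario5_profiles(scenario5_trajectory):
    return trajectory_profiles(scenario5_trajectory)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260930)
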