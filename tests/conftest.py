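import numpy as np
import pytest

from atraflow import load_parameters, make_grid, solve_steady_state


@pytest.fixture(scope="session")
def mouse_params():
    return load_parameters(species="mouse", condition="control")


@pytest.fixture(scope="session")
def human_params():
    return load_parameters(species="human", condition="control")


@pytest.fixture(scope="session")
def feeding_params():
    return load_parameters(species="mouse", condition="feeding")


def _solve(params, n=300):
    return solve_steady_state(params, grid=make_grid(params, n, n))


@pytest.fixture(scope="session")
def mouse_result(mouse_params):
    """Converged mouse-control steady state (shared across tests)."""
    return _solve(mouse_params)


@pytest.fixture(scope="session")
def human_result(human_params):
    return _solve(human_params)


@pytest.fixture(scope="session")
def feeding_result(feeding_params):
    return _solve(feeding_params)


@pytest.fixture(scope="session")
def all_results(mouse_result, human_result, feeding_result):
    return {"mouse": mouse_result, "human": human_result,
            "feeding": feeding_result}
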