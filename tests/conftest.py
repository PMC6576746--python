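import warnings

import pytest

from remap3d import SimulationConfig, simulate_interaction_data


@pytest.fixture(scope="session")
def benchmark_sim():
    """The default planted low-rank interaction benchmark (seed 42)."""
    return simulate_interaction_data(SimulationConfig())


@pytest.fixture(autouse=True)
def _quiet_convergence_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message="solver did not converge")
        yield
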