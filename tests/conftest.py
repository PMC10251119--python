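import numpy as np
import pytest
from hypothesis import settings

from driftbalance.simulator import SimulationConfig

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_run_config():
    """A seconds-scale simulation: 4 founders, early stop."""
    return SimulationConfig(
        n_initial=4, spacing=5.0, seed=11, stop_volume_fraction=0.01,
    )


@pytest.fixture(scope="session")
def tiny_run_result(tiny_run_config):
    from driftbalance.simulator import run

    return run(tiny_run_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20230610)
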