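import numpy as np
import pytest

from spinalcpg import SimConfig, nap_burster, run_two_cell, simple_neuron


@pytest.fixture(scope="session")
def table_config() -> SimConfig:
    """Standard two-cell protocol: 20 s settling + 100 s analysis."""
    return SimConfig(duration=120.0, settle=20.0)


@pytest.fixture(scope="session")
def uncoupled_runs(table_config):
    """Cached isolated-neuron runs for every published leak-reversal setting.

    Keyed by (has_nap, e_leak); the partner neuron is a far-hyperpolarized
    silent cell so each run is effectively a single neuron.
    """
    cache = {}

    def get(has_nap: bool, e_leak: float):
        key = (has_nap, e_leak)
        if key not in cache:
            neuron = nap_burster(e_leak) if has_nap else simple_neuron(e_leak)
            cache[key] = run_two_cell(
                neuron, simple_neuron(-100.0), coupling="none", config=table_config
            )
        return cache[key]

    return get


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20201223)
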