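import dataclasses

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from ins2p.synth import SyntheticConfig, simulate_experiment
from ins2p.traces import analyze_trace_array


@pytest.fixture(scope="session")
def default_sim():
    """One full synthetic experiment at the default study conditions
    (250 cells, 4 energies x 5 trials, 30 s at ~31 Hz)."""
    return simulate_experiment(SyntheticConfig(seed=20))


@pytest.fixture(scope="session")
def default_calls(default_sim):
    sim = default_sim
    return analyze_trace_array(sim.traces, sim.energies,
                               roi_ids=sim.cells["roi_id"].to_numpy())


@pytest.fixture(scope="session")
def lownoise_sim():
    """Same design at near-zero noise, for exact-recovery checks."""
    cfg = dataclasses.replace(SyntheticConfig(seed=21), noise_sd=1e-4)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def lownoise_calls(lownoise_sim):
    sim = lownoise_sim
    return analyze_trace_array(sim.traces, sim.energies,
                               roi_ids=sim.cells["roi_id"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
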