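import numpy as np
import pytest

import restdyn as rd


@pytest.fixture(scope="session")
def small_dataset():
    """Small 2-state dataset with well-separated patterns, shared by tests."""
    cfg = rd.SimulationConfig(
        n_subjects=3,
        n_sessions=2,
        n_nodes=6,
        n_states=2,
        samples_per_session=1500,
        noise_sd=0.3,
        seed=101,
    )
    paths = rd.simulate_state_paths(cfg)
    dataset = rd.simulate_envelopes(paths, cfg)
    return cfg, paths, dataset


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
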