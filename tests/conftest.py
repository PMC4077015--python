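import numpy as np
import pytest

from assrlab.lfp_io import AnalysisConfig, Recording
from assrlab.synthetic_data import SimulationConfig, simulate_session


@pytest.fixture(scope="session")
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tiny_sim_cfg() -> SimulationConfig:
    """Three trains per session: enough for first/middle/last ISI probes."""
    return SimulationConfig(n_trials=3, pre_s=12.0, post_s=16.0)


@pytest.fixture(scope="session")
def tiny_session(tiny_sim_cfg):
    """One 2-channel control session (~148 s), reused across tests."""
    return simulate_session(
        tiny_sim_cfg, n_channels=2, animal_id="a1", genotype="control", seed=11
    )


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture()
def noise_recording(rng) -> Recording:
    return Recording(
        signals=rng.standard_normal((2, 4680)),
        fs=1560.0,
        channel_ids=["c1", "c2"],
        animal_id="a0",
        genotype="control",
    )
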