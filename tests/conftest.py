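import numpy as np
import pytest

from isofatigue import SimConfig, simulate_trial


@pytest.fixture(scope="session")
def short_cfg() -> SimConfig:
    """A short but otherwise default endurance trial (12 repetitions)."""
    return SimConfig(n_max=12, seed=7)


@pytest.fixture(scope="session")
def short_trial(short_cfg):
    """One simulated trial shared across read-only tests."""
    return simulate_trial(short_cfg)


@pytest.fixture(scope="session")
def clean_cfg() -> SimConfig:
    """A noise-free trial: no mechanical noise, no amplitude instability,
    no motion artifacts.  Used for fidelity checks of the imposed
    schedules."""
    return SimConfig(
        n_max=10, seed=11, noise_cv=0.0, emg_amp_cv=0.0, artifact_rate=0.0
    )


@pytest.fixture(scope="session")
def clean_trial(clean_cfg):
    return simulate_trial(clean_cfg)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
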