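import numpy as np
import pytest

from pursuitprior import ObserverGenParams, TaskConfig, simulate_session


@pytest.fixture(scope="session")
def small_task() -> TaskConfig:
    """Reduced trial counts for fast unit tests (geometry unchanged)."""
    return TaskConfig(prior_direction=30.0, n_trials_narrow=72, n_trials_wide=72)


@pytest.fixture(scope="session")
def quiet_gen() -> ObserverGenParams:
    """Generator without saccades or latency/gain jitter, for clean oracles."""
    return ObserverGenParams(
        saccade_rate=0.0, latency_sd=0.0, gain_sd=0.0, position_noise_sd=0.0
    )


@pytest.fixture(scope="session")
def small_session(small_task, quiet_gen):
    return simulate_session(small_task, quiet_gen, seed=42)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
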