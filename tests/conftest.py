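import numpy as np
import pytest

import perimqc as pq


@pytest.fixture(scope="session")
def default_config():
    return pq.ProtocolConfig()


@pytest.fixture(scope="session")
def small_config():
    """Shrunk protocol for fast tests: same structure, ~10x fewer events."""
    return pq.ProtocolConfig(reps_peripheral=2, reps_reference=1)


@pytest.fixture(scope="session")
def default_schedule(default_config):
    return pq.build_schedule(default_config, seed=42)


@pytest.fixture(scope="session")
def quiet_session(default_schedule):
    """A fully vigilant session (no episodes)."""
    params = pq.ObserverParams(seed=11, vigilance=pq.VigilanceParams(episode_rate=0.0))
    return pq.simulate_session(default_schedule, params, subject_id="S001")


@pytest.fixture(scope="session")
def drowsy_session(default_schedule):
    """A session with frequent low-vigilance episodes."""
    params = pq.ObserverParams(
        seed=12, vigilance=pq.VigilanceParams(episode_rate=6.0)
    )
    return pq.simulate_session(default_schedule, params, subject_id="S002")


@pytest.fixture(scope="session")
def small_cohort(default_config):
    """Eight graded subjects on the full protocol."""
    return pq.simulate_cohort(
        8, default_config, pq.graded_rate_sampler(8.0), seed=123
    )
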