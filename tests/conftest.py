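import numpy as np
import pytest

from lickrig.config import SessionConfig
from lickrig.engine import run_session
from lickrig.subject import SubjectParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gng_delay_config():
    """The showcased GNG configuration: Delay Period (1, 5, 6 steps) with a
    200 ms stimulus, delay timer referenced to stimulus onset."""
    return SessionConfig(
        task="gng", n_trials=12,
        delay_period_min=1.0, delay_period_max=5.0, delay_period_steps=6,
        stimulus_duration_ms=200.0, percentage_of_go_trials=100.0,
    ).validate()


@pytest.fixture
def small_2afc_result():
    config = SessionConfig(task="2afc", n_trials=30, seed=7)
    return run_session(config, SubjectParams(alpha=4.0, beta=0.5))


@pytest.fixture
def lateralized_subject():
    """Near-deterministic subject: always correct on the extreme columns."""
    return SubjectParams(alpha=4.0, beta=0.05, guess=0.0, lapse=0.0,
                         reaction_time_median_s=0.2,
                         reaction_time_sigma=0.1)
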