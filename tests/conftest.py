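import numpy as np
import pytest

from reachkin.session import BetaGlmmParams, TaskParams, gen_session


@pytest.fixture(scope="session")
def default_session():
    """One full simulated session with the default task parameters."""
    return gen_session(seed=123)


@pytest.fixture(scope="session")
def small_session():
    """A short session (20 valid trials) for fast round-trip tests."""
    task = TaskParams(n_valid_trials=20, max_total_trials=24,
                      p_anticipation=0.05, p_omission=0.08)
    return gen_session(task=task, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(99)
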