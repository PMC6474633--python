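import numpy as np
import pytest

from hierlearn.taskgen import GenerativeConfig, StimulusSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cfg():
    return GenerativeConfig()


def make_sequence(stimuli, theta=None, block_id=None,
                  statistic="transitions"):
    """Hand-built sequence for unit tests (generative fields optional)."""
    stimuli = np.asarray(stimuli, dtype=int)
    T = len(stimuli)
    width = 1 if statistic == "frequency" else 2
    if theta is None:
        theta = np.full((T, width), 0.5)
    else:
        theta = np.asarray(theta, dtype=float).reshape(T, width)
    if block_id is None:
        block_id = np.zeros(T, dtype=int)
    change = np.zeros((T, width), dtype=bool)
    change[1:] = theta[1:] != theta[:-1]
    return StimulusSequence(stimuli=stimuli, theta=theta,
                            change_points=change,
                            block_id=np.asarray(block_id, dtype=int),
                            statistic=statistic)


@pytest.fixture(scope="session")
def small_design_pool():
    """A small pool of selected experiments shared across test modules."""
    from hierlearn.study import prepare_design_pool
    return prepare_design_pool(4, seed=77, grid_n=40)
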