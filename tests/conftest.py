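import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_study1():
    """One-subject, one-run Study-1-shaped design config."""
    from wmnet.simulate import study1_config

    return study1_config(n_subjects=1, n_runs=1, n_rois=4, seed=11)
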