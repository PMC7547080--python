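import numpy as np
import pytest
from hypothesis import settings

from lensmap3d.synthetic import mature_config, sample_epithelium

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def mature_truth():
    """One mature-preset ground truth shared across read-only tests."""
    return sample_epithelium(mature_config(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
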