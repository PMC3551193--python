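import numpy as np
import pytest
from hypothesis import settings

from neuroloop.plant import PlantParams
from neuroloop.session import train_ad_classifier

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def default_params():
    return PlantParams()


@pytest.fixture(scope="session")
def ad_classifier():
    """AD-vs-rest boundary trained once on the seeded plant fixture."""
    boundary, constraints, ev_segs, ne_segs = train_ad_classifier(seed=0)
    return boundary, constraints, ev_segs, ne_segs


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
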