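import numpy as np
import pytest

from gliomabm.tissue import make_synthetic_brain


@pytest.fixture(scope="session")
def gray_domain():
    """2 x 2 mm of uniform gray matter."""
    return make_synthetic_brain(2.0, 2.0, seed=0)


@pytest.fixture(scope="session")
def banded_domain():
    """2 x 2 mm with a 0.5-mm white-matter band through the middle."""
    return make_synthetic_brain(
        2.0, 2.0, tract_spec={"center_frac": 0.5, "thickness_mm": 0.5}, seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
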