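import numpy as np
import pytest

from pedsim.foot_model import BuildParams, build_foot


@pytest.fixture(scope="session")
def default_model():
    """One default skeleton shared by read-only tests."""
    return build_foot()


@pytest.fixture(scope="session")
def small_model():
    """Down-scaled skeleton for cheaper geometric tests."""
    return build_foot(BuildParams(scale=180.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260924)
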