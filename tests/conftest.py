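import numpy as np
import pytest

from phylodiff.fixtures import FixtureSpec, generate, golden_small


@pytest.fixture(scope="session")
def golden():
    """Deterministic 12-subject golden dataset shared across tests."""
    return golden_small()


@pytest.fixture(scope="session")
def small_profile(golden):
    return golden[0]


@pytest.fixture(scope="session")
def training_fixture():
    """20-subject cohort with strong temporal autocorrelation, used by the
    learning-signal tests."""
    return generate(FixtureSpec(S=20, L=5, K=24, ar_rho=0.9, seed=3))
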