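import numpy as np
import pytest

from snakereg import FieldSpec, PhantomSpec, make_pair, make_suite


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_case():
    """One 24^3 phantom pair with ground truth (shared, read-only)."""
    return make_pair(PhantomSpec(shape=(24, 24, 24)), FieldSpec(), seed=42)


@pytest.fixture(scope="session")
def small_suite():
    """Five 16^3 cases for loop-level tests (shared, read-only)."""
    return make_suite(5, PhantomSpec(shape=(16, 16, 16)), FieldSpec(amplitude=1.5), seed=99)
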