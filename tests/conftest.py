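import numpy as np
import pytest

from xtalfate.features import build_catalog
from xtalfate.sequence_io import STANDARD_AA, ProteinRecord


@pytest.fixture(scope="session")
def catalog():
    return build_catalog()


@pytest.fixture(scope="session")
def random_record():
    rng = np.random.default_rng(42)
    seq = "".join(rng.choice(list(STANDARD_AA), size=200))
    return ProteinRecord("rand200", seq)


def make_random_sequence(rng, length):
    return "".join(rng.choice(list(STANDARD_AA), size=length))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
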