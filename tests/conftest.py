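import numpy as np
import pytest

from tgaredox.motif import DEFAULT_REFERENCE, ClassifierParams


@pytest.fixture
def ref():
    return DEFAULT_REFERENCE


@pytest.fixture
def params():
    return ClassifierParams()


@pytest.fixture
def rng():
    return np.random.default_rng(20160415)


def random_dna(rng, n, gc=0.4):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))
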