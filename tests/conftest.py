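import numpy as np
import pytest

from animats.genome import random_chromosome
from animats.network import ARCH_DEEP, ARCH_SHALLOW
from animats.sequences import make_periodic_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(params=[ARCH_SHALLOW, ARCH_DEEP], ids=["4", "4x4"])
def architecture(request):
    return request.param


@pytest.fixture
def canonical_sequence():
    return make_periodic_sequence("101", 2916)


@pytest.fixture
def short_sequence():
    return make_periodic_sequence("101", 30)


@pytest.fixture
def chromosome(architecture, rng):
    return random_chromosome(architecture, rng)
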