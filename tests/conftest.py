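import numpy as np
import pytest

from abcsld import RandomSource, build_system1, build_system2


@pytest.fixture
def system1():
    return build_system1()


@pytest.fixture
def system2():
    return build_system2()


@pytest.fixture
def rng():
    return RandomSource(1234)


@pytest.fixture
def np_rng():
    return np.random.default_rng(99)
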