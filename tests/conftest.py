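import numpy as np
import pytest

from txstate import GeneratorParams, generate_study

SMALL_PARAMS = GeneratorParams(seed=7, n_probes=800)


@pytest.fixture(scope="session")
def small_study():
    """A reduced synthetic study (800 probes) for fast integration tests."""
    return generate_study(SMALL_PARAMS)


@pytest.fixture(scope="session")
def default_study():
    """The full-size default synthetic study, seed 1."""
    return generate_study(GeneratorParams(seed=1))


@pytest.fixture
def rng():
    return np.random.default_rng(0)
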