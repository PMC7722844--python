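import numpy as np
import pytest

from silentscan import synthetic_data as sd


@pytest.fixture(scope="session")
def small_genome():
    return sd.simulate_genome(20_000, 0.64, seed=101)


@pytest.fixture(scope="session")
def te_library():
    return {
        "TEalpha": sd.simulate_genome(1000, 0.50, seed=201),
        "TEbeta": sd.simulate_genome(800, 0.55, seed=202),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
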