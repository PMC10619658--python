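import numpy as np
import pytest

from canopyflow.plant import PlantSpec, generate_plant


@pytest.fixture(scope="session")
def default_plant():
    return generate_plant(PlantSpec(rng_seed=0))


@pytest.fixture(scope="session")
def mini_plant():
    """Two-leaf plant for coupled-solver tests."""
    return generate_plant(PlantSpec(n_leaves=2, rng_seed=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
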