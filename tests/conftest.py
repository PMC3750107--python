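import numpy as np
import pytest

from odespline.models import get_model
from odespline.synthetic import make_benchmark_dataset


@pytest.fixture(scope="session")
def enzyme_model():
    return get_model("enzyme")


@pytest.fixture(scope="session")
def g1s_model():
    return get_model("g1s")


@pytest.fixture(scope="session")
def enzyme_clean():
    """Noise-free enzyme benchmark: 4 courses x 40 points."""
    return make_benchmark_dataset("enzyme", 0.0, seed=1)


@pytest.fixture(scope="session")
def enzyme_noisy():
    """One 10%-noise realization of the enzyme benchmark."""
    return make_benchmark_dataset("enzyme", 0.10, seed=11)


@pytest.fixture(scope="session")
def g1s_clean():
    return make_benchmark_dataset("g1s", 0.0, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
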