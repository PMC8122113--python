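import numpy as np
import pytest

from crcsim.benchmarks import benchmark_model
from crcsim.synthetic_country import SyntheticSpec, generate_synthetic_country


@pytest.fixture(scope="session")
def western():
    return benchmark_model("western")


@pytest.fixture(scope="session")
def synthetic_country():
    """One synthetic country with known ground truth, shared by tests."""
    template, truth = generate_synthetic_country(SyntheticSpec(seed=11))
    return template, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
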