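import numpy as np
import pytest
from hypothesis import settings

from bsepscreen.descriptors import GroupCatalog
from bsepscreen.synthetic import GeneratorConfig, generate

settings.register_profile("deterministic", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def catalog():
    return GroupCatalog.default()


@pytest.fixture(scope="session")
def small_panel():
    """A small default-condition synthetic panel shared across tests."""
    return generate(GeneratorConfig(seed=7))


@pytest.fixture
def rng():
    return np.random.default_rng(42)
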