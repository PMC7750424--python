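import pytest

from spyield import generate_variants, media_fixture, sp_fixture
from spyield.synthetic_data import GeneratorConfig


@pytest.fixture(scope="session")
def peptides():
    return sp_fixture()


@pytest.fixture(scope="session")
def media_demand():
    return media_fixture()


@pytest.fixture(scope="session")
def small_dataset():
    """A quick, well-separated synthetic dataset shared across tests."""
    return generate_variants(GeneratorConfig(n_variants=168, seed=11))
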