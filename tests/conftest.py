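import pytest

from mitocomp.datasets import harpago_chiragra, lambis_lambis
from mitocomp.simulate import GeneratorConfig, generate_genome


@pytest.fixture(scope="session")
def harpago():
    return harpago_chiragra()


@pytest.fixture(scope="session")
def lambis():
    return lambis_lambis()


@pytest.fixture(scope="session")
def synthetic():
    """One deterministic synthetic mitogenome with sequence."""
    return generate_genome(GeneratorConfig(seed=11), organism_label="synthetic_11")
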