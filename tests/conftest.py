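import pytest

from parti import (
    PipelineConfig,
    compose_species,
    default_registry,
)


@pytest.fixture(scope="session")
def registry():
    monomers, standards = default_registry()
    return monomers, standards


@pytest.fixture(scope="session")
def monomers(registry):
    return registry[0]


@pytest.fixture(scope="session")
def leu_enk(registry):
    return registry[1]["Leu-Enk"]


@pytest.fixture(scope="session")
def adenosine_species():
    return compose_species(None, 0)


@pytest.fixture(scope="session")
def config():
    return PipelineConfig()
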