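import pytest

from msready import StandardizationConfig, build_fixture
from msready.registry import Registry


def _registry_for(name: str) -> Registry:
    reg = Registry()
    reg.ingest_substances(build_fixture(name).substances)
    reg.process_all(StandardizationConfig())
    return reg


@pytest.fixture(scope="session")
def nicotine_registry():
    return _registry_for("nicotine_family")


@pytest.fixture(scope="session")
def pfos_registry():
    return _registry_for("pfos_family")


@pytest.fixture(scope="session")
def triazine_registry():
    return _registry_for("triazines")


@pytest.fixture(scope="session")
def methapyrilene_registry():
    return _registry_for("methapyrilene")


@pytest.fixture(scope="session")
def msready_config():
    return StandardizationConfig()


@pytest.fixture(scope="session")
def qsarready_config():
    return StandardizationConfig(mode="qsarready")
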