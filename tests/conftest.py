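import pytest
from hypothesis import settings

from sbmt import ChamberConfig, fixtures

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def reference_config() -> ChamberConfig:
    """99-L chamber at 0.5 h⁻¹ with a 0.04 m² specimen (Q_v/A = 1.2375 m/h)."""
    return fixtures.REFERENCE_CONFIG


@pytest.fixture(scope="session")
def condition_tests():
    """The ten packaged material × condition chamber records."""
    return fixtures.chamber_tests()


@pytest.fixture(scope="session")
def effectiveness_table():
    return fixtures.sorption_effectiveness()


@pytest.fixture(scope="session")
def dwelling_table():
    return fixtures.dwelling_risk()
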