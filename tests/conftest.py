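import pytest
from hypothesis import HealthCheck, settings

from cspascore.domain import default_rules
from cspascore.fixtures import bundled_profiles

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def rules():
    return default_rules()


@pytest.fixture(scope="session")
def profiles():
    return bundled_profiles()


@pytest.fixture(scope="session")
def by_id(profiles):
    return {p.chemical_id: p for p in profiles}
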