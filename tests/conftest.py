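import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.function_scoped_fixture],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def packaged_profiles():
    from shorebird_risk import load_packaged_table

    return load_packaged_table()


@pytest.fixture(scope="session")
def packaged_reference():
    from shorebird_risk import load_packaged_reference

    return load_packaged_reference()
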