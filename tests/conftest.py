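import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def usecase():
    """The bundled worked-example patient and their reference tables."""
    from polyrisk.usecase import usecase_fixture

    return usecase_fixture()


@pytest.fixture(scope="session")
def usecase_record(usecase):
    from polyrisk.cohort import filter_active

    extract, acb, interactions = usecase
    records, _unknown = filter_active(extract, known=acb.drugs | interactions.drugs)
    assert len(records) == 1
    return records[0]
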