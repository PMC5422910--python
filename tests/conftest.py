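import pytest
from hypothesis import HealthCheck, settings

import esscrs as E

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def derivation_fixture_solved():
    return E.derivation_fixture()


@pytest.fixture(scope="session")
def derivation_cohort(derivation_fixture_solved):
    """One realization of the full derivation cohort (185,354 encounters)."""
    return E.realize_cohort(derivation_fixture_solved, seed=123)


@pytest.fixture(scope="session")
def derivation_reference(derivation_cohort):
    return {e.encounter_id: e.reference_label for e in derivation_cohort}


@pytest.fixture(scope="session")
def validation_cohort():
    """The sampled internal-validation cohort (392 encounters)."""
    full = E.realize_cohort(E.validation_year_fixture(), seed=7)
    return E.sample_validation_cohort(full, "model3", n_controls=200, seed=11)
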