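import pytest
from hypothesis import settings

from npcstage.cea import CEAParameters
from npcstage.simulate import (
    PairedCorrectnessSpec,
    cohort_a_spec,
    generate_decision_fixture_c,
    generate_fixture_cohort_a,
    generate_staging_fixture_b,
)

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def cohort_a():
    """Deterministic diagnostic cohort: 555 metastatic / 139 benign nodes."""
    return generate_fixture_cohort_a(cohort_a_spec(seed=1))


@pytest.fixture(scope="session")
def cohort_b():
    """Patient-level staging fixture with the (423, 40, 21, 19) correctness cells."""
    return generate_staging_fixture_b(PairedCorrectnessSpec())


@pytest.fixture(scope="session")
def cohort_c():
    """Per-oncologist before/after decision records."""
    return generate_decision_fixture_c()


@pytest.fixture()
def base_params():
    return CEAParameters()
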