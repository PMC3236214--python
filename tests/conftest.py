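import pytest

from lbwcost import (
    CohortSpec,
    HealthSystemInputs,
    HouseholdCostConfig,
    SyntheticConfig,
    generate_cohort,
    generate_survey,
)


@pytest.fixture(scope="session")
def synthetic_config():
    return SyntheticConfig()


@pytest.fixture(scope="session")
def survey(synthetic_config):
    """Default synthetic exit-survey microdata (87 routine + 46 admission)."""
    return generate_survey(synthetic_config, seed=11)


@pytest.fixture(scope="session")
def cohort_table(synthetic_config):
    """Default synthetic one-year follow-up cohort (990 infants)."""
    return generate_cohort(synthetic_config, seed=11)


@pytest.fixture(scope="session")
def cohort():
    return CohortSpec()


@pytest.fixture(scope="session")
def hs_inputs():
    return HealthSystemInputs()


@pytest.fixture(scope="session")
def hh_config():
    return HouseholdCostConfig()
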