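import pytest

from plandom.recode import derive_table
from plandom.synthetic_data import GeneratorConfig, generate_survey


@pytest.fixture(scope="session")
def survey_small():
    """A moderate synthetic survey shared across read-only tests."""
    return generate_survey(GeneratorConfig(n_respondents=1500, seed=7))


@pytest.fixture(scope="session")
def derived_small(survey_small):
    return derive_table(survey_small)
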