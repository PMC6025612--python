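import pandas as pd
import pytest

from pitchrisk.synthetic import (
    SoilPopulationSpec,
    SurveySpec,
    default_site,
    generate_soil_samples,
    generate_survey,
)


@pytest.fixture(scope="session")
def site():
    return default_site(seed=0)


@pytest.fixture(scope="session")
def pop():
    return SoilPopulationSpec()


@pytest.fixture(scope="session")
def soil_table(site, pop) -> pd.DataFrame:
    """Default synthetic surface-soil table (39 primaries + duplicates)."""
    return generate_soil_samples(site, pop)


@pytest.fixture(scope="session")
def primary_soil(soil_table) -> pd.DataFrame:
    return soil_table[~soil_table["is_duplicate"]].reset_index(drop=True)


@pytest.fixture(scope="session")
def survey_table() -> pd.DataFrame:
    return generate_survey(SurveySpec(), seed=0)
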