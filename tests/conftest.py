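import numpy as np
import pandas as pd
import pytest

from bfequity import harmonize, synthetic


@pytest.fixture(scope="session")
def world():
    return synthetic.generate_world(synthetic.desk_config(seed=7))


@pytest.fixture(scope="session")
def surveys(world):
    return synthetic.simulate_surveys(world)


@pytest.fixture(scope="session")
def harmonized(surveys):
    models = harmonize.estimate_correction_factors(surveys)
    corrected, _ = harmonize.apply_corrections(surveys, models)
    return corrected


@pytest.fixture(scope="session")
def tiny_config():
    """A 6-country world for fast end-to-end tests."""
    return dict(n_super_regions=2, n_regions_per=1, n_countries_per=3,
                surveys_per_country=4.0)


def make_obs(rows, sample_size=3000):
    """Build a survey-observation frame from (survey_id, country, year,
    indicator, value, national, standard) tuples."""
    recs = []
    for sid, country, year, indicator, value, national, standard in rows:
        recs.append({
            "survey_id": sid, "country_id": country, "year": year,
            "indicator": indicator, "value": value,
            "sample_size": sample_size,
            "variance": value * (1 - value) / sample_size,
            "national": national, "standard_definition": standard,
        })
    return pd.DataFrame(recs, columns=[
        "survey_id", "country_id", "year", "indicator", "value",
        "sample_size", "variance", "national", "standard_definition"])
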