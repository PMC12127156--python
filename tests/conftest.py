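import numpy as np
import pandas as pd
import pytest

from dietscore.survey import SurveyDesign
from dietscore.synthetic import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """One 1,500-woman synthetic cohort shared across read-only tests."""
    return generate_cohort(CohortConfig(n_participants=1500, seed=20240101))


@pytest.fixture(scope="session")
def small_frame(small_cohort):
    return small_cohort.frame


@pytest.fixture(scope="session")
def small_design(small_frame):
    return SurveyDesign(small_frame["survey_weight"].to_numpy())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def equal_design():
    def make(n, w=1.0):
        return SurveyDesign(np.full(n, float(w)))

    return make
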