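import numpy as np
import pytest

from misslab.dataset import Column, Dataset
from misslab.estimators import AnalysisModel
from misslab.synthetic import CannabisParams, GrowthParams, \
    generate_cannabis_population, generate_growth_cohort

CANNABIS_LINEAR = AnalysisModel("depression_21", "cannabis_use",
                                ("sex", "maternal_substance_use"), "linear")
CANNABIS_LOGISTIC = AnalysisModel("self_harm", "cannabis_use",
                                  ("sex", "maternal_substance_use"), "logistic")


@pytest.fixture(scope="session")
def cannabis_big():
    """Large complete cannabis cohort for recovery checks."""
    return generate_cannabis_population(CannabisParams(n=100_000, seed=7))


@pytest.fixture(scope="session")
def growth_big():
    return generate_growth_cohort(GrowthParams(n=100_000, seed=11))


@pytest.fixture()
def cannabis_small():
    return generate_cannabis_population(CannabisParams(n=2_000, seed=3))


@pytest.fixture()
def toy_dataset():
    """Tiny 2-column dataset with a hand-set mask."""
    cols = [Column("x", "continuous", "exposure"), Column("y", "continuous", "outcome")]
    values = np.array([[1.0, 2.0], [2.0, 4.0], [3.0, 6.0], [4.0, 8.0]])
    mask = np.array([[False, False], [True, False], [False, True], [False, False]])
    return Dataset(cols, values, mask)
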