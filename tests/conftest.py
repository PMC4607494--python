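import numpy as np
import pytest

from synergycc import study
from synergycc.cohort import JointTable
from synergycc.logistic import fit_logistic


@pytest.fixture(scope="session")
def study_table() -> JointTable:
    """The published 2x2x2 table, recovered from printed marginals and
    statistics by the cross-validated integer search."""
    return study.reconstruct_study_table().table


@pytest.fixture(scope="session")
def saturated_fit(study_table):
    return fit_logistic(study_table, "saturated")


@pytest.fixture(scope="session")
def main_effects_fit(study_table):
    return fit_logistic(study_table, "main_effects")


@pytest.fixture()
def small_table() -> JointTable:
    """A hand-sized table with all cells positive."""
    return JointTable(np.array([[12, 30], [8, 20]]), np.array([[5, 25], [15, 40]]))
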