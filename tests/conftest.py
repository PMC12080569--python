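import warnings

import numpy as np
import pytest

from dapapkpd.cohort import CohortSpec, PopulationParameters, generate_study

# scipy's truncnorm and the optimisers are chatty about benign conditions
warnings.filterwarnings("ignore", category=UserWarning,
                        message=".*did not report convergence.*")


@pytest.fixture(scope="session")
def reference_params() -> PopulationParameters:
    return PopulationParameters.reference()


@pytest.fixture(scope="session")
def small_study(reference_params):
    """A compact cohort (20 subjects) shared by unit tests that need a
    realistic event table without the cost of the full study size."""
    spec = CohortSpec(n_subjects=20)
    subjects, truth_df, table = generate_study(spec, reference_params, seed=123)
    return spec, subjects, truth_df, table


@pytest.fixture(scope="session")
def full_study(reference_params):
    """One full-size (85-subject) synthetic study."""
    spec = CohortSpec()
    subjects, truth_df, table = generate_study(spec, reference_params, seed=2024)
    return spec, subjects, truth_df, table


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
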