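import numpy as np
import pytest

from ntcp_rectox import CohortSpec, FractionationScheme, generate_cohort
from ntcp_rectox.synthetic_cohort import default_logistic_truth


@pytest.fixture(scope="session")
def scheme():
    return FractionationScheme()


@pytest.fixture(scope="session")
def study_cohort():
    """One 79-patient cohort under the default logistic generating truth."""
    spec = CohortSpec(n_patients=79, seed=20, toxicity_model=default_logistic_truth())
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def large_cohort():
    """A 600-patient cohort for tests that need stable empirical quantities."""
    spec = CohortSpec(n_patients=600, seed=77, toxicity_model=default_logistic_truth())
    return generate_cohort(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
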