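import numpy as np
import pytest

from venomnet.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The study-scale default cohort: 24 patients, seed 1."""
    return generate_cohort(CohortConfig(n_patients=24, seed=1))


@pytest.fixture(scope="session")
def strong_cohort():
    """Small cohort with a strong planted severity signal."""
    return generate_cohort(CohortConfig(n_patients=20, seed=7, severity_effect=3.0))


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)
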