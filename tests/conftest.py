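import numpy as np
import pytest

from hrvbp import (default_subject_params, default_true_model,
                   generate_cohort)
from hrvbp.pipeline import predictive_from_cohort


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Study-scale cohort (10 subjects x 4 reps) with eps_sd = 0 and
    sigma_bp = 0, shared by the protocol-arithmetic and exact-recovery
    tests."""
    tm = default_true_model(eps_sd=0.0)
    params = default_subject_params(10, seed=0, sigma_bp=0.0)
    return generate_cohort(10, 4, params, tm, seed=0)


@pytest.fixture(scope="session")
def noiseless_predictive(noiseless_cohort):
    return predictive_from_cohort(noiseless_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
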