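import warnings

import numpy as np
import pytest

from sca3prog import CohortConfig, default_truth, generate_cohort
from sca3prog.design import build_design, registry_spec
from sca3prog.lmm import fit_lmm

# boundary (singular random covariance) fits are expected in tests that
# simulate with re_cov = 0
warnings.filterwarnings("ignore", message="random-effects covariance is singular")


@pytest.fixture(scope="session")
def pm1_cohort():
    """One default synthetic cohort drawn from the piece-wise (PM1) truth."""
    return generate_cohort(CohortConfig(seed=11))


@pytest.fixture(scope="session")
def pm1_fit(pm1_cohort):
    return fit_lmm(build_design(pm1_cohort, registry_spec("PM1", 13.0)))


@pytest.fixture(scope="session")
def small_cohort():
    """A 30-subject cohort for cheap fits."""
    return generate_cohort(CohortConfig(n_subjects=30, seed=5))


def noiseless_config(model_name: str, seed: int = 0, n_subjects: int = 40,
                     resid_sd: float = 1e-9) -> CohortConfig:
    """Config whose trajectories are (numerically) deterministic given the
    fixed effects: zero random-effect covariance, vanishing residual SD."""
    truth = default_truth(model_name)
    q = len(truth.re_cov)
    truth = type(truth)(model_name=truth.model_name, knot=truth.knot,
                        beta=truth.beta, re_cov=np.zeros((q, q)),
                        resid_sd=resid_sd)
    return CohortConfig(n_subjects=n_subjects, seed=seed, truth=truth)
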