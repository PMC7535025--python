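import numpy as np
import pytest

from anemiascope.synthetic_cohort import (
    calibrate_copula,
    default_cohort_spec,
    generate_cohort,
)


@pytest.fixture(scope="session")
def calibrated_spec():
    """Default cohort spec with a moderately sized copula calibration."""
    spec = default_cohort_spec(n=4000, seed=11)
    spec.copula = calibrate_copula(
        spec.copula, spec.marginals, n_cal=20_000, seed=11
    )
    return spec


@pytest.fixture(scope="session")
def cohort(calibrated_spec):
    """A 4000-woman synthetic cohort shared across tests."""
    return generate_cohort(calibrated_spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
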