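import numpy as np
import pytest

from fracrisk import load_coefficients, load_config, generate_cohort


@pytest.fixture(scope="session")
def coeffs():
    return load_coefficients()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def clean_cohort(coeffs):
    """Synthetic cohort with no mortality and censoring at the 10-year horizon,

    so that observed 10-year incidence equals model-predicted risk by
    construction (up to Monte-Carlo error).
    """
    config = load_config(n=4000, seed=77, mortality_rate=0.0, admin_censor_years=10.0)
    return generate_cohort(config, coeffs)
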