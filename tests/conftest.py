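import numpy as np
import pytest

import stackdose as sd


@pytest.fixture(scope="session")
def small_cohort():
    """641-patient synthetic cohort under the default (published) marginals."""
    return sd.generate_cohort(sd.default_config(n=641, seed=11))


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort whose dose is an exact function of the covariates."""
    cfg = sd.default_config(n=300, seed=5)
    cfg = cfg.with_(dose_model=sd.DoseModel(noise_sd=0.0))
    return sd.generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
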