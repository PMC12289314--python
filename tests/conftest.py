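import numpy as np
import pytest

from patsim.cohort import CohortSpec, generate_cohort
from patsim import preprocess as pp


@pytest.fixture(scope="session")
def small_cohort():
    """A desk-scale cohort with every structural feature of the generator:
    mixed kinds, sparsity straddling 1%, lab missingness straddling 30%,
    outliers and noise."""
    spec = CohortSpec(n_patients=400, n_medications=20, n_procedures=20,
                      n_labs=6, latent_dim_true=5, outlier_rate=0.02,
                      noise_sd=0.5, seed=11)
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def processed_cohort(small_cohort):
    fitted, processed = pp.fit_apply(small_cohort, pp.PreprocessConfig(seed=0))
    return fitted, processed


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
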