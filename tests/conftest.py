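import numpy as np
import pytest

from panrx.synthetic import CohortSpec, generate_cohort, generate_null_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A structured cohort shared by read-only tests."""
    spec = CohortSpec(
        n_histotypes=6,
        cells_per_histotype=15,
        n_probes=200,
        n_hist_probes=60,
        n_resp_probes=25,
        hist_var_share=0.6,
        noise_sd_resp=0.2,
        seed=11,
    )
    return generate_cohort(spec)


@pytest.fixture(scope="session")
def null_small_cohort():
    spec = CohortSpec(
        n_histotypes=6,
        cells_per_histotype=15,
        n_probes=200,
        n_hist_probes=60,
        n_resp_probes=25,
        hist_var_share=0.6,
        noise_sd_resp=0.2,
        seed=13,
    )
    return generate_null_cohort(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
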