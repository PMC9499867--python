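import numpy as np
import pytest

from preclad import preprocess, synthetic


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort with its ground-truth latent column."""
    cc = synthetic.CohortConfig(seed=7)
    return synthetic.generate_cohort(cc, include_latent=True), cc


@pytest.fixture(scope="session")
def preprocessed(default_cohort):
    cohort, cc = default_cohort
    return preprocess.preprocess_cohort(cohort.drop(columns=["latent_cl"])), cc


@pytest.fixture(scope="session")
def followup(default_cohort):
    cohort, cc = default_cohort
    return synthetic.generate_followup(cohort, cc)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
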