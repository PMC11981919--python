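import numpy as np
import pytest

from gastroclone import postfilter as pf
from gastroclone.cohortsim import SimConfig, simulate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A compact cohort exercising every variant class (somatic, germline,
    artifact, trisomy) without full study-size cost."""
    config = SimConfig(
        n_donors=4,
        glands_per_donor=5,
        trisomy_prob=0.3,
        n_phased_snps=30,
        seed=123,
    )
    return simulate_cohort(config)


@pytest.fixture(scope="session")
def small_filtered(small_cohort):
    donors = dict(zip(small_cohort.metadata["sample"], small_cohort.metadata["donor"]))
    return pf.classify_variants(small_cohort.count_matrix, donors)


@pytest.fixture()
def rng():
    return np.random.default_rng(20250926)
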