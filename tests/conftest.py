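import numpy as np
import pytest

from marsa.synthetic import CohortSpec, make_ground_truth, simulate_cohort


@pytest.fixture(scope="session")
def gt2d():
    """30-item geometry embeddable in the 2-D arena (exact MA recovery)."""
    return make_ground_truth(30, 2, n_categories=1, cat_separation=0.0, seed=11)


@pytest.fixture(scope="session")
def gt3d():
    """30-item 3-D geometry with 4 separated categories."""
    return make_ground_truth(30, 3, n_categories=4, cat_separation=2.0, seed=12)


@pytest.fixture(scope="session")
def cohort12(gt3d):
    """12 noiseless subjects mixing shared and idiosyncratic geometry."""
    spec = CohortSpec(n_subjects=12, shared_w=1.0, idio_w=1.0, noise_sd=0.0, seed=7)
    return simulate_cohort(gt3d, spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
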