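import numpy as np
import pytest

from modgraph.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Desk-scale cohort shared by training-heavy tests (16px, 48 subjects)."""
    cfg = CohortConfig(n_subjects=48, image_side=16, n_slices_range=(4, 6),
                       missing_rates={"pet": 0.1}, seed=1)
    return generate_cohort(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
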