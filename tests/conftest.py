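import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=30,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_cohort():
    """Tiny null cohort shared across tests (8 vs 8, 300 CpGs)."""
    from cfmesa.io import beta_matrix
    from cfmesa.simulate import CohortDesign, generate_cohort

    design = CohortDesign(
        n_per_group={"sALS": 8, "control": 8}, n_cpgs=300, seed=7
    )
    samples, truth = generate_cohort(design)
    beta = beta_matrix(samples)
    labels = pd.Series({s.sample_id: s.group for s in samples})
    return samples, beta, labels, truth
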