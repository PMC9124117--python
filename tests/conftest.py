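import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=100,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def small_cohort():
    """A modest synthetic cohort with ground truth, shared across tests."""
    from graftsurv.synthetic import CohortSpec, generate_cohort

    spec = CohortSpec(n_patients=400, seed=11)
    return generate_cohort(spec)


@pytest.fixture
def processed_cohort(small_cohort):
    """The small cohort after cleaning, imputation and labelling."""
    from graftsurv import preprocessing as pp

    table, truth = small_cohort
    table = pp.clean_table(table)
    table = pp.drop_sparse_rows(table)
    table = pp.impute_table(table)
    table = pp.attach_labels(table)
    return table, truth


@pytest.fixture
def rng():
    return np.random.default_rng(202)
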