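import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ici_landscape.io_core import ExpressionMatrix

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_expression(values, genes=None, samples=None, log2_scale=False):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(values, index=genes, columns=samples), log2_scale=log2_scale
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A small disjoint-block cohort shared across read-only tests."""
    from ici_landscape.synthetic_cohort import CohortConfig, simulate_cohort

    return simulate_cohort(
        CohortConfig(n_samples=80, n_genes=400, markers_per_type=10, seed=202)
    )
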