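import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from kpmediation import CohortDesign, SyntheticTruth, generate_cohort

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """Null-truth cohort, 80 subjects, for structural tests."""
    table, truth = generate_cohort(CohortDesign(n_t1=80), seed=11)
    return table


@pytest.fixture(scope="session")
def causal_cohort():
    """Cohort with known non-null paths through the first metabolite."""
    truth = SyntheticTruth(
        c_prime=2.0,
        a=(0.5,) + (0.0,) * 8,
        b=(1.0,) + (0.0,) * 8,
    )
    table, truth = generate_cohort(CohortDesign(n_t1=500), truth, seed=7)
    return table, truth


@pytest.fixture()
def clustered_df():
    """Simple 3-visit longitudinal frame with a real random intercept."""
    rng = np.random.default_rng(42)
    n_subj, m = 120, 3
    sid = np.repeat(np.arange(n_subj), m)
    x = rng.normal(size=n_subj * m)
    z = rng.normal(size=n_subj * m)
    u = 1.7 * rng.normal(size=n_subj)[sid]
    y = 2.0 + 0.8 * x - 0.3 * z + u + 1.3 * rng.normal(size=n_subj * m)
    return pd.DataFrame(
        {"subject_id": sid.astype(str), "x": x, "z": z, "y": y}
    )
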