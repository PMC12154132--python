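import numpy as np
import pytest

from curemap.cure import mcm_fit
from curemap.synthetic import CohortConfig, generate_cohort, make_design


@pytest.fixture(scope="session")
def small_cohort():
    """A moderate synthetic cohort shared across tests (n=2000, seed=3)."""
    cfg = CohortConfig(n_subjects=2000, seed=3)
    df, geo, truth = generate_cohort(cfg)
    return cfg, df, geo, truth


@pytest.fixture(scope="session")
def small_designs(small_cohort):
    cfg, df, _, _ = small_cohort
    X, xnames = make_design(df, cfg.covariate_schema)
    Z, znames = make_design(df, cfg.covariate_schema, intercept=True)
    return X, xnames, Z, znames


@pytest.fixture(scope="session")
def fitted_mcm(small_cohort, small_designs):
    _, df, _, _ = small_cohort
    X, _, Z, _ = small_designs
    return mcm_fit(X, Z, df["time"].to_numpy(), df["event"].to_numpy())


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
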