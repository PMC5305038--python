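import numpy as np
import pytest

from lickstat.simulate import CohortConfig, GroupParams


@pytest.fixture
def small_params() -> GroupParams:
    """Fast-to-simulate group parameters for unit tests."""
    return GroupParams(
        cluster_size_mean=15.0,
        clusters_per_session_mean=6.0,
        session_duration_s=300.0,
    )


@pytest.fixture
def small_cohort_config(small_params) -> CohortConfig:
    return CohortConfig(
        n_control=4,
        n_mcao=3,
        sessions_per_subject=2,
        control_params=small_params,
        mcao_params=small_params,
        master_seed=42,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)
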