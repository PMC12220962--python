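import pytest

from mutburden import CohortConfig, simulate_cohort, synthetic_catalogue


@pytest.fixture(scope="session")
def catalogue():
    return synthetic_catalogue()


@pytest.fixture(scope="session")
def small_cohort():
    """A 10+10 human cohort with its ground truth (session-cached)."""
    cfg = CohortConfig(n_control=10, n_exposed=10, seed=7)
    return simulate_cohort(cfg)
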