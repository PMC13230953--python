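import pytest

import dualmem as dm


@pytest.fixture(scope="session")
def small_cohort():
    """Two-group cohort, 30 participants per group, default study structure."""
    return dm.generate_cohort(dm.CohortConfig(n_low=30, n_high=30, seed=42))


@pytest.fixture(scope="session")
def small_summaries(small_cohort):
    return dm.summarize_participants(small_cohort)


@pytest.fixture(scope="session")
def study_summaries():
    """Full study-sized cohort (118 low / 113 high) under default conditions."""
    return dm.summarize_participants(dm.generate_cohort(dm.CohortConfig(seed=7)))
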