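import pytest

from amypredict.cohort import apply_missingness, default_config, generate_cohort


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def cohort(config):
    """One default synthetic cohort, complete (no missingness)."""
    return generate_cohort(config, seed=7)


@pytest.fixture(scope="session")
def cohort_missing(config, cohort):
    """The same cohort with the configured per-variable missingness."""
    return apply_missingness(cohort, config, seed=8)
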