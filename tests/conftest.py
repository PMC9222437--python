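import pytest
from hypothesis import settings

import opsinhap as oh

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    """Bundled 11-haplotype cohort summary table."""
    return oh.load_table1_fixture()


@pytest.fixture(scope="session")
def cohort0():
    """Default synthetic association cohort (seed 0, published group sizes)."""
    return oh.generate_cohort(oh.CohortSpec(seed=0))


@pytest.fixture(scope="session")
def assay_summary0():
    """Per-haplotype skipping summaries of the default synthetic assay."""
    return oh.summarize_assay(oh.generate_assay(oh.AssaySpec(seed=0)))


@pytest.fixture(scope="session")
def ranking0(cohort0):
    """Split-halves ranking of the default cohort (1000 iterations)."""
    return oh.split_halves_rank(cohort0, oh.SplitHalvesConfig(1000, seed=0))
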