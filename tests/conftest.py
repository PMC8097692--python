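import pytest

from xcierosion import CohortConfig, generate_cohort

SMALL = CohortConfig(
    n_female_low=8,
    n_female_medium=2,
    n_female_high=8,
    n_male=6,
    n_genes_autosome=60,
    n_genes_x=12,
    plex_size=6,
    seed=11,
)


@pytest.fixture(scope="session")
def small_cohort():
    """A small but complete cohort shared across read-only tests."""
    return generate_cohort(SMALL)


@pytest.fixture(scope="session")
def study_cohort():
    """A cohort at the study's line counts (74 female, 46 male)."""
    return generate_cohort(CohortConfig(n_genes_autosome=120, n_genes_x=20, seed=5))
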