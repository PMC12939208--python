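import numpy as np
import pytest

from mutfm.synthetic_data import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort shared by read-only tests (do not mutate)."""
    cfg = SyntheticConfig(
        n_samples=120,
        n_genes=300,
        n_pathways=30,
        genes_per_pathway=8,
        n_informative=6,
        background_rate_range=(0.005, 0.05),
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
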