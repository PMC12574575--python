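import numpy as np
import pytest

from alcyte.simulate import SimConfig, default_planted_pairs, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A small mixed cohort with planted pairs and sex mismatches."""
    cfg = SimConfig(
        n_samples=80, n_cpgs=150, n_genes=300, n_high=26,
        n_signature_genes=60, planted_pairs=default_planted_pairs(4, subset_frac=0.4),
        n_sex_mismatches=3, seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def celltype_data():
    """One cell-resolved dataset with 10 planted pairs among 500 CpGs."""
    from alcyte.simulate import generate_celltype_cohort

    return generate_celltype_cohort(
        n_high=120, n_low=300, n_cpgs=500,
        planted_pairs=default_planted_pairs(10), seed=5,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
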