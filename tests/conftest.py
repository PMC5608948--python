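import numpy as np
import pandas as pd
import pytest

from omicdiv.synthetic import CohortDesign, simulate_cohort


@pytest.fixture(scope="session")
def small_design():
    return CohortDesign(
        n_per_pop=(40, 40, 40),
        n_snps=600,
        n_lipids=60,
        n_blocks=5,
        block_size=4,
        n_transcripts=50,
        n_mirnas=50,
        n_diff_features=5,
        missing_rate=0.01,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_cohort(small_design):
    return simulate_cohort(small_design)


@pytest.fixture(scope="session")
def default_cohort():
    """Cohort at the default (study-mirroring) design, shared across tests."""
    return simulate_cohort(CohortDesign(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def toy_genotypes():
    """Hand-constructed genotype matrix with known missingness patterns."""
    from omicdiv.io_qc import GenotypeMatrix

    dosages = pd.DataFrame(
        {
            "snp1": [0, 1, 2, 0, 1, 2],
            "snp2": [0, 0, np.nan, 1, 1, 2],
            "snp3": [np.nan, np.nan, np.nan, 0, 0, 0],
            "snp4": [2, 2, 2, 2, 2, 2],
        },
        index=[f"s{i}" for i in range(6)],
        dtype=float,
    )
    snp_meta = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2"],
            "pos": [100, 50_000, 150_000, 100_001],
            "ref": list("ACGT"),
            "alt": list("GTAC"),
        },
        index=dosages.columns,
    )
    sample_meta = pd.DataFrame(
        {"population": ["P1", "P1", "P1", "P2", "P2", "P2"]}, index=dosages.index
    )
    return GenotypeMatrix(dosages, snp_meta, sample_meta)
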