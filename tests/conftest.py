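import numpy as np
import pytest

from ursabc.coalsim import DemographicParams
from ursabc.synthdata import SyntheticConfig, generate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_adna_dataset():
    """A quick 4-locus autosomal dataset with enough variation to exercise
    the spectra (higher-than-default mutation rate, fewer samples)."""
    config = SyntheticConfig(
        n_loci=4, locus_length=500, n_uar=36, n_uma=36,
        true_params=DemographicParams(20_000.0, 5_000.0, 60_000.0),
        mu_per_site=1e-7, seed=101,
    )
    return generate_dataset(config)


@pytest.fixture(scope="session")
def mtdna_dataset_with_recurrence():
    """A single-locus mtDNA-style dataset with injected recurrent mutations
    so the four-gamete machinery has something to find."""
    config = SyntheticConfig(
        n_loci=1, locus_length=4000, n_uar=9, n_uma=26, mode="haploid-mtDNA",
        true_params=DemographicParams(100_000.0, 10_000.0, 30_000.0),
        mu_per_site=7.036e-8, recomb_equals_mu=False, n_recurrent=3, seed=77,
    )
    return generate_dataset(config)
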