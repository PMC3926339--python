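import numpy as np
import pytest

from diploidsim.fixtures import make_reference, synthetic_profile
from diploidsim.reference import ReferenceGenome


@pytest.fixture(scope="session")
def small_genome() -> ReferenceGenome:
    """200 kb, two chromosomes, 5% N-runs."""
    return make_reference(n_chroms=2, chrom_length=100_000, n_run_fraction=0.05, seed=11)


@pytest.fixture(scope="session")
def clean_genome() -> ReferenceGenome:
    """1 Mb single chromosome without N-runs (for spacing/ratio statistics)."""
    return make_reference(n_chroms=1, chrom_length=1_000_000, n_run_fraction=0.0, seed=12)


@pytest.fixture(scope="session")
def profile100():
    """Synthetic paired 100 bp quality profile with known truth distributions."""
    return synthetic_profile(read_length=100)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
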