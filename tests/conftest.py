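import numpy as np
import pytest

from mhc2sk import GeneratorConfig, encode_peptides, generate_dataset, load_blosum62_encoding
from mhc2sk.encoding import STANDARD_RESIDUES


@pytest.fixture(scope="session")
def enc():
    return load_blosum62_encoding()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


def random_peptides(rng, n, lo=9, hi=20):
    residues = list(STANDARD_RESIDUES)
    return ["".join(rng.choice(residues, size=rng.integers(lo, hi + 1))) for _ in range(n)]


@pytest.fixture(scope="session")
def small_peptides(rng):
    return random_peptides(rng, 20, lo=9, hi=16)


@pytest.fixture(scope="session")
def single_allele_dataset():
    """The allele-specific study condition: 200 peptides, noise 0.1, seed 42."""
    return generate_dataset(GeneratorConfig(n_alleles=1, peptides_per_allele=200, noise_sd=0.1, seed=42))


@pytest.fixture(scope="session")
def pan_dataset():
    """The default pan study condition: 10 alleles x 150 peptides, seed 42."""
    return generate_dataset(GeneratorConfig(seed=42))
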