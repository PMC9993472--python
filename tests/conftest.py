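import numpy as np
import pytest

from epiloop import synth
from epiloop.types import GeneModel, GenomicInterval


@pytest.fixture
def plus_gene():
    return GeneModel("gX", "gX", GenomicInterval("chr1", 5000, 9000, "+"), "+")


@pytest.fixture
def minus_gene():
    return GeneModel("gY", "gY", GenomicInterval("chr1", 100, 200, "-"), "-")


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Zero-noise synthetic bundle shared by recovery tests."""
    return synth.generate_dataset(synth.SynthConfig.noiseless(11))


@pytest.fixture(scope="session")
def noisy_bundle():
    """Default (noisy) synthetic bundle shared by robustness tests."""
    return synth.generate_dataset(synth.SynthConfig(seed=11))


def random_intervals(rng: np.random.Generator, n: int, n_chroms: int = 3):
    out = []
    for _ in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, 10_000))
        length = int(rng.integers(1, 500))
        out.append(GenomicInterval(chrom, start, start + length))
    return out
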