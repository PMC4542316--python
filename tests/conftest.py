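import numpy as np
import pytest

from epirewire.regions import GenomicRegion, RegionSet
from epirewire.synthetic import SyntheticConfig, generate


TOY_GENOME = {"chr1": 10_000, "chr2": 10_000}


@pytest.fixture
def toy_genome():
    return dict(TOY_GENOME)


def random_regions(rng, n, genome, name="rand", max_len=500):
    regs = []
    for i in range(n):
        chrom = list(genome)[int(rng.integers(0, len(genome)))]
        start = int(rng.integers(0, genome[chrom] - max_len))
        length = int(rng.integers(1, max_len))
        regs.append(GenomicRegion(chrom, start, start + length, ".", f"{name}_{i}"))
    return RegionSet(name, regs, genome)


@pytest.fixture(scope="session")
def small_config():
    # desk-scale study: same generative structure as the defaults, smaller sizes
    return SyntheticConfig(
        n_chroms=2,
        chrom_length=4_500_000,
        n_transcripts=300,
        n_peaks=600,
        n_superenhancers=6,
        n_celltypes=6,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate(small_config, seed=7)
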