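import numpy as np
import pytest

from enhancerdyn.genome import GenomeModel, GenomicInterval, PeakSet
from enhancerdyn.synth import ScenarioConfig, generate_scenario


@pytest.fixture(scope="session")
def small_config():
    return ScenarioConfig(
        n_chroms=2,
        chrom_length=2_500_000,
        n_pre_existing=40,
        n_de_novo=30,
        n_genes=150,
        seed=7,
    )


@pytest.fixture(scope="session")
def small_scenario(small_config, tmp_path_factory):
    out = tmp_path_factory.mktemp("scenario")
    ds, truth = generate_scenario(small_config, out)
    return ds, truth


@pytest.fixture
def tiny_genome():
    return GenomeModel(("chr1", "chr2"), (10_000, 5_000))


def random_peakset(rng, n, genome, max_len=200):
    intervals = []
    for _ in range(n):
        ci = int(rng.integers(len(genome.chrom_names)))
        chrom = genome.chrom_names[ci]
        length = genome.chrom_lengths[ci]
        start = int(rng.integers(0, length - max_len))
        end = start + int(rng.integers(1, max_len))
        intervals.append(GenomicInterval(chrom, start, end))
    return PeakSet(intervals)
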