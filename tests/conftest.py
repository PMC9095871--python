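import numpy as np
import pytest

from grr.genome import GenomeTable, GenomicInterval, RegionSet


@pytest.fixture
def toy_genome():
    return GenomeTable((("chr1", 1_000_000), ("chr2", 500_000)))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_region_set(rng, genome, n, max_len=5_000, name="random"):
    ivs = []
    for _ in range(n):
        chrom = genome.names[rng.integers(len(genome))]
        length = int(rng.integers(1, max_len))
        start = int(rng.integers(0, genome.length(chrom) - length))
        ivs.append(GenomicInterval(chrom, start, start + length))
    return RegionSet(name, ivs, genome)


def mask_of(rs, genome):
    """Per-base boolean coverage masks — the brute-force oracle for
    interval algebra."""
    return {
        c: np.zeros(genome.length(c), dtype=bool) for c in genome.names
    } | _fill(rs, genome)


def _fill(rs, genome):
    masks = {c: np.zeros(genome.length(c), dtype=bool) for c in genome.names}
    for iv in rs:
        masks[iv.chrom][iv.start:iv.end] = True
    return masks
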