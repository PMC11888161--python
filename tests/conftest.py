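import numpy as np
import pytest

from chipms import (
    GenomeLayout,
    GenomeSimSpec,
    Interval,
    IntervalSet,
    PeakSimSpec,
    simulate_genome_and_repeats,
    simulate_peaks,
)


@pytest.fixture
def toy_genome() -> GenomeLayout:
    return GenomeLayout((("chrA", 1000), ("chrB", 500)))


@pytest.fixture
def study_genome_catalog():
    """The default study-condition genome: 1 Mb, 5% clustered satellite."""
    return simulate_genome_and_repeats(GenomeSimSpec(seed=11))


def random_interval_set(rng: np.random.Generator, genome: GenomeLayout, max_intervals: int = 15, max_len: int = 400) -> IntervalSet:
    """A random (possibly overlapping/duplicated) interval set on a genome."""
    n = int(rng.integers(0, max_intervals + 1))
    ivs = []
    names = genome.names
    for _ in range(n):
        chrom = names[int(rng.integers(len(names)))]
        L = genome.length_of(chrom)
        length = int(rng.integers(1, min(max_len, L) + 1))
        start = int(rng.integers(0, L - length + 1))
        ivs.append(Interval(chrom, start, start + length))
    return IntervalSet(ivs, name="random")


def brute_force_overlap(a: IntervalSet, b: IntervalSet, genome: GenomeLayout) -> int:
    """Per-base membership-counting oracle for overlap_bp (small genomes only)."""
    total = 0
    for chrom, L in genome.entries:
        in_a = np.zeros(L, dtype=bool)
        in_b = np.zeros(L, dtype=bool)
        for iv in a:
            if iv.chrom == chrom:
                in_a[iv.start : iv.end] = True
        for iv in b:
            if iv.chrom == chrom:
                in_b[iv.start : iv.end] = True
        total += int((in_a & in_b).sum())
    return total
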