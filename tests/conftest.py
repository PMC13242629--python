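import numpy as np
import pytest

from breakscape.genome import GenomeDef, Interval
from breakscape.regions import build_region_catalog
from breakscape.simulate import make_toy_annotation, make_toy_genome


@pytest.fixture(scope="session")
def toy_genome():
    genome, _ = make_toy_genome([200_000, 150_000], seed=11, with_sequence=False)
    return genome


@pytest.fixture(scope="session")
def toy_annotation(toy_genome):
    return make_toy_annotation(toy_genome, 20, seed=11)


@pytest.fixture(scope="session")
def toy_catalog(toy_genome, toy_annotation):
    return build_region_catalog(toy_annotation, toy_genome)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


def random_intervals(rng, n, genome: GenomeDef, max_len=500):
    """Random interval list for oracle comparisons."""
    out = []
    for _ in range(n):
        k = rng.integers(0, len(genome.chrom_names))
        chrom = genome.chrom_names[k]
        L = genome.chrom_lengths[k]
        start = int(rng.integers(0, L - 1))
        end = int(min(L, start + 1 + rng.integers(0, max_len)))
        out.append(Interval(chrom, start, end))
    return out


def bp_set(intervals, genome: GenomeDef):
    """Brute-force per-base-pair membership set (small genomes only)."""
    return {
        (iv.chrom, p) for iv in intervals for p in range(iv.start, iv.end)
    }


def set_to_intervals(s):
    """Convert a bp set back to sorted disjoint intervals (oracle form)."""
    from itertools import groupby

    out = []
    by_chrom: dict[str, list[int]] = {}
    for chrom, p in s:
        by_chrom.setdefault(chrom, []).append(p)
    for chrom in sorted(by_chrom):
        pts = sorted(by_chrom[chrom])
        start = prev = pts[0]
        for p in pts[1:]:
            if p != prev + 1:
                out.append(Interval(chrom, start, prev + 1))
                start = p
            prev = p
        out.append(Interval(chrom, start, prev + 1))
    return out
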