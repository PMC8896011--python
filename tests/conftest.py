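import numpy as np
import pytest

from teenrich import (
    GenomeLayout,
    GenomicInterval,
    IntervalSet,
    SubfamilySpec,
    SyntheticGenomeSpec,
    make_genome,
)


@pytest.fixture
def toy_layout():
    return GenomeLayout.from_dict({"chr1": 10_000, "chr2": 5_000})


@pytest.fixture
def mb_layout():
    return GenomeLayout.from_dict({"chr1": 1_000_000})


def random_interval_set(rng, layout, n, max_len=500):
    """Uniform random intervals over a layout (test helper)."""
    chroms = list(layout.chrom_names)
    ivs = []
    for i in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        L = int(rng.integers(1, max_len + 1))
        limit = layout.chrom_lengths[chrom] - L
        s = int(rng.integers(0, limit + 1))
        ivs.append(GenomicInterval(chrom, s, s + L, ".", f"iv{i}"))
    return IntervalSet(ivs, layout)


@pytest.fixture(scope="session")
def small_genome():
    """Compact synthetic genome shared by read-only tests."""
    spec = SyntheticGenomeSpec(
        seed=42,
        chrom_lengths={"chr1": 300_000, "chr2": 200_000},
        subfamilies=[
            SubfamilySpec("L1PA1", 2, 3, 1.0, {"orf2_5p": True, "orf2_3p": True}, True),
            SubfamilySpec("L1PA7", 2, 4, 10.0, {"orf2_5p": True, "orf2_3p": True}, False),
            SubfamilySpec("L1PA17", 2, 4, 24.0, {"orf2_5p": False, "orf2_3p": False}, False),
        ],
    )
    return make_genome(spec)


def brute_force_overlap(a, b):
    """All-pairs any-overlap oracle: list of a-intervals hitting some b-interval."""
    hits = []
    for iva in a:
        if any(
            iva.chrom == ivb.chrom and iva.start < ivb.end and ivb.start < iva.end
            for ivb in b
        ):
            hits.append(iva)
    return hits
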