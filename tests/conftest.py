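import numpy as np
import pytest

from atacqc import (
    GeneModelRecord,
    GenomicInterval,
    Genome,
    HotspotSet,
    PositionFrequencyMatrix,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_pfm():
    # strongly informative 11-wide motif, consensus TGACGTCATTG
    counts = np.full((4, 11), 1.0)
    for j, base in enumerate("TGACGTCATTG"):
        counts["ACGT".index(base), j] = 40.0
    return PositionFrequencyMatrix(counts, motif_id="TOY1", name="toy")


@pytest.fixture
def toy_genes():
    return [
        GeneModelRecord("chr1", "+", 10_000, 13_000,
                        exons=[(10_000, 10_200), (11_000, 11_150), (12_800, 13_000)],
                        name="geneA"),
        GeneModelRecord("chr1", "-", 30_000, 33_000,
                        exons=[(30_000, 30_200), (31_500, 31_650), (32_800, 33_000)],
                        name="geneB"),
    ]


def random_hotspots(rng, n, span=100_000, max_len=400, chrom="chr1", label="X"):
    starts = rng.integers(0, span, size=n)
    lengths = rng.integers(1, max_len, size=n)
    ivs = [GenomicInterval(chrom, int(s), int(s + l)) for s, l in zip(starts, lengths)]
    return HotspotSet(label, ivs)


@pytest.fixture
def random_hotspots_factory():
    return random_hotspots


def brute_force_covered(start, end, intervals):
    """Per-base oracle: bases of [start, end) covered by any interval."""
    covered = set()
    for iv in intervals:
        covered.update(range(max(start, iv.start), min(end, iv.end)))
    return len(covered)


@pytest.fixture
def per_base_oracle():
    return brute_force_covered


@pytest.fixture
def tiny_genome():
    rng = np.random.default_rng(3)
    seq = "".join(rng.choice(list("ACGT"), size=12_000))
    return Genome({"chr1": seq})
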