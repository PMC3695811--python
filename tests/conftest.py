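import numpy as np
import pytest

from senscall.intervals_io import AlignedRead, GenomicInterval, TargetSet, merge_intervals


def make_read(
    name="r1",
    chrom="chr1",
    pos=0,
    cigar=(("M", 10),),
    bases=None,
    quals=None,
    qual=30,
    **kw,
):
    """Convenience AlignedRead builder with consistent bases/quals."""
    read_len = sum(n for op, n in cigar if op in "MIS")
    if bases is None:
        bases = "A" * read_len
    if quals is None:
        quals = (qual,) * read_len
    return AlignedRead(
        name=name, chrom=chrom, pos=pos, cigar=tuple(cigar),
        bases=bases, quals=tuple(quals), **kw,
    )


@pytest.fixture
def simple_target():
    return TargetSet([GenomicInterval("chr1", 0, 20)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_intervals(rng, n=1000, span=5000, max_len=80, chroms=("chr1", "chr2")):
    out = []
    for _ in range(n):
        chrom = chroms[int(rng.integers(len(chroms)))]
        start = int(rng.integers(0, span - 1))
        length = int(rng.integers(1, max_len))
        out.append(GenomicInterval(chrom, start, min(start + length, span)))
    return out


def brute_force_union_length(intervals, span=5000, chroms=("chr1", "chr2")):
    """Boolean position-mask oracle for merged interval length."""
    total = 0
    for chrom in chroms:
        mask = np.zeros(span, dtype=bool)
        for iv in intervals:
            if iv.chrom == chrom:
                mask[iv.start : iv.end] = True
        total += int(mask.sum())
    return total


def brute_force_depth(reads, target):
    """O(reads x positions) depth oracle: M and D consume reference."""
    depths = []
    for chrom, pos in target.positions():
        d = 0
        for r in reads:
            if r.chrom == chrom and r.pos <= pos < r.pos + r.ref_span:
                d += 1
        depths.append(d)
    return np.array(depths)
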