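import numpy as np
import pandas as pd
import pytest

from hushmap import Genome, IntervalSet, TagTrack


@pytest.fixture
def toy_genome() -> Genome:
    return Genome({"chr1": 100_000, "chr2": 50_000})


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_intervals(rows) -> IntervalSet:
    """rows: iterable of (chrom, start, end[, name[, score[, strand]]])."""
    full = []
    for r in rows:
        r = list(r) + [".", 0.0, "."][len(r) - 3:]
        full.append(tuple(r[:6]))
    return IntervalSet(
        pd.DataFrame(full, columns=["chrom", "start", "end", "name", "score", "strand"])
    )


def make_track(positions, strands=None, total_aligned=None, chrom="chr1") -> TagTrack:
    pos = np.asarray(positions, dtype=np.int64)
    st = None
    if strands is not None:
        st = {chrom: np.asarray([1 if s == "+" else -1 for s in strands], dtype=np.int8)}
    return TagTrack({chrom: pos}, st, total_aligned=total_aligned)


def random_merged_intervals(rng, n_max=20, chroms=("chr1", "chr2"),
                            genome_len=100_000) -> IntervalSet:
    """Random non-self-overlapping interval set for oracle comparisons."""
    rows = []
    for chrom in chroms:
        n = int(rng.integers(1, n_max // len(chroms) + 1))
        starts = np.sort(rng.choice(genome_len - 500, size=n, replace=False))
        ends = starts + rng.integers(50, 400, size=n)
        keep_s, keep_e = [starts[0]], [ends[0]]
        for s, e in zip(starts[1:], ends[1:]):
            if s > keep_e[-1]:
                keep_s.append(s)
                keep_e.append(e)
        rows.extend((chrom, int(s), int(e)) for s, e in zip(keep_s, keep_e))
    return make_intervals(rows)
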