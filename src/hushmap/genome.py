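"""Genomic interval algebra, single-base tag tracks, and overlap statistics.

All coordinates are 0-based, half-open (BED convention).  Intervals carry an
optional strand; tags are single-base positions with a strand.  The interval
overlap test mirrors the classic "available slots" null of interval-overlap
Fisher statistics: the genome is divided into ``G / (mean_len_A + mean_len_B)``
slots and the 2x2 table counts overlapping pairs, lone-A, lone-B and empty
slots.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd
from scipy import stats

UNSTRANDED = "."
_BED_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


class BedParseError(ValueError):
    """Raised for malformed BED records; message names the offending line."""


class ContractError(ValueError):
    """A precondition of an operation was violated."""


# ---------------------------------------------------------------------------
# Genome


@dataclass(frozen=True)
class Genome:
    """Chromosome name -> length (bp).  ``total_length`` is the genome size G."""

    sizes: Mapping[str, int]

    def __post_init__(self) -> None:
        for chrom, length in self.sizes.items():
            if length <= 0:
                raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")

    @property
    def total_length(self) -> int:
        return int(sum(self.sizes.values()))

    @property
    def chromosomes(self) -> list[str]:
        return list(self.sizes)

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sizes

    def __getitem__(self, chrom: str) -> int:
        return int(self.sizes[chrom])

    @classmethod
    def from_chrom_sizes(cls, path: str) -> "Genome":
        sizes: dict[str, int] = {}
        with open(path) as fh:
            for i, line in enumerate(fh, start=1):
                if not line.strip():
                    continue
                fields = line.split()
                if len(fields) < 2:
                    raise BedParseError(f"{path}:{i}: expected two columns, got {line!r}")
                sizes[fields[0]] = int(fields[1])
        return cls(sizes)

    def to_chrom_sizes(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom, length in self.sizes.items():
                fh.write(f"{chrom}\t{length}\n")


# ---------------------------------------------------------------------------
# Intervals


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = UNSTRANDED
    name: str = "."
    score: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", UNSTRANDED):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2


class IntervalSet:
    """An ordered (chrom, start, end) collection of genomic intervals.

    Backed by a pandas DataFrame with BED6 columns; always kept sorted.
    Duplicates are allowed; operations that require merged input check for
    self-overlap explicitly.
    """

    def __init__(self, frame: pd.DataFrame, sort: bool = True):
        df = frame.copy()
        for col, default in (("name", "."), ("score", 0.0), ("strand", UNSTRANDED)):
            if col not in df.columns:
                df[col] = default
        df = df[_BED_COLUMNS]
        df["start"] = df["start"].astype(np.int64)
        df["end"] = df["end"].astype(np.int64)
        if (df["start"] < 0).any() or (df["end"] <= df["start"]).any():
            bad = df.index[(df["start"] < 0) | (df["end"] <= df["start"])][0]
            raise ValueError(f"invalid interval at input row {bad}: start/end malformed")
        if sort:
            df = df.sort_values(["chrom", "start", "end"], kind="mergesort")
        self._df = df.reset_index(drop=True)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_intervals(cls, intervals: Iterable[GenomicInterval]) -> "IntervalSet":
        rows = [
            (iv.chrom, iv.start, iv.end, iv.name, iv.score, iv.strand)
            for iv in intervals
        ]
        return cls(pd.DataFrame(rows, columns=_BED_COLUMNS))

    @classmethod
    def from_arrays(cls, chrom, start, end, name=None, score=None, strand=None) -> "IntervalSet":
        n = len(start)
        df = pd.DataFrame(
            {
                "chrom": chrom if not isinstance(chrom, str) else [chrom] * n,
                "start": start,
                "end": end,
                "name": name if name is not None else ["."] * n,
                "score": score if score is not None else np.zeros(n),
                "strand": strand if strand is not None else [UNSTRANDED] * n,
            }
        )
        return cls(df)

    # -- basic protocol -----------------------------------------------------

    @property
    def frame(self) -> pd.DataFrame:
        return self._df

    def __len__(self) -> int:
        return len(self._df)

    def __iter__(self) -> Iterator[GenomicInterval]:
        for row in self._df.itertuples(index=False):
            yield GenomicInterval(row.chrom, int(row.start), int(row.end),
                                  row.strand, row.name, float(row.score))

    def __getitem__(self, i: int) -> GenomicInterval:
        row = self._df.iloc[i]
        return GenomicInterval(row.chrom, int(row.start), int(row.end),
                               row.strand, row.name, float(row.score))

    @property
    def mean_length(self) -> float:
        if len(self) == 0:
            raise ContractError("mean length undefined for an empty interval set")
        return float((self._df["end"] - self._df["start"]).mean())

    def subset(self, mask) -> "IntervalSet":
        return IntervalSet(self._df.loc[np.asarray(mask)], sort=False)

    def with_strand(self, strands) -> "IntervalSet":
        df = self._df.copy()
        df["strand"] = list(strands)
        return IntervalSet(df, sort=False)

    def by_chrom(self) -> dict[str, tuple[np.ndarray, np.ndarray]]:
        """chrom -> (starts, ends), both sorted by start."""
        out = {}
        for chrom, sub in self._df.groupby("chrom", sort=False):
            out[chrom] = (sub["start"].to_numpy(), sub["end"].to_numpy())
        return out

    def is_self_overlap_free(self) -> bool:
        for _, (starts, ends) in self.by_chrom().items():
            if len(starts) > 1 and (starts[1:] < ends[:-1]).any():
                return False
        return True

    # -- interval algebra ---------------------------------------------------

    def merge(self, max_gap: int = 0) -> "IntervalSet":
        """Union intervals on the same chromosome that overlap or lie within
        ``max_gap`` bp of each other.  Name/score/strand are dropped."""
        if max_gap < 0:
            raise ContractError("max_gap must be >= 0")
        rows = []
        for chrom, (starts, ends) in self.by_chrom().items():
            cur_s, cur_e = int(starts[0]), int(ends[0])
            for s, e in zip(starts[1:], ends[1:]):
                if s <= cur_e + max_gap:
                    cur_e = max(cur_e, int(e))
                else:
                    rows.append((chrom, cur_s, cur_e))
                    cur_s, cur_e = int(s), int(e)
            rows.append((chrom, cur_s, cur_e))
        return IntervalSet(pd.DataFrame(rows, columns=["chrom", "start", "end"]))

    def slop(self, pad: int, genome: Genome | None = None) -> "IntervalSet":
        """Extend every interval by ``pad`` bp on both sides (clipped at 0 and,
        when a genome is given, at the chromosome end)."""
        df = self._df.copy()
        df["start"] = np.maximum(df["start"] - pad, 0)
        if genome is not None:
            limits = df["chrom"].map(dict(genome.sizes)).to_numpy()
            df["end"] = np.minimum(df["end"] + pad, limits)
        else:
            df["end"] = df["end"] + pad
        return IntervalSet(df)

    def overlaps_any(self, other: "IntervalSet") -> np.ndarray:
        """Boolean per interval of self: does it share >= 1 bp with any
        interval of ``other``?  ``other`` need not be merged."""
        result = np.zeros(len(self), dtype=bool)
        other_by_chrom = {}
        for chrom, (starts, ends) in other.by_chrom().items():
            other_by_chrom[chrom] = (starts, np.maximum.accumulate(ends))
        chroms = self._df["chrom"].to_numpy()
        starts = self._df["start"].to_numpy()
        ends = self._df["end"].to_numpy()
        for chrom in pd.unique(chroms):
            if chrom not in other_by_chrom:
                continue
            o_starts, o_maxend = other_by_chrom[chrom]
            idx = np.flatnonzero(chroms == chrom)
            k = np.searchsorted(o_starts, ends[idx], side="left")
            hit = (k > 0) & (o_maxend[np.maximum(k - 1, 0)] > starts[idx])
            result[idx] = hit
        return result

    def to_bed(self, path: str, bed6: bool = True) -> None:
        df = self._df.copy()
        cols = _BED_COLUMNS if bed6 else ["chrom", "start", "end"]
        df[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str, genome: Genome | None = None) -> IntervalSet:
    """Read a 3+ column BED file into a sorted :class:`IntervalSet`.

    Rows on chromosomes absent from ``genome`` are dropped with a warning
    reporting how many were rejected.  Malformed coordinates raise
    :class:`BedParseError` naming the line.
    """
    rows = []
    rejected = 0
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}:{i}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(f"{path}:{i}: non-integer coordinates") from exc
            if start < 0 or start >= end:
                raise BedParseError(f"{path}:{i}: require 0 <= start < end, got {start}, {end}")
            if genome is not None:
                if chrom not in genome:
                    rejected += 1
                    continue
                if end > genome[chrom]:
                    raise BedParseError(
                        f"{path}:{i}: end {end} beyond chromosome {chrom} length {genome[chrom]}"
                    )
            name = fields[3] if len(fields) > 3 else "."
            score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            strand = fields[5] if len(fields) > 5 else UNSTRANDED
            rows.append((chrom, start, end, name, score, strand))
    if rejected:
        warnings.warn(f"{path}: rejected {rejected} records on chromosomes absent from genome")
    return IntervalSet(pd.DataFrame(rows, columns=_BED_COLUMNS))


# ---------------------------------------------------------------------------
# Tag tracks


class TagTrack:
    """Single-base, stranded read tags with the library's total aligned count.

    Tags are the 5' end of each read on its own strand, one position per tag
    (multiplicities are expanded).  ``total_aligned`` defaults to the number of
    stored tags and is the denominator of the standard 1e6-per-aligned scaling.
    """

    def __init__(
        self,
        positions: Mapping[str, np.ndarray],
        strands: Mapping[str, np.ndarray] | None = None,
        total_aligned: int | None = None,
        track_id: str = "",
    ):
        self.positions: dict[str, np.ndarray] = {}
        self.strands: dict[str, np.ndarray] = {}
        n = 0
        for chrom, pos in positions.items():
            pos = np.asarray(pos, dtype=np.int64)
            if strands is not None and chrom in strands:
                st = np.asarray(strands[chrom], dtype=np.int8)
            else:
                st = np.ones(len(pos), dtype=np.int8)
            order = np.argsort(pos, kind="mergesort")
            self.positions[chrom] = pos[order]
            self.strands[chrom] = st[order]
            n += len(pos)
        self.n_tags = n
        if total_aligned is None:
            total_aligned = n
        if total_aligned < n:
            raise ContractError(
                f"total_aligned ({total_aligned}) smaller than stored tag count ({n})"
            )
        self.total_aligned = int(total_aligned)
        self.track_id = track_id

    # strand encoding: +1 = plus, -1 = minus

    def count(self, chrom: str, start: int, end: int, strand: int | None = None) -> int:
        if chrom not in self.positions:
            return 0
        pos = self.positions[chrom]
        lo = np.searchsorted(pos, start, side="left")
        hi = np.searchsorted(pos, end, side="left")
        if strand is None:
            return int(hi - lo)
        return int(np.count_nonzero(self.strands[chrom][lo:hi] == strand))

    def split_by_strand(self) -> tuple["TagTrack", "TagTrack"]:
        plus, minus = {}, {}
        for chrom, pos in self.positions.items():
            st = self.strands[chrom]
            plus[chrom] = pos[st > 0]
            minus[chrom] = pos[st < 0]
        return (
            TagTrack(plus, total_aligned=self.total_aligned, track_id=self.track_id + "+"),
            TagTrack(minus, total_aligned=self.total_aligned, track_id=self.track_id + "-"),
        )

    @classmethod
    def from_plus_minus(cls, plus: "TagTrack", minus: "TagTrack",
                        total_aligned: int | None = None, track_id: str = "") -> "TagTrack":
        positions, strands = {}, {}
        for chrom in set(plus.positions) | set(minus.positions):
            p = plus.positions.get(chrom, np.empty(0, dtype=np.int64))
            m = minus.positions.get(chrom, np.empty(0, dtype=np.int64))
            positions[chrom] = np.concatenate([p, m])
            strands[chrom] = np.concatenate(
                [np.ones(len(p), dtype=np.int8), -np.ones(len(m), dtype=np.int8)]
            )
        if total_aligned is None:
            total_aligned = plus.total_aligned + minus.total_aligned
        return cls(positions, strands, total_aligned=total_aligned, track_id=track_id)

    @classmethod
    def from_bed(cls, path: str, genome: Genome | None = None,
                 total_aligned: int | None = None, track_id: str = "") -> "TagTrack":
        """Read a tag BED (one row per tag; score column, when integral and
        positive, is honored as a collapsed-read multiplicity)."""
        ivs = read_bed(path, genome)
        df = ivs.frame
        mult = df["score"].to_numpy()
        mult = np.where((mult > 0) & (mult == np.floor(mult)), mult, 1).astype(np.int64)
        positions, strands = {}, {}
        for chrom, sub in df.assign(mult=mult).groupby("chrom", sort=False):
            positions[chrom] = np.repeat(sub["start"].to_numpy(), sub["mult"].to_numpy())
            st = np.where(sub["strand"].to_numpy() == "-", -1, 1).astype(np.int8)
            strands[chrom] = np.repeat(st, sub["mult"].to_numpy())
        return cls(positions, strands, total_aligned=total_aligned,
                   track_id=track_id or path)

    def to_bed(self, path: str) -> None:
        with open(path, "w") as fh:
            for chrom in self.positions:
                pos, st = self.positions[chrom], self.strands[chrom]
                for p, s in zip(pos, st):
                    fh.write(f"{chrom}\t{p}\t{p + 1}\t.\t1\t{'+' if s > 0 else '-'}\n")


def count_tags(track: TagTrack, interval: GenomicInterval, strand_mode: str = "both") -> int:
    """Tags of ``track`` with position in [start, end) matching ``strand_mode``
    (one of both/+/-/sense/antisense; sense modes need a stranded interval)."""
    if strand_mode == "both":
        return track.count(interval.chrom, interval.start, interval.end)
    if strand_mode in ("+", "-"):
        return track.count(interval.chrom, interval.start, interval.end,
                           strand=1 if strand_mode == "+" else -1)
    if strand_mode in ("sense", "antisense"):
        if interval.strand == UNSTRANDED:
            raise ContractError(f"{strand_mode} counting requires a stranded interval")
        sense = 1 if interval.strand == "+" else -1
        strand = sense if strand_mode == "sense" else -sense
        return track.count(interval.chrom, interval.start, interval.end, strand=strand)
    raise ContractError(f"unknown strand_mode {strand_mode!r}")


# ---------------------------------------------------------------------------
# Coverage / bedGraph


def tag_coverage(track: TagTrack, genome: Genome, scale: bool = True) -> dict[str, np.ndarray]:
    """Per-base tag coverage; scaled by 1e6/total_aligned when ``scale``."""
    factor = 1e6 / track.total_aligned if scale else 1.0
    cov = {}
    for chrom, length in genome.sizes.items():
        pos = track.positions.get(chrom)
        if pos is None or len(pos) == 0:
            cov[chrom] = np.zeros(length)
        else:
            cov[chrom] = np.bincount(pos, minlength=length).astype(float) * factor
    return cov


def write_bedgraph(cov: Mapping[str, np.ndarray], path: str) -> None:
    """Write per-base coverage as a 4-column bedGraph with run-length-collapsed
    equal-value spans; zero runs are omitted."""
    with open(path, "w") as fh:
        for chrom, values in cov.items():
            values = np.asarray(values, dtype=float)
            if not np.isfinite(values).all():
                raise ValueError(f"non-finite coverage on {chrom}")
            if len(values) == 0:
                continue
            change = np.flatnonzero(np.diff(values)) + 1
            starts = np.concatenate([[0], change])
            ends = np.concatenate([change, [len(values)]])
            for s, e in zip(starts, ends):
                v = float(values[s])
                if v != 0.0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{v!r}\n")


def read_bedgraph(path: str, genome: Genome) -> dict[str, np.ndarray]:
    cov = {chrom: np.zeros(length) for chrom, length in genome.sizes.items()}
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith(("track", "#")):
                continue
            chrom, start, end, value = line.split()
            if chrom not in cov:
                raise BedParseError(f"{path}:{i}: unknown chromosome {chrom}")
            cov[chrom][int(start):int(end)] = float(value)
    return cov


# ---------------------------------------------------------------------------
# Interval-overlap Fisher statistic


@dataclass
class OverlapFisherResult:
    n11: int  # (A, B) pairs sharing >= 1 bp
    n12: int  # A intervals with no B overlap
    n21: int  # B intervals with no A overlap
    n22: int  # remaining empty genome slots
    odds_ratio: float
    p_two_sided: float

    @property
    def table(self) -> np.ndarray:
        return np.array([[self.n11, self.n12], [self.n21, self.n22]])


def _pair_counts(A: IntervalSet, B: IntervalSet) -> tuple[int, int]:
    """(number of overlapping (a, b) pairs, number of A intervals with >= 1
    overlap).  Requires B self-overlap free so its ends are sorted."""
    n_pairs = 0
    n_a_hit = 0
    b_by_chrom = B.by_chrom()
    for chrom, (a_starts, a_ends) in A.by_chrom().items():
        if chrom not in b_by_chrom:
            continue
        b_starts, b_ends = b_by_chrom[chrom]
        per_a = (
            np.searchsorted(b_starts, a_ends, side="left")
            - np.searchsorted(b_ends, a_starts, side="right")
        )
        n_pairs += int(per_a.sum())
        n_a_hit += int(np.count_nonzero(per_a > 0))
    return n_pairs, n_a_hit


def odds_ratio_from_table(n11: int, n12: int, n21: int, n22: int,
                          haldane: bool = False) -> float:
    if haldane:
        return ((n11 + 0.5) * (n22 + 0.5)) / ((n12 + 0.5) * (n21 + 0.5))
    if n11 * n22 == 0:
        return 0.0
    if n12 * n21 == 0:
        return math.inf
    return (n11 * n22) / (n12 * n21)


def fisher_overlap(A: IntervalSet, B: IntervalSet, genome: Genome,
                   haldane: bool = False) -> OverlapFisherResult:
    """Interval-overlap association between two merged interval sets.

    The 2x2 table is: n11 = overlapping (A, B) pairs; n12 = A intervals with
    no overlap; n21 = B intervals with no overlap; n22 = max(0,
    floor(G / (mean_len_A + mean_len_B)) - n11 - n12 - n21).  The odds ratio is
    (n11*n22)/(n12*n21) with 0 and +inf conventions for zero cells (or the
    Haldane 0.5 correction when requested); the p-value is the two-sided
    Fisher exact test on the table.
    """
    if len(A) == 0 or len(B) == 0:
        raise ContractError("fisher_overlap requires non-empty interval sets")
    for label, s in (("A", A), ("B", B)):
        if not s.is_self_overlap_free():
            raise ContractError(
                f"fisher_overlap requires merged input; set {label} has self-overlap "
                "(call .merge() first)"
            )
    n11, n_a_hit = _pair_counts(A, B)
    n11_check, n_b_hit = _pair_counts(B, A)
    assert n11 == n11_check
    n12 = len(A) - n_a_hit
    n21 = len(B) - n_b_hit
    slots = int(genome.total_length // (A.mean_length + B.mean_length))
    n22 = max(0, slots - n11 - n12 - n21)
    oddsr = odds_ratio_from_table(n11, n12, n21, n22, haldane=haldane)
    _, p = stats.fisher_exact([[n11, n12], [n21, n22]], alternative="two-sided")
    return OverlapFisherResult(n11, n12, n21, n22, oddsr, float(p))
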