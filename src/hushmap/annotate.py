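"""Repeat-family, trinucleotide, and gene-feature annotation analysis per
region class: binary presence heatmaps, class-vs-class category enrichment,
strand-aware trinucleotide densities, TTS-overlap fractions, and
TSS/midpoint/TTS meta-profiles.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import (ContractError, Genome, IntervalSet, TagTrack, read_bed)
from .maps import AggregateProfile, HeatmapMatrix, _check_geometry, bootstrap_band, build_heatmap
from .peaks import RegionClassification

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def read_fasta(path: str):
    """Open an (indexed) FASTA file for region sequence queries."""
    import pyfaidx

    return pyfaidx.Fasta(path, as_raw=True)


# ---------------------------------------------------------------------------
# Annotation track


class AnnotationTrack:
    """Intervals each carrying exactly one category label (repeat family,
    exon, TSS, TTS, ...).  The category lives in the BED name column."""

    def __init__(self, intervals: IntervalSet):
        self.intervals = intervals

    @property
    def categories(self) -> list[str]:
        return sorted(self.intervals.frame["name"].unique())

    def subset(self, category: str) -> IntervalSet:
        if category not in self.categories:
            raise ContractError(
                f"unknown category {category!r}; vocabulary: {self.categories}"
            )
        return self.intervals.subset(
            (self.intervals.frame["name"] == category).to_numpy()
        )

    @classmethod
    def from_bed(cls, path: str, genome: Genome | None = None) -> "AnnotationTrack":
        return cls(read_bed(path, genome))


# ---------------------------------------------------------------------------
# Presence heatmaps (Fig 3C-style repeat-position maps)


def presence_matrix(
    annot: AnnotationTrack,
    regions: IntervalSet,
    half_width: int = 5000,
    bin_size: int = 50,
    category: str | None = None,
) -> HeatmapMatrix:
    """Binary heatmap: bin value 1 iff >= 1 annotated bp of the category
    overlaps the bin's genomic span; '-' rows are column-reversed exactly as
    in the signal heatmaps."""
    n_bins = _check_geometry(half_width, bin_size)
    feats = annot.subset(category) if category is not None else annot.intervals
    by_chrom = feats.by_chrom()
    df = regions.frame
    values = np.zeros((len(df), n_bins))
    for i, row in enumerate(df.itertuples(index=False)):
        if row.chrom not in by_chrom:
            continue
        center = (int(row.start) + int(row.end)) // 2
        lo, hi = center - half_width, center + half_width
        starts, ends = by_chrom[row.chrom]
        maxend = np.maximum.accumulate(ends)
        k = np.searchsorted(starts, hi, side="left")
        j = k - 1
        # walk left over candidate features (few per window in practice)
        while j >= 0 and maxend[j] > lo:
            s, e = int(starts[j]), int(ends[j])
            if e > lo and s < hi:
                b0 = max(0, (s - lo) // bin_size)
                b1 = min(n_bins, -(-(e - lo) // bin_size))
                values[i, b0:b1] = 1.0
            j -= 1
        if row.strand == "-":
            values[i] = values[i, ::-1]
    return HeatmapMatrix(
        values, list(df["name"]), df["strand"].to_numpy(),
        half_width, bin_size, total_aligned=0,
        track_id=f"presence:{category or 'all'}",
    )


# ---------------------------------------------------------------------------
# Class-vs-class category enrichment (repeat families etc.)


@dataclass
class ClassEnrichment:
    category: str
    a_overlapping: int
    a_total: int
    b_overlapping: int
    b_total: int
    odds_ratio: float
    p_value: float
    q_value: float = float("nan")


def class_category_enrichment(
    classes: RegionClassification,
    annot: AnnotationTrack,
    class_a: str,
    class_b: str,
    categories: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-category Fisher exact test comparing the fraction of class-A vs.
    class-B regions that overlap the category, BH-corrected across categories.

    Degenerate tables with a zero margin (e.g. the category overlaps no region
    of either class) report odds ratio 1 and p = 1 by convention.
    """
    regions_a = classes.regions(class_a)
    regions_b = classes.regions(class_b)
    if len(regions_a) == 0 or len(regions_b) == 0:
        raise ContractError("both classes must be non-empty")
    rows = []
    for category in (categories or annot.categories):
        feats = annot.subset(category)
        a_hit = int(regions_a.overlaps_any(feats).sum())
        b_hit = int(regions_b.overlaps_any(feats).sum())
        table = np.array(
            [[a_hit, len(regions_a) - a_hit], [b_hit, len(regions_b) - b_hit]]
        )
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            oddsr, p = 1.0, 1.0
        else:
            num = table[0, 0] * table[1, 1]
            den = table[0, 1] * table[1, 0]
            oddsr = float("inf") if den == 0 else (0.0 if num == 0 else num / den)
            _, p = stats.fisher_exact(table, alternative="two-sided")
        rows.append((category, a_hit, len(regions_a), b_hit, len(regions_b),
                     oddsr, float(p)))
    df = pd.DataFrame(rows, columns=["category", "a_overlapping", "a_total",
                                     "b_overlapping", "b_total",
                                     "odds_ratio", "p_value"])
    df["q_value"] = multipletests(df["p_value"], method="fdr_bh")[1]
    return df


# ---------------------------------------------------------------------------
# Trinucleotide densities


def _fetch(seqs, chrom: str, start: int, end: int) -> str:
    """Sequence accessor for either a dict[str, str] or a pyfaidx.Fasta."""
    if isinstance(seqs, Mapping):
        if chrom not in seqs:
            raise ContractError(f"no sequence for chromosome {chrom}")
        return str(seqs[chrom][start:end])
    return str(seqs[chrom][start:end])


ALL_TRINUCLEOTIDES = tuple(
    a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
)


def trinucleotide_density(
    seqs, regions: IntervalSet, trinucleotides: Sequence[str] = ALL_TRINUCLEOTIDES
) -> pd.Series:
    """Pooled overlapping-window trinucleotide density over a region set.

    Counts are strand-aware ('-' regions use the reverse complement) and
    windows containing N are voided (excluded from numerator and denominator).
    """
    counts: Counter = Counter()
    valid_windows = 0
    for iv in regions:
        seq = _fetch(seqs, iv.chrom, iv.start, iv.end).upper()
        if len(seq) != iv.length:
            raise ContractError(
                f"region {iv.chrom}:{iv.start}-{iv.end} has no full sequence"
            )
        if iv.strand == "-":
            seq = revcomp(seq)
        for k in range(len(seq) - 2):
            w = seq[k:k + 3]
            if "N" in w:
                continue
            counts[w] += 1
            valid_windows += 1
    if valid_windows == 0:
        raise ContractError("no valid trinucleotide windows in the region set")
    return pd.Series(
        {t: counts.get(t, 0) / valid_windows for t in trinucleotides},
        name="density",
    )


def trinucleotide_enrichment(
    seqs,
    regions_by_class: Mapping[str, IntervalSet],
    background: IntervalSet,
    trinucleotides: Sequence[str] = ALL_TRINUCLEOTIDES,
) -> pd.DataFrame:
    """Per-class trinucleotide density ratios against a background region set."""
    bg = trinucleotide_density(seqs, background, trinucleotides)
    rows = []
    for label, regions in regions_by_class.items():
        dens = trinucleotide_density(seqs, regions, trinucleotides)
        for t in trinucleotides:
            ratio = dens[t] / bg[t] if bg[t] > 0 else float("nan")
            rows.append((label, t, dens[t], bg[t], ratio))
    return pd.DataFrame(
        rows, columns=["class", "trinucleotide", "density", "background_density", "ratio"]
    )


# ---------------------------------------------------------------------------
# Feature-overlap fractions (TTS overlap, Fig 6D-style)


def feature_overlap_fraction(
    regions: IntervalSet,
    features: AnnotationTrack | IntervalSet,
    category: str | None = None,
    slop: int = 500,
    genome: Genome | None = None,
) -> float:
    """Fraction of regions sharing >= 1 bp with any feature interval extended
    by +-slop bp."""
    if slop < 0:
        raise ContractError("slop must be >= 0")
    if len(regions) == 0:
        raise ContractError("empty region set")
    if isinstance(features, AnnotationTrack):
        feats = features.subset(category) if category is not None else features.intervals
    else:
        feats = features
    if len(feats) == 0:
        return 0.0
    if slop > 0:
        feats = feats.slop(slop, genome)
    return float(regions.overlaps_any(feats).mean())


# ---------------------------------------------------------------------------
# Gene anchors and meta-profiles (Fig 6E-style)


def gene_anchors(genes: IntervalSet, anchor: str) -> IntervalSet:
    """Unique oriented 1-bp anchor intervals at the TSS, midpoint, or TTS of
    stranded gene models; identical anchor coordinates are collapsed."""
    if anchor not in ("TSS", "midpoint", "TTS"):
        raise ContractError("anchor must be one of TSS, midpoint, TTS")
    rows = []
    for iv in genes:
        if iv.strand not in ("+", "-"):
            raise ContractError(f"gene {iv.name} lacks a strand")
        if anchor == "midpoint":
            pos = iv.center
        elif (anchor == "TSS") == (iv.strand == "+"):
            pos = iv.start
        else:
            pos = iv.end - 1
        rows.append((iv.chrom, pos, pos + 1, iv.name, 0.0, iv.strand))
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
    df = df.drop_duplicates(subset=["chrom", "start"], keep="first")
    return IntervalSet(df)


def meta_feature_profiles(
    track: TagTrack,
    genes: IntervalSet,
    anchor: str = "TSS",
    half_width: int = 2000,
    bin_size: int = 50,
    n_boot: int = 1000,
    stat: str = "median",
    seed: int = 0,
    strand_mode: str = "both",
    genome: Genome | None = None,
) -> AggregateProfile:
    """Bootstrap aggregate of coverage in oriented windows at the chosen gene
    anchor, in reads per billion per base per region."""
    anchors = gene_anchors(genes, anchor)
    h = build_heatmap(track, anchors, half_width, bin_size,
                      strand_mode=strand_mode, genome=genome)
    return bootstrap_band(h, n_boot=n_boot, stat=stat, seed=seed,
                          normalization="per_billion_per_base_per_region")
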