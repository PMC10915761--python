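"""CLIP RT-stop analysis: feature assignment, length- and
transcription-normalized enrichment, and RT-stop aggregates at classified
regions.

RT stops are single-base tags marking the nucleotide at which the protein is
crosslinked to RNA.  Enrichment per feature category f is the doubly
normalized ratio

    E_f = (S_f / S_tot) / [ (L_f / L_tot) * (T_f / T_bar) ]

where S_f is the stop count in f, L_f the union length of f's intervals,
T_f the sense nascent-transcription (PRO-seq) tag density in f, and T_bar the
length-weighted mean of the T_f.  Stops sampled proportionally to L_f * T_f
give E_f = 1 for every category, which is the fixed point the normalization
is validated against.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationTrack
from .genome import ContractError, IntervalSet, TagTrack
from .maps import AggregateProfile, aggregate, build_heatmap
from .peaks import HUSH_K9NEG, HUSH_K9POS, MPP8_ONLY, RegionClassification


def _containment_index(intervals: IntervalSet, stranded: bool):
    """Per (chrom[, strand]) merged interval arrays for point-containment."""
    index: dict = {}
    df = intervals.frame
    if stranded:
        keys = [(c, s) for c in df["chrom"].unique() for s in ("+", "-", ".")]
        for chrom, strand in keys:
            sub = df[(df["chrom"] == chrom) & (df["strand"] == strand)]
            if len(sub):
                merged = IntervalSet(sub).merge()
                index[(chrom, strand)] = merged.by_chrom()[chrom]
    else:
        for chrom, (starts, ends) in IntervalSet(df).merge().by_chrom().items():
            index[chrom] = (starts, ends)
    return index


def _contains(index, chrom: str, pos: np.ndarray, strand: np.ndarray | None):
    """Boolean: is each position inside any indexed interval (strand-aware
    when strand arrays are given; unstranded features match both strands)."""
    def check(key, mask):
        if key not in index:
            return np.zeros(mask.sum(), dtype=bool)
        starts, ends = index[key]
        k = np.searchsorted(starts, pos[mask], side="right")
        ok = k > 0
        ok[ok] = ends[k[ok] - 1] > pos[mask][ok]
        return ok

    if strand is None:
        return check(chrom, np.ones(len(pos), dtype=bool))
    out = np.zeros(len(pos), dtype=bool)
    for s_val, s_char in ((1, "+"), (-1, "-")):
        mask = strand == s_val
        if mask.any():
            hit = check((chrom, s_char), mask)
            hit |= check((chrom, "."), mask)
            out[mask] = hit
    return out


def assign_stops(
    stops: TagTrack,
    annot: AnnotationTrack,
    priority: Sequence[str],
    stranded: bool = True,
) -> dict[str, int]:
    """Partition RT stops over categories by a priority rule.

    Each stop goes to the single highest-priority category whose interval
    contains it on the same strand (unstranded feature intervals match either
    strand); stops matching no category count as ``unassigned``.  The returned
    counts always sum to the number of stored stops.
    """
    for category in priority:
        annot.subset(category)  # vocabulary check
    counts = {category: 0 for category in priority}
    counts["unassigned"] = 0
    indexes = {
        category: _containment_index(annot.subset(category), stranded)
        for category in priority
    }
    for chrom, pos in stops.positions.items():
        strand = stops.strands[chrom] if stranded else None
        unassigned = np.ones(len(pos), dtype=bool)
        for category in priority:
            if not unassigned.any():
                break
            sub = pos[unassigned]
            sub_strand = strand[unassigned] if strand is not None else None
            if stranded:
                hit = _contains(indexes[category], chrom, sub, sub_strand)
            else:
                hit = _contains(indexes[category], chrom, sub, None)
            counts[category] += int(hit.sum())
            idx = np.flatnonzero(unassigned)
            unassigned[idx[hit]] = False
        counts["unassigned"] += int(unassigned.sum())
    return counts


def clip_enrichment(
    stops: TagTrack,
    annot: AnnotationTrack,
    proseq: TagTrack,
    categories: Sequence[str] | None = None,
    stranded: bool = True,
    raw: bool = False,
    eps: float = 1.0,
) -> pd.DataFrame:
    """Length- and transcription-normalized RT-stop enrichment per category.

    ``raw=True`` returns the simpler S_f / (L_f * T_f) form instead of the
    doubly normalized ratio (see module docstring).  A pseudocount ``eps`` is
    applied to the stop and PRO-seq counts.
    """
    categories = list(categories or annot.categories)
    s_tot = stops.n_tags
    if s_tot == 0:
        raise ContractError("no RT stops supplied")
    stop_counts = assign_stops(stops, annot, categories, stranded=stranded)

    rows = []
    for category in categories:
        feats = annot.subset(category)
        merged = feats.merge()
        length = int((merged.frame["end"] - merged.frame["start"]).sum())
        if length == 0:
            raise ContractError(f"category {category!r} has zero length")
        pro = 0
        for iv in feats:
            if stranded and iv.strand in ("+", "-"):
                pro += proseq.count(iv.chrom, iv.start, iv.end,
                                    strand=1 if iv.strand == "+" else -1)
            else:
                pro += proseq.count(iv.chrom, iv.start, iv.end)
        rows.append((category, stop_counts[category], length, pro))

    df = pd.DataFrame(rows, columns=["category", "stops", "length", "pro_tags"])
    df["transcription"] = (df["pro_tags"] + eps) / df["length"]
    l_tot = df["length"].sum()
    t_bar = float((df["length"] * df["transcription"]).sum() / l_tot)
    if raw:
        df["enrichment"] = (df["stops"] + eps) / (df["length"] * df["transcription"])
    else:
        df["enrichment"] = ((df["stops"] + eps) / s_tot) / (
            (df["length"] / l_tot) * (df["transcription"] / t_bar)
        )
    df["stop_fraction"] = df["stops"] / s_tot
    return df


def clip_aggregate(
    stops: TagTrack,
    classes: RegionClassification,
    half_width: int = 5000,
    bin_size: int = 50,
    labels: Sequence[str] = (HUSH_K9POS, HUSH_K9NEG, MPP8_ONLY),
) -> dict[str, AggregateProfile]:
    """Mean RT-stop aggregate (tags per million) per region class.  An empty
    class yields a flagged empty profile (n_regions = 0), not an error."""
    out = {}
    for label in labels:
        regions = classes.regions(label)
        if len(regions) == 0:
            n_bins = 2 * half_width // bin_size
            centers = (-half_width + bin_size / 2 + bin_size * np.arange(n_bins))
            out[label] = AggregateProfile(centers, np.full(n_bins, np.nan),
                                          n_regions=0)
            continue
        h = build_heatmap(stops, regions, half_width, bin_size)
        out[label] = aggregate(h, stat="mean")
    return out
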