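"""Consolidated region superset, H3K9me3 enrichment calls, and class assignment.

Peaks from several ChIP factors/marks are consolidated into one non-overlapping
region superset by 1-D mean shift on peak midpoints.  Each superset region is
then tested for H3K9me3 enrichment (IP vs. input) with a negative-binomial
Wald test using median-of-ratios size factors and a method-of-moments
dispersion pooled over abundance bins, and assigned one of three classes:

* ``HUSH_K9POS``  — overlaps MPP8 and TASOR peaks, H3K9me3-enriched;
* ``HUSH_K9NEG``  — overlaps MPP8 and TASOR peaks, not H3K9me3-enriched;
* ``MPP8_ONLY``   — overlaps MPP8 but not TASOR peaks;
* ``UNCLASSIFIED`` — no MPP8 overlap.

Regions are finally oriented by the ratio of plus- to minus-strand nascent
transcription (PRO-seq) around the region center.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import ContractError, IntervalSet, TagTrack

HUSH_K9POS = "HUSH_K9POS"
HUSH_K9NEG = "HUSH_K9NEG"
MPP8_ONLY = "MPP8_ONLY"
UNCLASSIFIED = "UNCLASSIFIED"
CLASS_LABELS = (HUSH_K9POS, HUSH_K9NEG, MPP8_ONLY, UNCLASSIFIED)


# ---------------------------------------------------------------------------
# Mean-shift consolidation


@dataclass
class RegionSuperset:
    regions: IntervalSet          # name column carries the region id
    provenance: list[tuple[str, ...]]  # contributing input peak sets per region
    bandwidth: float

    @property
    def region_ids(self) -> list[str]:
        return list(self.regions.frame["name"])


def _meanshift_modes(midpoints: np.ndarray, bandwidth: float,
                     tol: float, max_iter: int) -> np.ndarray:
    """Flat-kernel 1-D mean shift: each point moves to the mean of the data
    midpoints within +-bandwidth of its current position."""
    data = np.sort(midpoints.astype(float))
    csum = np.concatenate([[0.0], np.cumsum(data)])
    x = midpoints.astype(float).copy()
    for _ in range(max_iter):
        lo = np.searchsorted(data, x - bandwidth, side="left")
        hi = np.searchsorted(data, x + bandwidth, side="right")
        new = (csum[hi] - csum[lo]) / (hi - lo)
        if np.max(np.abs(new - x)) < tol:
            x = new
            break
        x = new
    return x


def consolidate_meanshift(
    peak_sets: Mapping[str, IntervalSet] | Sequence[IntervalSet],
    bandwidth: float = 500.0,
    tol: float = 1e-3,
    max_iter: int = 200,
) -> RegionSuperset:
    """Consolidate peak sets into one superset of non-overlapping regions.

    Peak midpoints on each chromosome are clustered by flat-kernel mean shift
    (half-width = ``bandwidth``); peaks converging to the same mode form one
    region whose extent is the union of its member peaks.  Overlapping region
    unions are merged.  Every input peak is contained in exactly one region.
    """
    if bandwidth <= 0:
        raise ContractError("bandwidth must be > 0")
    if not isinstance(peak_sets, Mapping):
        peak_sets = {f"set{i}": s for i, s in enumerate(peak_sets)}
    frames = []
    for name, s in peak_sets.items():
        df = s.frame[["chrom", "start", "end"]].copy()
        df["source"] = name
        frames.append(df)
    all_peaks = pd.concat(frames, ignore_index=True)
    if len(all_peaks) == 0:
        raise ContractError("no peaks supplied")

    rows = []  # (chrom, start, end, provenance frozenset)
    for chrom, sub in all_peaks.groupby("chrom", sort=True):
        mids = ((sub["start"] + sub["end"]) // 2).to_numpy(dtype=float)
        modes = _meanshift_modes(mids, bandwidth, tol, max_iter)
        order = np.argsort(modes, kind="mergesort")
        sorted_modes = modes[order]
        # group converged points whose modes agree to sub-bp resolution
        cluster_tol = max(10.0 * tol, 0.5)
        breaks = np.flatnonzero(np.diff(sorted_modes) > cluster_tol) + 1
        groups = np.split(order, breaks)
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        sources = sub["source"].to_numpy()
        clusters = [
            (chrom, int(starts[g].min()), int(ends[g].max()), frozenset(sources[g]))
            for g in groups
        ]
        clusters.sort(key=lambda c: (c[1], c[2]))
        # merge overlapping unions so the superset is non-overlapping
        merged = [clusters[0]]
        for c in clusters[1:]:
            last = merged[-1]
            if c[1] < last[2]:
                merged[-1] = (chrom, last[1], max(last[2], c[2]), last[3] | c[3])
            else:
                merged.append(c)
        rows.extend(merged)

    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    width = len(str(len(rows)))
    df = pd.DataFrame(
        {
            "chrom": [r[0] for r in rows],
            "start": [r[1] for r in rows],
            "end": [r[2] for r in rows],
            "name": [f"region_{i:0{width}d}" for i in range(len(rows))],
        }
    )
    provenance = [tuple(sorted(r[3])) for r in rows]
    return RegionSuperset(IntervalSet(df, sort=False), provenance, bandwidth)


# ---------------------------------------------------------------------------
# Count table and NB enrichment test


@dataclass
class CountTable:
    counts: np.ndarray            # regions x samples, integer
    samples: list[str]
    region_ids: list[str]
    total_aligned: np.ndarray     # per sample
    size_factors: np.ndarray | None = None

    @classmethod
    def from_tracks(cls, regions: IntervalSet,
                    tracks: Mapping[str, TagTrack]) -> "CountTable":
        samples = list(tracks)
        counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
        df = regions.frame
        for j, name in enumerate(samples):
            track = tracks[name]
            for i, row in enumerate(df.itertuples(index=False)):
                counts[i, j] = track.count(row.chrom, int(row.start), int(row.end))
        return cls(counts, samples, list(df["name"]),
                   np.array([tracks[s].total_aligned for s in samples]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.region_ids, columns=self.samples)

    def set_library_size_factors(self) -> np.ndarray:
        """Size factors proportional to each library's total aligned tags,
        normalized to geometric mean 1.  Preferred when the counted regions
        are a targeted, enrichment-biased set (median-of-ratios would absorb
        genuine enrichment into the factors)."""
        factors = self.total_aligned.astype(float)
        factors = factors / np.exp(np.mean(np.log(factors)))
        self.size_factors = factors
        return factors


def compute_size_factors(table: CountTable) -> np.ndarray:
    """Median-of-ratios size factors, renormalized to geometric mean 1.

    For each region with all-positive counts, the ratio of each sample's count
    to the region's geometric mean is formed; the per-sample factor is the
    median ratio over such regions.
    """
    counts = table.counts
    if counts.shape[1] < 2:
        raise ContractError("size factors require >= 2 samples")
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ContractError(
            "no region with all-positive counts; consider adding pseudocounts"
        )
    logc = np.log(counts[positive].astype(float))
    log_geomean = logc.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logc - log_geomean, axis=0))
    factors /= np.exp(np.mean(np.log(factors)))
    table.size_factors = factors
    return factors


@dataclass
class NBTestResult:
    region_ids: list[str]
    log2_fold_change: np.ndarray
    p_value: np.ndarray
    q_value: np.ndarray
    call: np.ndarray              # boolean enrichment call
    mean_ip: np.ndarray
    mean_control: np.ndarray
    dispersion: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "log2_fold_change": self.log2_fold_change,
                "p_value": self.p_value,
                "q_value": self.q_value,
                "call": self.call,
                "mean_ip": self.mean_ip,
                "mean_control": self.mean_control,
                "dispersion": self.dispersion,
            },
            index=self.region_ids,
        )


def nb_enrichment_test(
    table: CountTable,
    ip_samples: Sequence[str],
    control_samples: Sequence[str],
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    n_dispersion_bins: int = 10,
) -> NBTestResult:
    """Per-region negative-binomial Wald test of IP vs. control enrichment.

    Counts are normalized by size factors (computed if absent).  The NB
    dispersion is estimated by method of moments from within-group variances
    and pooled (mean) across regions within abundance bins.  The Wald statistic
    is the log2 fold change over its delta-method standard error,
    ``var(log mu_hat) ~= (1/mu + dispersion)/n``; p-values are two-sided normal
    tails, corrected by Benjamini-Hochberg across all regions.  A region is
    called enriched when ``q <= alpha`` and ``log2FC >= lfc_min``.
    """
    if len(ip_samples) == 0 or len(control_samples) == 0:
        raise ContractError("both sample groups must be non-empty")
    if not 0 < alpha < 1:
        raise ContractError("alpha must lie in (0, 1)")
    if table.size_factors is None:
        compute_size_factors(table)
    idx = {s: j for j, s in enumerate(table.samples)}
    ip_j = [idx[s] for s in ip_samples]
    ct_j = [idx[s] for s in control_samples]
    norm = table.counts.astype(float) / table.size_factors[np.newaxis, :]

    mu_ip = norm[:, ip_j].mean(axis=1)
    mu_ct = norm[:, ct_j].mean(axis=1)
    overall = norm[:, ip_j + ct_j].mean(axis=1)

    # method-of-moments dispersion from within-group variance, pooled by dof
    dof = 0
    ss = np.zeros(len(overall))
    for cols in (ip_j, ct_j):
        if len(cols) >= 2:
            ss += norm[:, cols].var(axis=1, ddof=1) * (len(cols) - 1)
            dof += len(cols) - 1
    if dof == 0:
        raise ContractError(
            "dispersion estimation needs >= 2 replicates in at least one group"
        )
    var_within = ss / dof

    # pool moments within abundance bins: dispersion of a bin is
    # (mean within-group variance - mean count) / (mean count)^2, which is
    # unbiased when means are shared within the bin and errs conservative
    # (larger dispersion) when they are heterogeneous
    dispersion = np.full(len(overall), 1e-8)
    usable = overall > 0
    if usable.any():
        n_bins = int(min(n_dispersion_bins, max(1, usable.sum() // 50)))
        ranks = stats.rankdata(overall[usable], method="ordinal")
        bins = np.minimum((ranks - 1) * n_bins // usable.sum(), n_bins - 1).astype(int)
        pooled = np.full(n_bins, 1e-8)
        for b in range(n_bins):
            sel = bins == b
            if sel.any():
                m = float(overall[usable][sel].mean())
                v = float(var_within[usable][sel].mean())
                pooled[b] = max((v - m) / m**2, 1e-8)
        dispersion[usable] = pooled[bins]

    mu_ip_eff = np.maximum(mu_ip, 0.5)
    mu_ct_eff = np.maximum(mu_ct, 0.5)
    l2fc = np.log2(mu_ip_eff / mu_ct_eff)
    var_log = (1.0 / mu_ip_eff + dispersion) / len(ip_j) \
        + (1.0 / mu_ct_eff + dispersion) / len(ct_j)
    se_l2fc = np.sqrt(var_log) / np.log(2)
    z = l2fc / se_l2fc
    p = 2.0 * stats.norm.sf(np.abs(z))
    _, q, _, _ = multipletests(p, method="fdr_bh")
    call = (q <= alpha) & (l2fc >= lfc_min)
    return NBTestResult(list(table.region_ids), l2fc, p, q, call,
                        mu_ip, mu_ct, dispersion)


# ---------------------------------------------------------------------------
# Classification and orientation


class RegionClassification:
    """Per-region class labels with supporting evidence and orientation."""

    def __init__(self, frame: pd.DataFrame):
        self.frame = frame.reset_index(drop=True)

    @property
    def labels(self) -> np.ndarray:
        return self.frame["label"].to_numpy()

    def regions(self, label: str | None = None) -> IntervalSet:
        df = self.frame
        if label is not None:
            if label not in CLASS_LABELS:
                raise ContractError(f"unknown class label {label!r}")
            df = df[df["label"] == label]
        bed = df[["chrom", "start", "end"]].copy()
        bed["name"] = df["region_id"]
        bed["score"] = 0.0
        bed["strand"] = df["orientation"]
        return IntervalSet(bed, sort=False)

    def to_bed(self, path: str) -> None:
        df = self.frame
        cols = pd.DataFrame(
            {
                "chrom": df["chrom"],
                "start": df["start"],
                "end": df["end"],
                "name": df["region_id"],
                "score": 0,
                "strand": df["orientation"],
                "label": df["label"],
                "log2_fold_change": df["log2_fold_change"].round(4),
                "q_value": df["q_value"],
                "overlaps_mpp8": df["overlaps_mpp8"].astype(int),
                "overlaps_tasor": df["overlaps_tasor"].astype(int),
                "k9_call": df["k9_call"].astype(int),
            }
        )
        cols.to_csv(path, sep="\t", header=False, index=False)


def classify_regions(
    superset: RegionSuperset,
    mpp8: IntervalSet,
    tasor: IntervalSet,
    k9_calls: NBTestResult,
) -> RegionClassification:
    """Assign each superset region one of the three target classes.

    Only MPP8-overlapping regions are classified: TASOR overlap (>= 1 bp)
    makes a HUSH target, split into H3K9me3-positive/negative by the
    enrichment call; MPP8 without TASOR is MPP8-only; everything else is
    left unclassified.
    """
    ids = superset.region_ids
    if list(k9_calls.region_ids) != ids:
        raise ContractError("k9_calls are not indexed by the superset regions")
    has_mpp8 = superset.regions.overlaps_any(mpp8)
    has_tasor = superset.regions.overlaps_any(tasor)
    k9 = k9_calls.call
    labels = np.where(
        has_mpp8 & has_tasor & k9, HUSH_K9POS,
        np.where(
            has_mpp8 & has_tasor, HUSH_K9NEG,
            np.where(has_mpp8, MPP8_ONLY, UNCLASSIFIED),
        ),
    )
    df = superset.regions.frame
    frame = pd.DataFrame(
        {
            "region_id": ids,
            "chrom": df["chrom"].to_numpy(),
            "start": df["start"].to_numpy(),
            "end": df["end"].to_numpy(),
            "label": labels,
            "overlaps_mpp8": has_mpp8,
            "overlaps_tasor": has_tasor,
            "k9_call": k9,
            "log2_fold_change": k9_calls.log2_fold_change,
            "q_value": k9_calls.q_value,
            "orientation": "+",
        }
    )
    return RegionClassification(frame)


def orient_by_proseq(
    regions: IntervalSet,
    proseq_plus: TagTrack,
    proseq_minus: TagTrack,
    window: int = 1000,
) -> IntervalSet:
    """Strand each region by the ratio of plus- to minus-strand nascent
    transcription in [center - window, center + window); ties break to '+'."""
    if window <= 0:
        raise ContractError("window must be > 0")
    strands = []
    for iv in regions:
        lo = max(0, iv.center - window)
        hi = iv.center + window
        n_plus = proseq_plus.count(iv.chrom, lo, hi)
        n_minus = proseq_minus.count(iv.chrom, lo, hi)
        strands.append("+" if n_plus >= n_minus else "-")
    return regions.with_strand(strands)


# ---------------------------------------------------------------------------
# End-to-end classification pipeline


def run_classification(
    peak_sets: Mapping[str, IntervalSet],
    k9_ip_tracks: Mapping[str, TagTrack],
    k9_input_tracks: Mapping[str, TagTrack],
    proseq_plus: TagTrack,
    proseq_minus: TagTrack,
    bandwidth: float = 500.0,
    alpha: float = 0.05,
    lfc_min: float = 1.0,
    window: int = 1000,
    mpp8_key: str = "MPP8",
    tasor_key: str = "TASOR",
) -> tuple[RegionSuperset, RegionClassification, NBTestResult]:
    """Superset consolidation -> H3K9me3 NB test -> classification -> strand
    orientation, in one call.  ``peak_sets`` must include the MPP8 and TASOR
    peak sets under ``mpp8_key``/``tasor_key``."""
    for key in (mpp8_key, tasor_key):
        if key not in peak_sets:
            raise ContractError(f"peak_sets must contain {key!r}")
    superset = consolidate_meanshift(peak_sets, bandwidth=bandwidth)
    tracks = {**{f"ip_{k}": v for k, v in k9_ip_tracks.items()},
              **{f"ctrl_{k}": v for k, v in k9_input_tracks.items()}}
    table = CountTable.from_tracks(superset.regions, tracks)
    # library-size normalization: the superset is an enrichment-biased region
    # set, where median-of-ratios factors would soak up true enrichment
    table.set_library_size_factors()
    result = nb_enrichment_test(
        table,
        [f"ip_{k}" for k in k9_ip_tracks],
        [f"ctrl_{k}" for k in k9_input_tracks],
        alpha=alpha,
        lfc_min=lfc_min,
    )
    classification = classify_regions(
        superset, peak_sets[mpp8_key], peak_sets[tasor_key], result
    )
    oriented = orient_by_proseq(superset.regions, proseq_plus, proseq_minus, window)
    classification.frame["orientation"] = oriented.frame["strand"].to_numpy()
    return superset, classification, result
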