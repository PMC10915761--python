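"""Coverage heatmaps, aggregate profiles with bootstrap bands, differential
maps, and peak-shift / transcriptional-readthrough statistics.

A heatmap is a regions x position-bins matrix of tag counts binned by signed
distance from each region's center, scaled to tags per million aligned reads
(1e6 / total_aligned).  Minus-strand regions are stored with their column
order reversed so that "downstream in the sense direction" is always to the
right.  Aggregate profiles are per-bin row statistics; bootstrap bands come
from resampling rows with replacement and taking the 0.025/0.975 quantiles.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np

from .genome import ContractError, Genome, IntervalSet, TagTrack
from .peaks import (CLASS_LABELS, HUSH_K9NEG, HUSH_K9POS, MPP8_ONLY,
                    RegionClassification, UNCLASSIFIED)


@dataclass
class HeatmapMatrix:
    values: np.ndarray            # regions x bins; NaN marks out-of-bounds bins
    region_ids: list[str]
    strands: np.ndarray           # '+', '-', or '.' per region
    half_width: int
    bin_size: int
    total_aligned: int            # 0 for unit-less matrices (differences, presence)
    track_id: str = ""

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        return (-self.half_width + self.bin_size / 2
                + self.bin_size * np.arange(self.n_bins))

    @property
    def bin_edges(self) -> np.ndarray:
        return -self.half_width + self.bin_size * np.arange(self.n_bins + 1)

    def subset(self, mask) -> "HeatmapMatrix":
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask
        return replace(
            self,
            values=self.values[idx],
            region_ids=[self.region_ids[i] for i in idx],
            strands=self.strands[idx],
        )

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(f"# half_width={self.half_width} bin_size={self.bin_size} "
                     f"total_aligned={self.total_aligned} track_id={self.track_id}\n")
            centers = "\t".join(str(int(c)) if c == int(c) else str(c)
                                for c in self.bin_centers)
            fh.write(f"region_id\tstrand\t{centers}\n")
            for rid, strand, row in zip(self.region_ids, self.strands, self.values):
                vals = "\t".join("nan" if np.isnan(v) else f"{v:.6g}" for v in row)
                fh.write(f"{rid}\t{strand}\t{vals}\n")


@dataclass
class AggregateProfile:
    bin_centers: np.ndarray
    center: np.ndarray
    lower: np.ndarray | None = None
    upper: np.ndarray | None = None
    normalization: str = "per_million"
    stat: str = "mean"
    n_regions: int = 0

    def to_tsv(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write("bin_center\tcenter\tlower\tupper\n")
            lo = self.lower if self.lower is not None else [float("nan")] * len(self.center)
            hi = self.upper if self.upper is not None else [float("nan")] * len(self.center)
            for c, v, a, b in zip(self.bin_centers, self.center, lo, hi):
                fh.write(f"{c:g}\t{v:.6g}\t{a:.6g}\t{b:.6g}\n")


# ---------------------------------------------------------------------------
# Heatmap construction


def _check_geometry(half_width: int, bin_size: int) -> int:
    if half_width <= 0 or bin_size <= 0:
        raise ContractError("half_width and bin_size must be > 0")
    if (2 * half_width) % bin_size != 0:
        raise ContractError(
            f"bin_size {bin_size} must divide the window 2*{half_width}"
        )
    return 2 * half_width // bin_size


def build_heatmap(
    track: TagTrack,
    regions: IntervalSet,
    half_width: int = 5000,
    bin_size: int = 50,
    strand_mode: str = "both",
    genome: Genome | None = None,
) -> HeatmapMatrix:
    """Bin tags by signed distance from each region center.

    For a '+' (or unstranded) region, a tag at genomic position p falls in bin
    ``(p - center + half_width) // bin_size``; for a '-' region the distance
    is mirrored so the row is exactly the column-reversed '+' row.  Values are
    scaled by 1e6/total_aligned.  When a genome is supplied, bins extending
    beyond the chromosome are recorded as NaN (missing, not zero).
    """
    n_bins = _check_geometry(half_width, bin_size)
    df = regions.frame
    values = np.zeros((len(df), n_bins))
    for i, row in enumerate(df.itertuples(index=False)):
        center = (int(row.start) + int(row.end)) // 2
        lo, hi = center - half_width, center + half_width
        pos = track.positions.get(row.chrom)
        if pos is not None and len(pos):
            a = np.searchsorted(pos, max(lo, 0), side="left")
            b = np.searchsorted(pos, hi, side="left")
            window = pos[a:b]
            if strand_mode != "both":
                st = track.strands[row.chrom][a:b]
                if strand_mode in ("+", "-"):
                    want = 1 if strand_mode == "+" else -1
                elif strand_mode in ("sense", "antisense"):
                    if row.strand not in ("+", "-"):
                        raise ContractError(
                            f"{strand_mode} mode requires stranded regions"
                        )
                    sense = 1 if row.strand == "+" else -1
                    want = sense if strand_mode == "sense" else -sense
                else:
                    raise ContractError(f"unknown strand_mode {strand_mode!r}")
                window = window[st == want]
            window = window[window >= lo]
            if row.strand == "-":
                rel = center - window - 1 + half_width
            else:
                rel = window - center + half_width
            values[i] += np.bincount(rel // bin_size, minlength=n_bins)
        if genome is not None:
            chrom_len = genome[row.chrom]
            edges = center - half_width + bin_size * np.arange(n_bins + 1)
            bad = (edges[:-1] < 0) | (edges[1:] > chrom_len)
            if row.strand == "-":
                bad = bad[::-1]
            values[i, bad] = np.nan
    values *= 1e6 / track.total_aligned
    return HeatmapMatrix(
        values,
        list(df["name"]),
        df["strand"].to_numpy(),
        half_width,
        bin_size,
        track.total_aligned,
        track.track_id,
    )


def differential_matrix(a: HeatmapMatrix, b: HeatmapMatrix) -> HeatmapMatrix:
    """Elementwise ``a - b`` of scaled values (signed; total_aligned unset)."""
    if (a.region_ids != b.region_ids or a.half_width != b.half_width
            or a.bin_size != b.bin_size):
        raise ContractError("differential requires identical regions and geometry")
    return HeatmapMatrix(
        a.values - b.values,
        list(a.region_ids),
        a.strands.copy(),
        a.half_width,
        a.bin_size,
        total_aligned=0,
        track_id=f"{a.track_id}-{b.track_id}",
    )


# ---------------------------------------------------------------------------
# Row ordering


def central_mean(h: HeatmapMatrix, central_bp: int = 1000) -> np.ndarray:
    """Per-region mean of bins whose center lies within +-central_bp."""
    sel = np.abs(h.bin_centers) <= central_bp
    with np.errstate(invalid="ignore"):
        return np.nanmean(h.values[:, sel], axis=1)


def sort_by_class(
    classes: RegionClassification,
    k9: HeatmapMatrix,
    mpp8: HeatmapMatrix,
    tasor: HeatmapMatrix,
    central_bp: int = 1000,
) -> np.ndarray:
    """Row order for class-sorted heatmap layouts.

    Blocks follow HUSH_K9POS, HUSH_K9NEG, MPP8_ONLY (then UNCLASSIFIED);
    within a block rows descend by central H3K9me3 signal, then by combined
    MPP8+TASOR central signal, with ties broken by region id.
    """
    ids = list(classes.frame["region_id"])
    for h in (k9, mpp8, tasor):
        if h.region_ids != ids:
            raise ContractError("heatmaps and classification must share region order")
    block = {label: i for i, label in enumerate(CLASS_LABELS)}
    key_block = np.array([block[l] for l in classes.labels])
    key_k9 = np.nan_to_num(central_mean(k9, central_bp))
    key_mt = np.nan_to_num(central_mean(mpp8, central_bp)
                           + central_mean(tasor, central_bp))
    order = sorted(
        range(len(ids)),
        key=lambda i: (key_block[i], -key_k9[i], -key_mt[i], ids[i]),
    )
    return np.array(order)


# ---------------------------------------------------------------------------
# Aggregates


def _row_stat(values: np.ndarray, stat: str) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        if stat == "mean":
            return np.nanmean(values, axis=0)
        if stat == "median":
            return np.nanmedian(values, axis=0)
    raise ContractError(f"unknown statistic {stat!r}")


def _rows_for_normalization(h: HeatmapMatrix, normalization: str) -> np.ndarray:
    if normalization == "per_million":
        return h.values
    if normalization == "per_billion_per_base_per_region":
        if h.total_aligned <= 0:
            raise ContractError(
                "per-billion normalization needs a matrix with total_aligned set"
            )
        raw = h.values * (h.total_aligned / 1e6)
        return raw / h.bin_size * (1e9 / h.total_aligned)
    raise ContractError(f"unknown normalization {normalization!r}")


def aggregate(h: HeatmapMatrix, stat: str = "mean",
              normalization: str = "per_million") -> AggregateProfile:
    """Per-bin row statistic.  ``per_billion_per_base_per_region`` divides raw
    per-bin tag counts by (number of rows x bin_size) and scales by
    1e9/total_aligned; for the mean statistic this equals the stated
    "reads per billion per base per region" unit."""
    if h.values.shape[0] < 1:
        raise ContractError("aggregate needs at least one row")
    if normalization == "unit_scaled":
        return unit_scale(aggregate(h, stat=stat))
    rows = _rows_for_normalization(h, normalization)
    return AggregateProfile(h.bin_centers, _row_stat(rows, stat),
                            normalization=normalization, stat=stat,
                            n_regions=h.values.shape[0])


def bootstrap_band(h: HeatmapMatrix, n_boot: int = 1000, stat: str = "mean",
                   seed: int = 0,
                   normalization: str = "per_million") -> AggregateProfile:
    """Aggregate profile with a bootstrap (0.025, 0.975) band.

    Rows are resampled with replacement (resample size = number of rows)
    ``n_boot`` times; the band is the per-bin quantile pair across resamples.
    Deterministic for a fixed seed.
    """
    if n_boot < 1:
        raise ContractError("n_boot must be >= 1")
    rows = _rows_for_normalization(h, normalization)
    n = rows.shape[0]
    if n < 1:
        raise ContractError("bootstrap needs at least one row")
    rng = np.random.default_rng(seed)
    boot = np.empty((n_boot, rows.shape[1]))
    for b in range(n_boot):
        boot[b] = _row_stat(rows[rng.integers(0, n, size=n)], stat)
    lower = np.nanquantile(boot, 0.025, axis=0)
    upper = np.nanquantile(boot, 0.975, axis=0)
    return AggregateProfile(h.bin_centers, _row_stat(rows, stat), lower, upper,
                            normalization=normalization, stat=stat, n_regions=n)


def unit_scale(p: AggregateProfile) -> AggregateProfile:
    """Affinely rescale the profile so its center spans exactly [0, 1]."""
    finite = p.center[np.isfinite(p.center)]
    if len(finite) == 0:
        raise ContractError("cannot unit-scale an all-missing profile")
    lo, hi = float(finite.min()), float(finite.max())
    if hi == lo:
        raise ContractError("cannot unit-scale a constant profile (shape undefined)")
    scale = lambda x: (x - lo) / (hi - lo)  # noqa: E731
    return AggregateProfile(
        p.bin_centers,
        scale(p.center),
        scale(p.lower) if p.lower is not None else None,
        scale(p.upper) if p.upper is not None else None,
        normalization="unit_scaled",
        stat=p.stat,
        n_regions=p.n_regions,
    )


def subtract_baseline(p: AggregateProfile, flank_frac: float = 0.1) -> AggregateProfile:
    """Subtract the mean of the outermost ``flank_frac`` bins on each side and
    clip at zero.  Used before centroid computations so that uniform background
    does not drag the signal-weighted position toward the window center."""
    k = max(1, int(round(flank_frac * len(p.center))))
    flank = np.concatenate([p.center[:k], p.center[-k:]])
    baseline = float(np.nanmean(flank))
    return replace(p, center=np.clip(p.center - baseline, 0.0, None),
                   lower=None, upper=None)


# ---------------------------------------------------------------------------
# Shift and readthrough statistics


def centroid_shift(wt: AggregateProfile, ko: AggregateProfile) -> float:
    """Difference of signal-weighted mean positions (KO - WT) in bp; positive
    means the KO profile sits downstream in the sense orientation."""
    if len(wt.bin_centers) != len(ko.bin_centers) or \
            not np.allclose(wt.bin_centers, ko.bin_centers):
        raise ContractError("profiles must share bins")
    centroids = []
    for p in (wt, ko):
        w = np.nan_to_num(p.center)
        total = w.sum()
        if total <= 0:
            raise ContractError("centroid undefined for a profile without positive mass")
        centroids.append(float((w * p.bin_centers).sum() / total))
    return centroids[1] - centroids[0]


def _denoised_row(values: np.ndarray, bin_centers: np.ndarray,
                  flank_frac: float, noise_sigma: float) -> AggregateProfile:
    """Single-row profile with the flank-estimated background removed: the
    flank mean is subtracted and bins below flank_mean + noise_sigma * flank_SD
    are zeroed, so background fluctuations do not contribute centroid mass."""
    k = max(1, int(round(flank_frac * len(values))))
    flank = np.concatenate([values[:k], values[-k:]])
    baseline = float(np.nanmean(flank))
    spread = float(np.nanstd(flank))
    out = np.clip(values - baseline, 0.0, None)
    out[np.nan_to_num(values) < baseline + noise_sigma * spread] = 0.0
    return AggregateProfile(bin_centers, out)


def region_centroid_shifts(wt: HeatmapMatrix, ko: HeatmapMatrix,
                           flank_frac: float = 0.1,
                           noise_sigma: float = 2.0) -> np.ndarray:
    """Per-region centroid shift (KO - WT) from denoised single-row profiles;
    NaN where either row has no mass above the background threshold."""
    if wt.region_ids != ko.region_ids:
        raise ContractError("matrices must share region order")
    shifts = np.full(len(wt.region_ids), np.nan)
    for i in range(len(shifts)):
        rows = []
        ok = True
        for h in (wt, ko):
            p = _denoised_row(h.values[i], h.bin_centers, flank_frac, noise_sigma)
            if np.nan_to_num(p.center).sum() <= 0:
                ok = False
                break
            rows.append(p)
        if ok:
            shifts[i] = centroid_shift(rows[0], rows[1])
    return shifts


def readthrough_index(
    proseq: TagTrack,
    tts: IntervalSet,
    body_window: int = 2000,
    down_window: int = 2000,
    eps: float = 1.0,
) -> np.ndarray:
    """Per-anchor readthrough index from stranded nascent-transcription tags.

    For each oriented terminator anchor t (interval center, strand required):
    ``RI = (sense tags downstream of t within down_window + eps) /
    (sense tags upstream within body_window + eps)``.  Larger values mean more
    transcription escaping past the terminator.
    """
    if body_window <= 0 or down_window <= 0:
        raise ContractError("windows must be > 0")
    out = np.empty(len(tts))
    for i, iv in enumerate(tts):
        if iv.strand not in ("+", "-"):
            raise ContractError("readthrough_index needs stranded anchors")
        t = iv.center
        sense = 1 if iv.strand == "+" else -1
        if iv.strand == "+":
            body = proseq.count(iv.chrom, max(0, t - body_window), t, strand=sense)
            down = proseq.count(iv.chrom, t, t + down_window, strand=sense)
        else:
            body = proseq.count(iv.chrom, t, t + body_window, strand=sense)
            down = proseq.count(iv.chrom, max(0, t - down_window), t, strand=sense)
        out[i] = (down + eps) / (body + eps)
    return out


# ---------------------------------------------------------------------------
# Per-class convenience


def class_heatmaps(
    track: TagTrack,
    classes: RegionClassification,
    half_width: int = 5000,
    bin_size: int = 50,
    strand_mode: str = "both",
    labels: tuple[str, ...] = (HUSH_K9POS, HUSH_K9NEG, MPP8_ONLY),
) -> Mapping[str, HeatmapMatrix]:
    """One heatmap per class label, rows oriented by the stored orientation."""
    out = {}
    for label in labels:
        regions = classes.regions(label)
        if len(regions) == 0:
            continue
        out[label] = build_heatmap(track, regions, half_width, bin_size, strand_mode)
    return out
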