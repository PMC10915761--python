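"""Synthetic multi-assay dataset with planted region classes and known truth.

The generator plants three region classes on a small two-chromosome genome and
emits coherent ChIP-seq, RNA-seq, PRO-seq and CLIP RT-stop tag tracks plus
peak calls, gene models, repeats, and (optionally) sequence:

* ``HUSH_K9POS``  — MPP8+TASOR bound, H3K9me3-marked, transcriptionally low,
  carries an "L1like" repeat and A-rich sense-strand sequence;
* ``HUSH_K9NEG``  — MPP8+TASOR bound, no H3K9me3, highly transcribed; a
  configurable fraction sits at the TTS of a planted gene;
* ``MPP8_ONLY``   — MPP8 without TASOR, H3K9me3-marked, carries an "LTRlike"
  repeat, transcriptionally quiet.

Knock-out/depletion conditions modify the tracks the way termination-factor
loss and HUSH depletion do: ``WDR82KO`` attenuates HUSH ChIP signal, displaces
it downstream (sense direction) at a planted subset of regions, attenuates
gene-body nascent transcription and adds terminator readthrough; ``MPP8dep``
de-represses the H3K9me3-positive class and halves expression of the
H3K9me3-negative class.

Tags are drawn per base pair from a negative binomial with mean
``background_rate x fold`` and a configurable dispersion (Poisson in the
dispersion -> 0 limit).  Every track has its own deterministic random stream
derived from the configured seed, so any subset of tracks reproduces the
corresponding tracks of a full run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import AnnotationTrack
from .genome import ContractError, Genome, IntervalSet, TagTrack
from .peaks import HUSH_K9NEG, HUSH_K9POS, MPP8_ONLY

ASSAYS = ("MPP8", "TASOR", "H3K9me3", "input", "RNA", "PRO", "CLIP")
CONDITIONS = ("WT", "WDR82KO", "MPP8dep")


def _default_chip_folds() -> dict[str, dict[str, float]]:
    return {
        "MPP8": {HUSH_K9POS: 8.0, HUSH_K9NEG: 8.0, MPP8_ONLY: 8.0},
        "TASOR": {HUSH_K9POS: 8.0, HUSH_K9NEG: 8.0, MPP8_ONLY: 1.0},
        "H3K9me3": {HUSH_K9POS: 10.0, HUSH_K9NEG: 1.0, MPP8_ONLY: 10.0},
        "input": {HUSH_K9POS: 1.0, HUSH_K9NEG: 1.0, MPP8_ONLY: 1.0},
    }


@dataclass
class SyntheticConfig:
    """Study conditions for the simulator; defaults are the planted dataset
    every recovery test runs against."""

    chrom_lengths: tuple[int, ...] = (5_000_000, 5_000_000)
    n_k9pos: int = 100
    n_k9neg: int = 200
    n_mpp8only: int = 100
    region_width_median: float = 1000.0
    region_width_sigma: float = 0.4     # log-normal sigma of region widths
    min_gap: int = 3000                 # bp between planted regions
    background_rate: float = 0.01       # tags per bp per track
    dispersion: float = 0.2             # NB dispersion of per-bp counts
    chip_folds: dict = field(default_factory=_default_chip_folds)
    rna_folds: dict = field(default_factory=lambda: {
        HUSH_K9POS: 1.0, HUSH_K9NEG: 8.0, MPP8_ONLY: 1.0})
    pro_folds: dict = field(default_factory=lambda: {
        HUSH_K9POS: 4.0, HUSH_K9NEG: 8.0, MPP8_ONLY: 1.0})
    clip_folds: dict = field(default_factory=lambda: {
        HUSH_K9POS: 12.0, HUSH_K9NEG: 12.0, MPP8_ONLY: 1.0})
    terminator_fraction: float = 0.75   # K9NEG regions placed at a gene TTS
    gene_length_range: tuple[int, int] = (5000, 20000)
    gene_pro_fold: float = 8.0          # sense nascent transcription in bodies
    n_background_genes: int = 50
    n_background_repeats: int = 300
    shift_fraction: float = 0.25        # HUSH regions whose KO signal shifts
    shift_bp: int = 500                 # downstream (sense) displacement
    ko_chip_retention: float = 0.2      # HUSH ChIP enrichment kept in WDR82KO
    ko_body_attenuation: float = 0.5    # gene-body PRO signal kept in WDR82KO
    readthrough_fold: float = 5.0       # downstream-of-TTS sense rate in KO
    readthrough_window: int = 2000
    mpp8dep_rna_fold_k9pos: float = 4.0
    mpp8dep_rna_fold_k9neg: float = 0.5
    a_rich_prob: float = 0.5            # sense-strand p(A) inside K9POS regions
    n_replicates: int = 2               # H3K9me3 IP and input replicates
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.terminator_fraction <= 1.0:
            raise ContractError("terminator_fraction must lie in [0, 1]")
        if not 0.0 <= self.shift_fraction <= 1.0:
            raise ContractError("shift_fraction must lie in [0, 1]")
        if min(self.n_k9pos, self.n_k9neg, self.n_mpp8only) < 1:
            raise ContractError("class counts must be >= 1")

    @property
    def genome(self) -> Genome:
        return Genome({f"chr{i + 1}": length
                       for i, length in enumerate(self.chrom_lengths)})


@dataclass
class SyntheticAnnotations:
    """Planted annotations plus the ground-truth table (one row per region)."""

    genome: Genome
    truth: pd.DataFrame
    regions: IntervalSet            # oriented; name = region id
    genes: IntervalSet              # stranded gene bodies; name = gene id
    repeats: AnnotationTrack
    peaks: dict[str, IntervalSet]   # per-factor planted peak calls

    def regions_by_label(self, label: str) -> IntervalSet:
        sub = self.truth[self.truth["label"] == label]
        return IntervalSet(
            pd.DataFrame(
                {
                    "chrom": sub["chrom"],
                    "start": sub["start"],
                    "end": sub["end"],
                    "name": sub["region_id"],
                    "score": 0.0,
                    "strand": sub["strand"],
                }
            )
        )


def _rng(cfg: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg.seed), int(stream)])


# ---------------------------------------------------------------------------
# Annotations


def _place_regions(cfg: SyntheticConfig, rng: np.random.Generator) -> pd.DataFrame:
    n_total = cfg.n_k9pos + cfg.n_k9neg + cfg.n_mpp8only
    widths = np.round(
        cfg.region_width_median
        * np.exp(rng.normal(0.0, cfg.region_width_sigma, size=n_total))
    ).astype(int)
    widths = np.maximum(widths, 100)
    lengths = np.array(cfg.chrom_lengths, dtype=float)
    per_chrom = np.floor(n_total * lengths / lengths.sum()).astype(int)
    per_chrom[0] += n_total - per_chrom.sum()
    rows = []
    k = 0
    # keep window room at chromosome ends so +-5 kb heatmaps never clip
    edge_pad = 20_000
    for c, n_c in enumerate(per_chrom):
        chrom = f"chr{c + 1}"
        w = widths[k:k + n_c]
        free = cfg.chrom_lengths[c] - 2 * edge_pad - int(w.sum()) \
            - (n_c + 1) * cfg.min_gap
        if free < 0:
            raise ContractError(
                "genome too small to place the requested regions without overlap"
            )
        cuts = np.sort(rng.uniform(0.0, free, size=n_c))
        extra = np.diff(np.concatenate([[0.0], cuts])).astype(int)
        pos = edge_pad
        for j in range(n_c):
            pos += cfg.min_gap + extra[j]
            rows.append((chrom, pos, pos + int(w[j])))
            pos += int(w[j])
        k += n_c
    labels = np.array(
        [HUSH_K9POS] * cfg.n_k9pos + [HUSH_K9NEG] * cfg.n_k9neg
        + [MPP8_ONLY] * cfg.n_mpp8only
    )
    rng.shuffle(labels)
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["label"] = labels
    df["strand"] = rng.choice(["+", "-"], size=n_total)
    width = len(str(n_total))
    df["region_id"] = [f"true_{i:0{width}d}" for i in range(n_total)]
    return df


def simulate_annotations(cfg: SyntheticConfig) -> SyntheticAnnotations:
    """Plant regions, classes, orientations, terminator genes and repeats.

    Deterministic given ``cfg.seed``.  Regions are non-overlapping with at
    least ``min_gap`` bp between them; the configured fraction of HUSH_K9NEG
    regions has a gene whose TTS coincides with the region center; K9POS and
    MPP8_ONLY regions carry an "L1like"/"LTRlike" repeat respectively.
    """
    rng = _rng(cfg, 1000)
    genome = cfg.genome
    truth = _place_regions(cfg, rng)

    # terminator genes for a fixed fraction of K9NEG regions
    k9neg_idx = truth.index[truth["label"] == HUSH_K9NEG].to_numpy()
    n_term = int(round(cfg.terminator_fraction * len(k9neg_idx)))
    term_idx = rng.choice(k9neg_idx, size=n_term, replace=False)
    truth["at_terminator"] = False
    truth.loc[term_idx, "at_terminator"] = True
    # keep transcription units >= 1 kb clear of the other planted regions so
    # each region's nascent-transcription signal is attributable to itself
    clearance = 1000
    spans = {chrom: (sub["start"].to_numpy(), sub["end"].to_numpy())
             for chrom, sub in truth.sort_values(["chrom", "start"])
             .groupby("chrom", sort=False)}

    def clamp_to_free(chrom, gs, ge, own_start, own_end):
        starts, ends = spans[chrom]
        others = ~((starts == own_start) & (ends == own_end))
        prev_end = ends[others][ends[others] <= own_start]
        next_start = starts[others][starts[others] >= own_end]
        if len(prev_end):
            gs = max(gs, int(prev_end.max()) + clearance)
        if len(next_start):
            ge = min(ge, int(next_start.min()) - clearance)
        return gs, ge

    gene_rows = []
    for i in sorted(term_idx):
        row = truth.loc[i]
        center = (row["start"] + row["end"]) // 2
        glen = int(rng.integers(*cfg.gene_length_range))
        if row["strand"] == "+":
            gs, ge = max(0, center - glen), center
        else:
            gs, ge = center, min(genome[row["chrom"]], center + glen)
        gs, ge = clamp_to_free(row["chrom"], gs, ge, row["start"], row["end"])
        gene_rows.append((row["chrom"], gs, ge, f"gene_{row['region_id']}",
                          0.0, row["strand"]))
    # background genes elsewhere (transcribed, not HUSH-bound), rejected if
    # they come near a planted region
    clear_zone = IntervalSet(truth[["chrom", "start", "end"]]) \
        .slop(clearance + cfg.readthrough_window)
    j = 0
    attempts = 0
    while j < cfg.n_background_genes and attempts < 50 * cfg.n_background_genes:
        attempts += 1
        c = int(rng.integers(0, len(cfg.chrom_lengths)))
        chrom = f"chr{c + 1}"
        glen = int(rng.integers(*cfg.gene_length_range))
        gs = int(rng.integers(20_000, cfg.chrom_lengths[c] - glen - 20_000))
        candidate = IntervalSet(pd.DataFrame(
            [(chrom, max(0, gs - cfg.readthrough_window),
              gs + glen + cfg.readthrough_window)],
            columns=["chrom", "start", "end"]))
        if candidate.overlaps_any(clear_zone)[0]:
            continue
        gene_rows.append((chrom, gs, gs + glen, f"bg_gene_{j:03d}", 0.0,
                          str(rng.choice(["+", "-"]))))
        j += 1
    genes = IntervalSet(pd.DataFrame(
        gene_rows, columns=["chrom", "start", "end", "name", "score", "strand"]))

    # repeats: class-linked families plus scattered background family
    rep_rows = []
    for _, row in truth.iterrows():
        if row["label"] == HUSH_K9POS:
            family = "L1like"
        elif row["label"] == MPP8_ONLY:
            family = "LTRlike"
        else:
            continue
        span = row["end"] - row["start"]
        pad = span // 10
        rep_rows.append((row["chrom"], row["start"] + pad, row["end"] - pad,
                         family, 0.0, row["strand"]))
    for j in range(cfg.n_background_repeats):
        c = int(rng.integers(0, len(cfg.chrom_lengths)))
        chrom = f"chr{c + 1}"
        rlen = int(rng.integers(150, 400))
        rs = int(rng.integers(0, cfg.chrom_lengths[c] - rlen))
        rep_rows.append((chrom, rs, rs + rlen, "SINElike", 0.0,
                         str(rng.choice(["+", "-"]))))
    repeats = AnnotationTrack(IntervalSet(pd.DataFrame(
        rep_rows, columns=["chrom", "start", "end", "name", "score", "strand"])))

    # shifted subset of HUSH regions (WDR82-KO displacement)
    hush_idx = truth.index[truth["label"].isin([HUSH_K9POS, HUSH_K9NEG])].to_numpy()
    n_shift = int(round(cfg.shift_fraction * len(hush_idx)))
    shift_idx = rng.choice(hush_idx, size=n_shift, replace=False)
    truth["shifted"] = False
    truth.loc[shift_idx, "shifted"] = True

    regions = IntervalSet(pd.DataFrame(
        {
            "chrom": truth["chrom"],
            "start": truth["start"],
            "end": truth["end"],
            "name": truth["region_id"],
            "score": 0.0,
            "strand": truth["strand"],
        }
    ))
    # peak calls are emitted from truth, decoupling classification from
    # peak calling (out of scope)
    is_hush = truth["label"].isin([HUSH_K9POS, HUSH_K9NEG]).to_numpy()
    is_k9 = truth["label"].isin([HUSH_K9POS, MPP8_ONLY]).to_numpy()
    peaks = {
        "MPP8": regions,
        "TASOR": regions.subset(is_hush),
        "H3K9me3": regions.subset(is_k9),
    }
    truth = truth[["region_id", "chrom", "start", "end", "label", "strand",
                   "at_terminator", "shifted"]].reset_index(drop=True)
    return SyntheticAnnotations(genome, truth, regions, genes, repeats, peaks)


# ---------------------------------------------------------------------------
# Sequence


def simulate_sequences(cfg: SyntheticConfig,
                       ann: SyntheticAnnotations) -> dict[str, str]:
    """Random genome sequence with A-rich sense-strand composition inside
    HUSH_K9POS regions ('-' regions are planted T-rich on the reference so
    their reverse complement is A-rich).  Deterministic given ``cfg.seed``."""
    rng = _rng(cfg, 1001)
    bases = np.frombuffer(b"ACGT", dtype="S1")
    seqs: dict[str, str] = {}
    p_rest = (1.0 - cfg.a_rich_prob) / 3.0
    for chrom, length in ann.genome.sizes.items():
        arr = bases[rng.integers(0, 4, size=length)]
        sub = ann.truth[(ann.truth["chrom"] == chrom)
                        & (ann.truth["label"] == HUSH_K9POS)]
        for row in sub.itertuples(index=False):
            n = row.end - row.start
            if row.strand == "+":
                p = [cfg.a_rich_prob, p_rest, p_rest, p_rest]   # A-rich
            else:
                p = [p_rest, p_rest, p_rest, cfg.a_rich_prob]   # T-rich
            arr[row.start:row.end] = bases[rng.choice(4, size=n, p=p)]
        seqs[chrom] = arr.tobytes().decode("ascii")
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str, width: int = 80) -> None:
    with open(path, "w") as fh:
        for chrom, seq in seqs.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Tracks


# stable per-track random streams: any subset of tracks reproduces the same
# tags as a full run with the same seed
_TRACK_STREAM = {
    (assay, condition): 10 * (i + 1) + 100 * (j + 1)
    for i, assay in enumerate(ASSAYS)
    for j, condition in enumerate(CONDITIONS)
}

DEFAULT_TRACKS: tuple[tuple[str, str], ...] = (
    ("MPP8", "WT"), ("TASOR", "WT"), ("H3K9me3", "WT"), ("input", "WT"),
    ("RNA", "WT"), ("PRO", "WT"), ("CLIP", "WT"),
    ("MPP8", "WDR82KO"), ("TASOR", "WDR82KO"), ("PRO", "WDR82KO"),
    ("RNA", "MPP8dep"),
)


def _sample_counts(rng: np.random.Generator, mu: np.ndarray,
                   dispersion: float) -> np.ndarray:
    if dispersion < 1e-9:
        return rng.poisson(mu)
    lam = rng.gamma(1.0 / dispersion, mu * dispersion)
    return rng.poisson(lam)


def _positions_from_mu(rng, mu_by_chrom, dispersion):
    positions = {}
    for chrom, mu in mu_by_chrom.items():
        counts = _sample_counts(rng, mu, dispersion)
        idx = np.flatnonzero(counts)
        positions[chrom] = np.repeat(idx.astype(np.int64), counts[idx])
    return positions


def _shifted_span(row, shift_bp: int, chrom_len: int) -> tuple[int, int]:
    if row.strand == "+":
        return row.start + shift_bp, min(row.end + shift_bp, chrom_len)
    return max(row.start - shift_bp, 0), row.end - shift_bp


def _chip_mu(cfg: SyntheticConfig, ann: SyntheticAnnotations,
             assay: str, condition: str) -> dict[str, np.ndarray]:
    folds = cfg.chip_folds[assay]
    mu = {chrom: np.full(length, cfg.background_rate)
          for chrom, length in ann.genome.sizes.items()}
    hush = (HUSH_K9POS, HUSH_K9NEG)
    for row in ann.truth.itertuples(index=False):
        fold = folds[row.label]
        if condition == "WDR82KO" and assay in ("MPP8", "TASOR") \
                and row.label in hush:
            if row.shifted:
                s, e = _shifted_span(row, cfg.shift_bp, ann.genome[row.chrom])
                mu[row.chrom][s:e] = cfg.background_rate * fold
                continue
            fold = 1.0 + (fold - 1.0) * cfg.ko_chip_retention
        mu[row.chrom][row.start:row.end] = cfg.background_rate * fold
    return mu


def _rna_mu(cfg, ann, condition) -> dict[str, np.ndarray]:
    mu = {chrom: np.full(length, cfg.background_rate)
          for chrom, length in ann.genome.sizes.items()}
    for row in ann.truth.itertuples(index=False):
        fold = cfg.rna_folds[row.label]
        if condition == "MPP8dep":
            if row.label == HUSH_K9POS:
                fold *= cfg.mpp8dep_rna_fold_k9pos
            elif row.label == HUSH_K9NEG:
                fold *= cfg.mpp8dep_rna_fold_k9neg
        mu[row.chrom][row.start:row.end] = cfg.background_rate * fold
    return mu


def _stranded_background(cfg, ann):
    half = cfg.background_rate / 2.0
    return (
        {c: np.full(n, half) for c, n in ann.genome.sizes.items()},
        {c: np.full(n, half) for c, n in ann.genome.sizes.items()},
    )


def _pro_mu(cfg, ann, condition):
    half = cfg.background_rate / 2.0
    mu_plus, mu_minus = _stranded_background(cfg, ann)
    atten = cfg.ko_body_attenuation if condition == "WDR82KO" else 1.0
    # gene bodies: sense-strand nascent transcription
    for iv in ann.genes:
        mu = mu_plus if iv.strand == "+" else mu_minus
        rate = half * cfg.gene_pro_fold * atten
        np.maximum(mu[iv.chrom][iv.start:iv.end], rate,
                   out=mu[iv.chrom][iv.start:iv.end])
    # planted regions: sense-strand signal by class
    for row in ann.truth.itertuples(index=False):
        fold = cfg.pro_folds[row.label]
        if condition == "WDR82KO" and row.label in (HUSH_K9POS, HUSH_K9NEG):
            fold = max(1.0, fold * cfg.ko_body_attenuation)
        mu = mu_plus if row.strand == "+" else mu_minus
        rate = half * fold
        np.maximum(mu[row.chrom][row.start:row.end], rate,
                   out=mu[row.chrom][row.start:row.end])
    # terminator readthrough downstream of every gene TTS in the KO
    if condition == "WDR82KO":
        for iv in ann.genes:
            mu = mu_plus if iv.strand == "+" else mu_minus
            if iv.strand == "+":
                s = iv.end
                e = min(iv.end + cfg.readthrough_window, ann.genome[iv.chrom])
            else:
                s = max(iv.start - cfg.readthrough_window, 0)
                e = iv.start
            np.maximum(mu[iv.chrom][s:e], half * cfg.readthrough_fold,
                       out=mu[iv.chrom][s:e])
    return mu_plus, mu_minus


def _clip_mu(cfg, ann):
    half = cfg.background_rate / 2.0
    mu_plus, mu_minus = _stranded_background(cfg, ann)
    for row in ann.truth.itertuples(index=False):
        mu = mu_plus if row.strand == "+" else mu_minus
        mu[row.chrom][row.start:row.end] = half * cfg.clip_folds[row.label]
    return mu_plus, mu_minus


def simulate_track(cfg: SyntheticConfig, ann: SyntheticAnnotations,
                   assay: str, condition: str = "WT",
                   replicate: int = 0) -> TagTrack:
    """One tag track for an assay/condition/replicate combination."""
    if (assay, condition) not in _TRACK_STREAM:
        raise ContractError(f"unknown track {(assay, condition)!r}")
    rng = _rng(cfg, _TRACK_STREAM[(assay, condition)] + replicate)
    track_id = f"{assay}.{condition}" + (f".rep{replicate}" if replicate else "")
    if assay in cfg.chip_folds:
        mu = _chip_mu(cfg, ann, assay, condition)
        positions = _positions_from_mu(rng, mu, cfg.dispersion)
        return TagTrack(positions, track_id=track_id)
    if assay == "RNA":
        mu = _rna_mu(cfg, ann, condition)
        positions = _positions_from_mu(rng, mu, cfg.dispersion)
        return TagTrack(positions, track_id=track_id)
    if assay in ("PRO", "CLIP"):
        mu_plus, mu_minus = (_pro_mu(cfg, ann, condition) if assay == "PRO"
                             else _clip_mu(cfg, ann))
        pos_plus = _positions_from_mu(rng, mu_plus, cfg.dispersion)
        pos_minus = _positions_from_mu(rng, mu_minus, cfg.dispersion)
        positions, strands = {}, {}
        for chrom in ann.genome.chromosomes:
            p, m = pos_plus[chrom], pos_minus[chrom]
            positions[chrom] = np.concatenate([p, m])
            strands[chrom] = np.concatenate(
                [np.ones(len(p), np.int8), -np.ones(len(m), np.int8)]
            )
        return TagTrack(positions, strands, track_id=track_id)
    raise ContractError(f"unknown assay {assay!r}")


def simulate_tracks(
    cfg: SyntheticConfig,
    ann: SyntheticAnnotations,
    tracks: Sequence[tuple[str, str]] | None = None,
) -> dict[str, TagTrack]:
    """Simulate the requested (assay, condition) tracks; replicated assays
    (H3K9me3 IP and input) yield ``cfg.n_replicates`` tracks each, keyed
    ``"{assay}.{condition}.rep{r}"``, others ``"{assay}.{condition}"``."""
    out: dict[str, TagTrack] = {}
    for assay, condition in (tracks if tracks is not None else DEFAULT_TRACKS):
        if assay in ("H3K9me3", "input"):
            for r in range(cfg.n_replicates):
                t = simulate_track(cfg, ann, assay, condition, replicate=r)
                out[f"{assay}.{condition}.rep{r}"] = t
        else:
            out[f"{assay}.{condition}"] = simulate_track(cfg, ann, assay, condition)
    return out


# ---------------------------------------------------------------------------
# On-disk dataset


def write_gtf(genes: IntervalSet, path: str, source: str = "hushmap_sim") -> None:
    with open(path, "w") as fh:
        for iv in genes:
            attrs = f'gene_id "{iv.name}";'
            fh.write(
                f"{iv.chrom}\t{source}\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\t{attrs}\n"
            )


def read_gtf_genes(path: str, genome: Genome | None = None) -> IntervalSet:
    """Gene-level records of a GTF/GFF file as a stranded interval set
    (1-based inclusive coordinates converted to 0-based half-open)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "gene":
                continue
            if genome is not None and f[0] not in genome:
                continue
            name = "."
            for token in f[8].split(";"):
                token = token.strip()
                if token.startswith("gene_id"):
                    name = token.split(None, 1)[1].strip('" ')
                    break
            rows.append((f[0], int(f[3]) - 1, int(f[4]), name, 0.0, f[6]))
    return IntervalSet(pd.DataFrame(
        rows, columns=["chrom", "start", "end", "name", "score", "strand"]))


def write_dataset(cfg: SyntheticConfig, out_dir: str,
                  tracks: Sequence[tuple[str, str]] | None = None,
                  with_sequence: bool = False) -> SyntheticAnnotations:
    """Write the full synthetic dataset (annotations, peak BEDs, tag BEDs,
    truth table, chrom.sizes and optionally FASTA) to a directory."""
    os.makedirs(out_dir, exist_ok=True)
    ann = simulate_annotations(cfg)
    ann.genome.to_chrom_sizes(os.path.join(out_dir, "chrom.sizes"))
    ann.truth.to_csv(os.path.join(out_dir, "truth.tsv"), sep="\t", index=False)
    ann.regions.to_bed(os.path.join(out_dir, "regions.bed"))
    for factor, peaks in ann.peaks.items():
        peaks.to_bed(os.path.join(out_dir, f"peaks_{factor}.bed"))
    ann.repeats.intervals.to_bed(os.path.join(out_dir, "repeats.bed"))
    write_gtf(ann.genes, os.path.join(out_dir, "genes.gtf"))
    for name, track in simulate_tracks(cfg, ann, tracks).items():
        if name.startswith("PRO"):
            plus, minus = track.split_by_strand()
            plus.to_bed(os.path.join(out_dir, f"tags_{name}.plus.bed"))
            minus.to_bed(os.path.join(out_dir, f"tags_{name}.minus.bed"))
        else:
            track.to_bed(os.path.join(out_dir, f"tags_{name}.bed"))
    if with_sequence:
        write_fasta(simulate_sequences(cfg, ann),
                    os.path.join(out_dir, "genome.fa"))
    return ann
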