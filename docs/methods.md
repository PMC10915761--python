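# Methods

This note records the models, estimators, numerical conventions and design
choices behind `hushmap`, and what the synthetic-data tests do and do not
demonstrate.

## Coordinates, tags, scaling

All intervals are 0-based, half-open (BED).  Sequencing reads are reduced to
single-base tags — the 5′ end of the read on its own strand — which makes
ChIP tags, RNA/PRO-seq tags and CLIP RT stops uniform.  A track carries its
library's `total_aligned` count; coverage values are scaled to tags per
million aligned (1e6/`total_aligned`).  Meta-profiles additionally support
"reads per billion per base per region": per-bin raw tag counts divided by
(number of regions × bin width in bp) × 1e9/`total_aligned`.

## Interval-overlap statistic

For merged interval sets A and B on a genome of total length G, the 2×2
table is

|            | overlap        | no overlap |
|------------|----------------|------------|
| A          | n11 (pairs)    | n12        |
| B          | n21            | n22        |

with n11 = number of (a, b) pairs sharing ≥ 1 bp, n12/n21 = intervals of
A/B with no partner, and n22 = max(0, ⌊G/(L̄_A + L̄_B)⌋ − n11 − n12 − n21),
the remaining "slots" of the genomic null (the genome divided into segments
of the combined mean interval length).  The odds ratio is
(n11·n22)/(n12·n21); a zero numerator product reports 0, a zero denominator
product reports +∞, and an optional Haldane correction adds 0.5 to every
cell for plotting.  The p-value is the two-sided Fisher exact test on the
table.  Inputs must be merged and are treated as unstranded; unmerged input
is rejected rather than silently merged.  The construction is validated
against a quadratic-time pair-enumeration oracle on random interval sets.

## Mean-shift peak consolidation

Peak midpoints on each chromosome are clustered with 1-D mean shift using a
flat (boxcar) kernel of half-width `bandwidth` (default 500 bp), convergence
tolerance 1e-3 bp, and at most 200 iterations.  Points whose converged modes
agree to sub-bp resolution form one cluster; the cluster's region is the
union (min start, max end) of its member peaks, and overlapping region
unions are merged so the superset is non-overlapping.  Every input peak is
therefore contained in exactly one region, and the result is invariant to
input order.  With a flat kernel, peaks further than 2×bandwidth apart can
never interact, so well-separated peaks are never joined.

## H3K9me3 enrichment calls

Counts of IP and input tags in superset regions are modeled as negative
binomial.  The pipeline normalizes samples by **library size** (total
aligned tags, rescaled to geometric mean 1).  Median-of-ratios factors are
provided (`compute_size_factors`) and are the right choice for genome-wide
count tables, but a consolidated peak superset is an enrichment-biased
region set: on synthetic data where half the regions are truly marked,
median-of-ratios factors absorbed most of the enrichment into the
normalization and halved the detected fold changes, so the pipeline default
is library size.

Dispersion is estimated by method of moments pooled across regions within
abundance bins (up to 10 quantile bins of the mean normalized count, at
least 50 regions per bin): within each bin,
α = (mean within-group variance − mean count) / (mean count)².
Averaging the moment numerator and denominator separately, rather than
averaging per-region ratio estimates, avoids the downward bias of
ratio-of-noisy-moments with few replicates; with heterogeneous means inside
a bin the estimator errs toward larger dispersion, i.e. conservative calls.

The test statistic is Wald on the log2 fold change: group means of
normalized counts (floored at 0.5 so that log and variance are defined for
empty regions), delta-method variance var(log μ̂) ≈ (1/μ + α)/n per group,
two-sided normal p-values, BH correction across all regions jointly, and an
enrichment call when q ≤ α (default 0.05) **and** log2FC ≥ `lfc_min`
(default 1).  Calibration, measured on all-null simulations with two
replicates per group: the p ≤ 0.05 rate is ≈ 0.055 at dispersion 0.1 and
stays below 0.06 through dispersion 0.2; at dispersion 0.5 the normal
approximation to two-replicate NB means turns mildly liberal (≈ 0.08), but
BH discovery FDR remains controlled in mixed simulations across the whole
0.05–0.5 range.  More replicates tighten the tail behavior.

## Classification and orientation

"Bound by a factor" is operationalized as ≥ 1 bp overlap with that factor's
called peak set — peak calls are the evidence unit, avoiding an unstated
coverage cutoff.  MPP8 ∩ TASOR → HUSH target, split by the H3K9me3 call;
MPP8 without TASOR → MPP8-only; regions without MPP8 overlap remain
unclassified (the superset may be seeded from additional marks).  Regions
are oriented by comparing plus- and minus-strand PRO-seq tags within
±1 kb of the region center, ties breaking to '+'.  Orientation is reliable
only where nascent transcription is planted/present; untranscribed regions
get an arbitrary (but deterministic) strand.

## Heatmaps and aggregates

A heatmap bins tags by signed distance from the region center
(default ±5 kb, 50 bp bins; bin size must divide the window).  For a
minus-strand region the distance is mirrored as d = center − position − 1,
which makes the row exactly the column reversal of the plus-strand row (the
−1 accounts for half-open asymmetry).  Window bins extending beyond
chromosome ends are recorded as missing (NaN) and excluded from aggregates
rather than zero-filled, avoiding edge dilution.  Class-sorted layouts
follow the block order HUSH_K9POS, HUSH_K9NEG, MPP8_ONLY with rows
descending by central (±1 kb) H3K9me3 signal, then combined MPP8+TASOR
signal, ties by region id.

Aggregate profiles are per-bin row means or medians.  Bootstrap bands
resample rows with replacement (resample size = row count, default 1,000
resamples) and take the 0.025/0.975 per-bin quantiles; a fixed integer seed
makes bands reproducible.  Unit scaling maps a profile affinely onto [0, 1]
(rejecting constant profiles) to compare shapes across conditions.
Differential maps subtract scaled matrices elementwise and may be negative.

## Shift and readthrough statistics

`centroid_shift` is the difference of signal-weighted mean positions
(KO − WT) in bp, positive meaning downstream in the sense orientation.
Because a uniform background pulls any weighted centroid toward the window
center, shift quantification first subtracts a flank-estimated baseline
(mean of the outermost 10% of bins) and clips at zero.  On aggregate
profiles over tens of regions the residual background is negligible and the
planted +500 bp displacement is recovered to within one 50 bp bin.
Per-region centroids (`region_centroid_shifts`, which additionally zeroes
bins below flank mean + 2 SD) remain noisier and biased a few tens of bp
toward zero at realistic signal-to-background ratios; class-aggregate
profiles are the recommended estimator and the one the validation uses.

The readthrough index at an oriented terminator anchor t is
RI = (sense tags in the 2 kb downstream of t + 1)/(sense tags in the 2 kb
upstream + 1); the pseudocount keeps silent terminators finite.  Termination
failure is reported as the per-anchor ratio RI(KO)/RI(WT).

## Annotation and CLIP analyses

Repeat presence heatmaps set a bin to 1 when ≥ 1 annotated bp of the
category overlaps it, with the same orientation convention as signal maps.
Class-vs-class category enrichment is a per-category Fisher exact test on
region-overlap indicators with BH across categories; tables with a zero
margin report odds ratio 1 and p = 1 by convention.  Trinucleotide densities
count overlapping 3-mers strand-aware ('−' regions use the reverse
complement); windows containing N are excluded from both numerator and
denominator.  TTS-overlap fractions extend terminator anchors by a ±500 bp
slop by default (an explicit overlap-distance rule, reported with the
result).  Meta-profiles anchor oriented windows at unique TSS / midpoint /
TTS coordinates of stranded gene models (identical anchor positions
collapsed) and use the per-billion normalization with median bootstrap
bands.

CLIP RT stops are assigned to the highest-priority feature category
containing them on the same strand (unstranded features match both strands);
the counts partition the stop total for any priority order.  The enrichment
E_f = (S_f/S_tot) / [(L_f/L_tot)·(T_f/T̄)] divides each category's stop
share by its share of length × relative transcription, where T_f is the
sense PRO-seq density in the category and T̄ the length-weighted mean
density; a pseudocount of 1 guards empty categories, and a `raw` flag
exposes the simpler S_f/(L_f·T_f) form.  The doubly normalized form has the
fixed point E_f ≡ 1 when stops are sampled proportionally to L_f·T_f, which
is what the validation checks (max deviation ≈ 0.02 at 1e5 stops); it is
also invariant to rescaling all transcription densities.

## Synthetic data: what it emulates

The generator plants 400 regions (100 HUSH_K9POS, 200 HUSH_K9NEG,
100 MPP8_ONLY) on a 10 Mb two-chromosome genome, widths log-normal with
median 1 kb (σ = 0.4), at least 3 kb apart and 20 kb clear of chromosome
ends.  Tags are drawn per base pair from NB(mean = background × fold,
dispersion 0.2); background is 0.01 tags/bp per track (≈ 100 k background
tags per library, a light but realistic sequencing depth), and Poisson is
the dispersion → 0 limit.  Enrichment folds: MPP8 8× at all three classes;
TASOR 8× at HUSH classes only; H3K9me3 10× at K9POS and MPP8_ONLY; RNA 8×
at K9NEG (transcribed) vs 1× at K9POS (silenced); PRO-seq sense-strand 8×
at K9NEG, 4× at K9POS, 8× in gene bodies; CLIP 12× sense at HUSH classes
(an order-of-magnitude protein–RNA contact enrichment; with antisense
background included the central aggregate ratio over MPP8-only is ≈ 6.5×).
75% of K9NEG regions sit at the TTS of a planted gene (5–20 kb, TTS at the
region center); K9POS regions carry an "L1like" repeat and A-rich
sense-strand sequence (p(A) = 0.5 vs 0.25 background), MPP8_ONLY regions an
"LTRlike" repeat; 300 background "SINElike" repeats and 50 background genes
are scattered, with transcription units kept ≥ 1 kb clear of other planted
regions so each region's strand signal is attributable to itself.

Condition effects mirror termination-factor and HUSH-depletion phenotypes:
in WDR82-KO, HUSH ChIP enrichment retains 20% at most HUSH regions, while a
planted 25% subset keeps full enrichment displaced +500 bp in the sense
direction; gene-body nascent transcription halves and the 2 kb downstream
of every gene TTS gains 5× background sense signal (readthrough).  In
MPP8-depletion, RNA at K9POS rises 4× (de-repression) and at K9NEG falls to
0.5×.  Peak BEDs are emitted from truth, by design: classification is
tested independently of peak calling, which is out of scope.  Every track
has its own deterministic random stream derived from the seed, so a subset
of tracks reproduces exactly the corresponding tracks of a full run.

What passing recovery tests shows — and does not.  The simulation captures
class structure, strand structure, overdispersed counts, condition effects
and annotation linkage, so it exercises every pipeline stage end to end
with known truth.  It does not model read-level error, fragment-length
effects, mappability, copy-number variation, or correlated (clumped)
backgrounds beyond per-bp NB noise; recovery rates on synthetic data are
therefore upper bounds on real-data behavior, and thresholds (α, `lfc_min`,
bandwidth, windows) remain user-facing configuration rather than claims of
fidelity to any particular dataset.

## Numerical conventions and degenerate inputs

Empty interval sets are rejected where a statistic would be undefined
(Fisher overlap, mean length, unit scaling of constant profiles, centroids
of zero-mass profiles); empty classes in per-class aggregates yield flagged
empty profiles instead of errors.  Ties break deterministically ('+' strand
on orientation ties, region id on sort ties).  Bootstrap and simulation
randomness comes exclusively from integer seeds through NumPy generator
streams, so identical seeds give identical output across runs.  Problem
sizes in the validation suite (10 Mb genome, 400 regions, 10 classification
seeds, 1,000 bootstrap resamples, 1e5 CLIP stops) were chosen so the full
suite completes in a few minutes while keeping Monte-Carlo error well inside
the asserted tolerances.
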