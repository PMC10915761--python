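"""Heatmap construction, aggregates, bootstrap bands, differential maps,
centroid shifts, and the readthrough index."""

import numpy as np
import pytest

from hushmap import (
    ContractError,
    Genome,
    HeatmapMatrix,
    TagTrack,
    aggregate,
    bootstrap_band,
    build_heatmap,
    centroid_shift,
    differential_matrix,
    readthrough_index,
    subtract_baseline,
    unit_scale,
)
from hushmap.maps import AggregateProfile, central_mean, sort_by_class
from hushmap.peaks import (HUSH_K9NEG, HUSH_K9POS, MPP8_ONLY,
                           RegionClassification)
import pandas as pd

from conftest import make_intervals, make_track


def matrix(values, half_width=1000, bin_size=50, strands=None, total=1_000_000):
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return HeatmapMatrix(values, [f"r{i:03d}" for i in range(n)],
                         np.asarray(strands if strands is not None else ["+"] * n),
                         half_width, bin_size, total)


# ---------------------------------------------------------------------------
# build_heatmap


class TestBuildHeatmap:
    def test_plus_strand_tag_position(self):
        regions = make_intervals([("chr1", 900, 1100, "r", 0.0, "+")])
        track = make_track([1010], total_aligned=1_000_000)
        h = build_heatmap(track, regions, half_width=100, bin_size=20)
        assert h.values[0].sum() == pytest.approx(1.0)
        # distance +10 falls in the bin spanning [0, 20)
        assert h.values[0, np.flatnonzero(h.bin_edges == 0)[0]] == 1.0

    def test_minus_strand_is_column_reversal(self):
        regions_p = make_intervals([("chr1", 900, 1100, "r", 0.0, "+")])
        regions_m = make_intervals([("chr1", 900, 1100, "r", 0.0, "-")])
        track = make_track([1010, 1034, 950], total_aligned=1_000_000)
        hp = build_heatmap(track, regions_p, 100, 20)
        hm = build_heatmap(track, regions_m, 100, 20)
        np.testing.assert_array_equal(hm.values[0], hp.values[0][::-1])

    def test_scaling_rule(self):
        regions = make_intervals([("chr1", 900, 1100)])
        track = make_track([1005] * 4, total_aligned=2_000_000)
        h = build_heatmap(track, regions, 100, 20)
        assert h.values[0].max() == pytest.approx(2.0)

    def test_indivisible_window_rejected(self):
        regions = make_intervals([("chr1", 900, 1100)])
        with pytest.raises(ContractError):
            build_heatmap(make_track([]), regions, half_width=100, bin_size=33)

    def test_out_of_bounds_bins_are_missing_not_zero(self):
        genome = Genome({"chr1": 1000})
        regions = make_intervals([("chr1", 0, 100)])  # center 50, window ±200
        track = make_track([60], total_aligned=1_000_000)
        h = build_heatmap(track, regions, 200, 50, genome=genome)
        assert np.isnan(h.values[0, :3]).all()  # bins below position 0
        assert np.isfinite(h.values[0, 3:]).all()

    def test_mass_conservation(self, rng):
        """Raw counts in the matrix equal the tags inside all windows."""
        starts = np.arange(10) * 5000 + 2000
        regions = make_intervals([("chr1", s, s + 500) for s in starts])
        track = TagTrack({"chr1": rng.integers(0, 60_000, 5000)},
                         total_aligned=10_000_000)
        h = build_heatmap(track, regions, 1000, 50)
        raw = h.values.sum() * track.total_aligned / 1e6
        expected = sum(
            track.count("chr1", s + 250 - 1000, s + 250 + 1000) for s in starts)
        assert raw == pytest.approx(expected)

    def test_scaling_linearity_in_total_aligned(self, rng):
        pos = rng.integers(0, 10_000, 300)
        regions = make_intervals([("chr1", 4000, 5000)])
        h1 = build_heatmap(TagTrack({"chr1": pos}, total_aligned=1_000_000),
                           regions, 1000, 50)
        h2 = build_heatmap(TagTrack({"chr1": pos}, total_aligned=2_000_000),
                           regions, 1000, 50)
        np.testing.assert_allclose(h2.values, h1.values / 2)

    def test_orientation_involution(self, rng):
        pos = rng.integers(0, 20_000, 500)
        track = TagTrack({"chr1": pos}, total_aligned=1_000_000)
        rows = [("chr1", 3000, 4000, "a", 0.0, "+"), ("chr1", 9000, 9800, "b", 0.0, "-")]
        regions = make_intervals(rows)
        flipped_twice = make_intervals(rows)  # flipping '+'<->'-' twice is identity
        h1 = build_heatmap(track, regions, 1000, 50)
        h2 = build_heatmap(track, flipped_twice, 1000, 50)
        np.testing.assert_array_equal(h1.values, h2.values)

    def test_sense_mode_uses_region_strand(self):
        regions = make_intervals([("chr1", 900, 1100, "r", 0.0, "-")])
        track = make_track([1010, 1030], strands="+-", total_aligned=1_000_000)
        h = build_heatmap(track, regions, 100, 20, strand_mode="sense")
        assert h.values[0].sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# sort_by_class


def test_sort_by_class_blocks_and_descending_signal():
    frame = pd.DataFrame(
        {
            "region_id": ["r000", "r001", "r002", "r003"],
            "chrom": "chr1",
            "start": [0, 1000, 2000, 3000],
            "end": [100, 1100, 2100, 3100],
            "label": [HUSH_K9NEG, HUSH_K9POS, HUSH_K9POS, MPP8_ONLY],
            "overlaps_mpp8": True,
            "overlaps_tasor": True,
            "k9_call": False,
            "log2_fold_change": 0.0,
            "q_value": 1.0,
            "orientation": "+",
        }
    )
    classes = RegionClassification(frame)
    k9_vals = np.zeros((4, 40))
    k9_vals[1] = 3.0
    k9_vals[2] = 5.0
    k9 = matrix(k9_vals)
    flat = matrix(np.zeros((4, 40)))
    order = sort_by_class(classes, k9, flat, flat)
    # K9POS block first (higher central K9 first), then K9NEG, then MPP8-only
    assert list(order) == [2, 1, 0, 3]


def test_sort_by_class_tie_breaks_by_region_id():
    frame = pd.DataFrame(
        {
            "region_id": ["r001", "r000"],
            "chrom": "chr1",
            "start": [0, 1000],
            "end": [100, 1100],
            "label": [HUSH_K9POS, HUSH_K9POS],
            "overlaps_mpp8": True,
            "overlaps_tasor": True,
            "k9_call": True,
            "log2_fold_change": 0.0,
            "q_value": 1.0,
            "orientation": "+",
        }
    )
    classes = RegionClassification(frame)
    flat = HeatmapMatrix(np.ones((2, 40)), ["r001", "r000"],
                         np.array(["+", "+"]), 1000, 50, 1_000_000)
    order = sort_by_class(classes, flat, flat, flat)
    assert [frame["region_id"][i] for i in order] == ["r000", "r001"]


# ---------------------------------------------------------------------------
# aggregate / bootstrap / unit_scale


class TestAggregate:
    def test_identical_rows_equal_any_row(self):
        h = matrix(np.tile(np.arange(40.0), (5, 1)))
        p = aggregate(h)
        np.testing.assert_allclose(p.center, np.arange(40.0))

    def test_single_row_median_equals_row(self):
        h = matrix(np.arange(40.0)[None, :])
        np.testing.assert_allclose(aggregate(h, stat="median").center,
                                   np.arange(40.0))

    def test_per_billion_per_base_per_region_unit(self):
        # 2 regions, bin_size 10, 4 raw tags in one bin, total 1e9
        vals = np.zeros((2, 10))
        vals[0, 3] = 3 * 1e6 / 1e9
        vals[1, 3] = 1 * 1e6 / 1e9
        h = matrix(vals, half_width=50, bin_size=10, total=1_000_000_000)
        p = aggregate(h, normalization="per_billion_per_base_per_region")
        assert p.center[3] == pytest.approx(4 / (2 * 10))

    def test_mean_aggregate_commutes_with_differential(self, rng):
        a = matrix(rng.random((6, 40)))
        b = matrix(rng.random((6, 40)))
        d = differential_matrix(a, b)
        np.testing.assert_allclose(
            aggregate(d).center, aggregate(a).center - aggregate(b).center)


class TestBootstrapBand:
    def test_constant_matrix_collapses_band(self):
        h = matrix(np.full((10, 20), 7.0))
        p = bootstrap_band(h, n_boot=50, seed=1)
        np.testing.assert_allclose(p.lower, 7.0)
        np.testing.assert_allclose(p.upper, 7.0)

    def test_deterministic_given_seed(self, rng):
        h = matrix(rng.random((30, 20)))
        p1 = bootstrap_band(h, n_boot=100, seed=42)
        p2 = bootstrap_band(h, n_boot=100, seed=42)
        np.testing.assert_array_equal(p1.lower, p2.lower)
        np.testing.assert_array_equal(p1.upper, p2.upper)

    def test_single_resample_is_both_band_edges(self, rng):
        h = matrix(rng.random((15, 20)))
        p = bootstrap_band(h, n_boot=1, seed=3)
        np.testing.assert_allclose(p.lower, p.upper)

    def test_band_brackets_center_statistic(self, rng):
        h = matrix(rng.normal(3, 1, size=(100, 20)))
        p = bootstrap_band(h, n_boot=200, seed=5)
        assert (p.lower <= p.center + 1e-9).all()
        assert (p.center <= p.upper + 1e-9).all()


class TestUnitScale:
    def test_affine_map(self):
        p = AggregateProfile(np.arange(3.0), np.array([2.0, 4.0, 6.0]))
        np.testing.assert_allclose(unit_scale(p).center, [0.0, 0.5, 1.0])

    def test_idempotent_and_scale_invariant(self):
        p = AggregateProfile(np.arange(3.0), np.array([0.0, 0.25, 1.0]))
        np.testing.assert_allclose(unit_scale(p).center, p.center)
        p10 = AggregateProfile(np.arange(3.0), p.center * 10)
        np.testing.assert_allclose(unit_scale(p10).center, unit_scale(p).center)

    def test_constant_profile_rejected(self):
        p = AggregateProfile(np.arange(3.0), np.full(3, 2.0))
        with pytest.raises(ContractError):
            unit_scale(p)


# ---------------------------------------------------------------------------
# differential


class TestDifferential:
    def test_self_difference_is_zero(self, rng):
        a = matrix(rng.random((4, 40)))
        np.testing.assert_allclose(differential_matrix(a, a).values, 0.0)

    def test_linearity(self, rng):
        b = matrix(rng.random((4, 40)))
        c = rng.random((4, 40))
        a = matrix(b.values + c)
        np.testing.assert_allclose(differential_matrix(a, b).values, c)

    def test_geometry_mismatch_rejected(self, rng):
        a = matrix(rng.random((4, 40)), bin_size=50)
        b = matrix(rng.random((4, 20)), bin_size=100)
        with pytest.raises(ContractError):
            differential_matrix(a, b)


# ---------------------------------------------------------------------------
# centroid shift and readthrough


class TestCentroidShift:
    def test_pure_translation_recovered(self):
        centers = np.arange(-975.0, 1000.0, 50.0)
        base = np.exp(-0.5 * (centers / 100) ** 2)
        wt = AggregateProfile(centers, base)
        ko = AggregateProfile(centers, np.roll(base, 4))  # +200 bp
        assert centroid_shift(wt, ko) == pytest.approx(200.0, abs=25.0)

    def test_identical_profiles_zero_shift(self):
        centers = np.arange(-975.0, 1000.0, 50.0)
        p = AggregateProfile(centers, np.abs(centers) + 1)
        assert centroid_shift(p, p) == 0.0

    def test_zero_mass_rejected(self):
        centers = np.arange(-975.0, 1000.0, 50.0)
        p = AggregateProfile(centers, np.ones_like(centers))
        zero = AggregateProfile(centers, np.zeros_like(centers))
        with pytest.raises(ContractError):
            centroid_shift(p, zero)

    def test_baseline_subtraction_removes_uniform_background(self):
        centers = np.arange(-975.0, 1000.0, 50.0)
        signal = np.exp(-0.5 * ((centers - 300) / 100) ** 2)
        with_bg = AggregateProfile(centers, signal + 5.0)
        cleaned = subtract_baseline(with_bg, flank_frac=0.1)
        ref = AggregateProfile(centers, signal)
        assert abs(centroid_shift(ref, cleaned)) < 20.0


class TestReadthroughIndex:
    def track(self):
        # '+' terminator at 5000: body upstream [3000,5000), downstream [5000,7000)
        up = list(range(3000, 5000, 20))     # 100 sense tags upstream
        return make_track(up, strands="+" * len(up))

    def test_all_signal_upstream(self):
        tts = make_intervals([("chr1", 5000, 5001, "t", 0.0, "+")])
        ri = readthrough_index(self.track(), tts, 2000, 2000)
        assert ri[0] == pytest.approx(1 / 101)

    def test_symmetric_signal_unit_index(self):
        pos = list(range(3000, 7000, 40))  # equal mass both sides
        track = make_track(pos, strands="+" * len(pos))
        tts = make_intervals([("chr1", 5000, 5001, "t", 0.0, "+")])
        assert readthrough_index(track, tts, 2000, 2000)[0] == pytest.approx(1.0)

    def test_minus_strand_orientation_mirrored(self):
        # '-' terminator: downstream is to the left, sense tags on '-'
        down = list(range(3000, 5000, 20))
        track = make_track(down, strands="-" * len(down))
        tts = make_intervals([("chr1", 5000, 5001, "t", 0.0, "-")])
        ri = readthrough_index(track, tts, 2000, 2000)
        assert ri[0] == pytest.approx(101.0)

    def test_unstranded_anchor_rejected(self):
        tts = make_intervals([("chr1", 5000, 5001)])
        with pytest.raises(ContractError):
            readthrough_index(self.track(), tts)


def test_central_mean_window():
    h = matrix(np.arange(40.0)[None, :])  # bins span ±1000 in 50 bp steps
    sel = np.abs(h.bin_centers) <= 100
    assert central_mean(h, 100)[0] == pytest.approx(np.arange(40.0)[sel].mean())
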