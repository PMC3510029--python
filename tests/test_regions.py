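"""Bin aggregation, interval merging, domain calling and permutation FDR."""

import dataclasses
import warnings

import numpy as np
import pytest

import chromredist as cr
from chromredist.regions import (BinTrack, CallParams, ChromBins, bin_track,
                                 call_blocks, call_differential_blocks,
                                 call_differential_regions,
                                 call_enriched_regions, estimate_fdr,
                                 merge_intervals, rotate_track,
                                 total_called_bases)
from chromredist.tracks import ChromProbes, ProbeTrack


def _track(values, spacing=100, length=50, chrom="chr1"):
    starts = np.arange(len(values)) * spacing
    return ProbeTrack({chrom: ChromProbes(starts, starts + length,
                                          np.asarray(values, float))},
                      already_log=True)


def _bins(starts, scores, bin_size=200, step=100, chrom="chr1"):
    starts = np.asarray(starts, dtype=np.int64)
    return BinTrack({chrom: ChromBins(starts, starts + bin_size,
                                      np.asarray(scores, float))},
                    bin_size=bin_size, step=step)


class TestBinTrack:
    def test_two_probe_mean(self):
        track = _track([1.0, 3.0], spacing=100, length=100)
        bins = bin_track(track, bin_size=200, step=200)
        assert bins.chroms["chr1"].scores[0] == pytest.approx(2.0)

    def test_bin_start_enumeration_with_trailing_partial(self):
        track = _track(np.zeros(10), spacing=100, length=50)
        bins = bin_track(track, 200, 100, chrom_lengths={"chr1": 1000})
        cb = bins.chroms["chr1"]
        assert cb.starts.tolist() == list(range(0, 1000, 100))
        assert cb.ends[-1] == 1000  # trailing partial bin

    def test_constant_track_constant_bins(self):
        track = _track(np.full(20, 1.25))
        bins = bin_track(track, 200, 100)
        scores = bins.chroms["chr1"].scores
        np.testing.assert_allclose(scores[np.isfinite(scores)], 1.25)

    def test_empty_bins_are_nan(self):
        track = _track([1.0])  # one probe, chromosome length from probe end
        bins = bin_track(track, 200, 100, chrom_lengths={"chr1": 2000})
        scores = bins.chroms["chr1"].scores
        assert np.isnan(scores[10:]).all()


class TestMerge:
    def test_examples(self):
        assert merge_intervals([(0, 200), (300, 500)], gap=200) == [(0, 500)]
        assert merge_intervals([(0, 200), (600, 800)], gap=200) == \
            [(0, 200), (600, 800)]
        assert merge_intervals([], gap=200) == []

    def test_against_bruteforce_union_oracle(self):
        rng = np.random.default_rng(2024)
        for _ in range(300):
            n = rng.integers(1, 50)
            starts = rng.integers(0, 2000, n)
            lengths = rng.integers(1, 120, n)
            gap = int(rng.integers(0, 250))
            intervals = [(int(s), int(s + l)) for s, l in zip(starts, lengths)]
            got = merge_intervals(intervals, gap=gap)
            # oracle: paint a base-pair bitmap, close gaps <= gap, read runs
            hi = max(e for _, e in intervals) + gap + 2
            mask = np.zeros(hi, bool)
            for s, e in intervals:
                mask[s:e] = True
            runs, s0, prev_end = [], None, None
            for i in range(hi):
                if mask[i] and s0 is None:
                    s0 = i
                elif not mask[i] and s0 is not None:
                    runs.append((s0, i))
                    s0 = None
            merged = []
            for s, e in runs:
                if merged and s - merged[-1][1] <= gap:
                    merged[-1] = (merged[-1][0], e)
                else:
                    merged.append((s, e))
            assert got == merged

    def test_monotone_gap(self):
        intervals = [(0, 10), (30, 40), (100, 130)]
        for g1, g2 in [(0, 20), (20, 60), (60, 100)]:
            a = merge_intervals(intervals, g1)
            b = merge_intervals(intervals, g2)
            assert sum(e - s for s, e in a) <= sum(e - s for s, e in b)


class TestEnrichedCalling:
    def test_no_bin_passes(self):
        bins = _bins(range(0, 1000, 100), np.linspace(-1, 1, 10))
        assert call_enriched_regions(bins, CallParams(), z_cutoff=50) == []

    def test_merge_within_gap(self):
        scores = np.zeros(40)
        scores[[0, 3]] = 50.0  # bins [0,200) and [300,500): gap 100 <= 200
        bins = _bins(np.arange(40) * 100, scores)
        regions = call_enriched_regions(bins, CallParams(), z_cutoff=2)
        assert [(r.start, r.end) for r in regions] == [(0, 500)]

    def test_no_merge_beyond_gap(self):
        scores = np.zeros(40)
        scores[[0, 6]] = 50.0  # [0,200) and [600,800): gap 400 > 200
        bins = _bins(np.arange(40) * 100, scores)
        regions = call_enriched_regions(bins, CallParams(), z_cutoff=2)
        assert [(r.start, r.end) for r in regions] == [(0, 200), (600, 800)]

    def test_strict_length_filter(self):
        scores = np.zeros(60)
        scores[0:4] = 50.0   # union span [0,500): length 500, not > 500
        scores[30:35] = 50.0  # union span [3000,3600): length 600 > 500
        bins = _bins(np.arange(60) * 100, scores)
        regions = call_enriched_regions(bins, CallParams(), z_cutoff=2,
                                        min_region_len=500)
        assert [(r.start, r.end) for r in regions] == [(3000, 3600)]

    def test_cutoff_is_strict(self):
        # z of the two 1.0 values is exactly +1 in this symmetric vector
        bins = _bins(np.arange(4) * 100, [1.0, -1.0, 1.0, -1.0],
                     bin_size=100)
        assert call_enriched_regions(bins, CallParams(), z_cutoff=1.0) == []
        assert len(call_enriched_regions(bins, CallParams(), z_cutoff=0.999)) > 0


class TestDifferentialCalling:
    def test_identical_tracks_empty_with_warning(self):
        track = _track(np.random.default_rng(1).normal(size=100))
        bins = bin_track(track, 200, 100)
        with pytest.warns(UserWarning, match="zero-variance"):
            out = call_differential_regions(bins, bins, CallParams(), "hyper")
        assert out == []

    def test_toy_fifty_lifted_bins_single_region(self):
        rng = np.random.default_rng(7)
        scores = rng.normal(0, 1, 1000)
        scores[400:450] += 5.0
        zeros = np.zeros(1000)
        mut = _bins(np.arange(1000) * 100, scores, bin_size=100)
        wt = _bins(np.arange(1000) * 100, zeros, bin_size=100)
        regions = call_differential_regions(mut, wt, CallParams(), "hyper",
                                            z_cutoff=2.0)
        # brute-force oracle on the z vector
        z = cr.zscore_transform(scores)
        passing = np.nonzero(z > 2.0)[0]
        main = [r for r in regions if r.end - r.start > 2000]
        assert len(main) == 1
        assert main[0].start <= 40000 + 200 and main[0].end >= 45000 - 200
        assert 40000 in [p * 100 for p in passing] or z[400] > 2

    def test_hypo_equals_mirrored_hyper(self):
        rng = np.random.default_rng(11)
        a = rng.normal(0, 1, 500)
        b = rng.normal(0, 1, 500)
        b[100:130] += 4
        bins_a = _bins(np.arange(500) * 100, a, bin_size=100)
        bins_b = _bins(np.arange(500) * 100, b, bin_size=100)
        hypo = call_differential_regions(bins_a, bins_b, CallParams(), "hypo",
                                         z_cutoff=-2.5)
        hyper = call_differential_regions(bins_b, bins_a, CallParams(), "hyper",
                                          z_cutoff=2.5)
        assert [(r.start, r.end) for r in hypo] == \
            [(r.start, r.end) for r in hyper]

    def test_raising_cutoff_never_increases_called_bases(self):
        rng = np.random.default_rng(3)
        scores = rng.normal(0, 1, 800)
        scores[100:160] += 2.5
        mut = _bins(np.arange(800) * 100, scores, bin_size=100)
        wt = _bins(np.arange(800) * 100, np.zeros(800), bin_size=100)
        bases = [total_called_bases(call_differential_regions(
            mut, wt, CallParams(), "hyper", z_cutoff=c))
            for c in (0.5, 1.0, 1.5, 2.0, 3.0)]
        assert bases == sorted(bases, reverse=True)

    def test_outputs_sorted_nonoverlapping_in_bounds(self, default_norm,
                                                     default_bundle):
        params = CallParams()
        regions = call_differential_blocks(
            default_norm[("H3K9m2", "met1")], default_norm[("H3K9m2", "WT")],
            params, z_cutoff=params.z_cut_diff_met1)
        by_chrom = {}
        for r in regions:
            by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in by_chrom.items():
            length = len(default_bundle.genome[chrom])
            assert all(0 <= r.start < r.end <= length for r in rs)
            assert all(a.end <= b.start for a, b in zip(rs, rs[1:]))


class TestBlocks:
    def test_all_below_cutoff_empty(self):
        track = _track(np.zeros(50))
        with pytest.warns(UserWarning):
            assert call_blocks(track, CallParams()) == []

    def test_gap_bridging_rule_trace(self):
        # pattern pass,pass,fail,pass bridged by max_gap_probes=2
        values = np.zeros(60)
        values[[10, 11, 13]] = 10.0
        track = _track(values)
        params = CallParams(block_max_gap_probes=2, block_min_probes=4)
        blocks = call_blocks(track, params, z_cutoff=2)
        assert [(b.start, b.end) for b in blocks] == [(1000, 1350)]
        assert blocks[0].n_support == 3  # passing probes; span counts 4

    def test_long_gap_splits_and_min_probes_drops(self):
        # pass,fail,fail,fail,pass: two 1-probe candidates, both dropped
        values = np.zeros(60)
        values[[10, 14]] = 10.0
        track = _track(values)
        params = CallParams(block_max_gap_probes=2, block_min_probes=4)
        assert call_blocks(track, params, z_cutoff=2) == []
        lax = CallParams(block_max_gap_probes=2, block_min_probes=1)
        assert len(call_blocks(track, lax, z_cutoff=2)) == 2


class TestFdr:
    def test_rotation_by_zero_offset_reproduces_call(self):
        rng = np.random.default_rng(5)
        values = rng.normal(0, 1, 300)
        values[50:80] += 4
        track = _track(values)
        params = CallParams()
        observed = call_blocks(track, params, z_cutoff=2)
        rotated = rotate_track(track, {"chr1": 0})
        assert call_blocks(rotated, params, z_cutoff=2) == observed

    def test_planted_strong_signal_is_significant(self):
        rng = np.random.default_rng(9)
        values = rng.normal(0, 1, 1000)
        for start in (100, 300, 700):  # three 5-sd domains of 50 probes
            values[start:start + 50] += 5.0
        diff = _track(values)
        zero = diff.with_values({"chr1": np.zeros(1000)})
        params = CallParams(fdr_permutations=100, seed=0)
        result = estimate_fdr(
            lambda d, z: call_differential_blocks(d, z, params, z_cutoff=2.0),
            (diff, zero), params)
        assert result.observed_count == 3
        assert result.fdr < 0.01
        assert result.significant

    def test_pure_noise_not_significant(self, no_warnings):
        rng = np.random.default_rng(13)
        diff = _track(rng.normal(0, 1, 1000))
        zero = diff.with_values({"chr1": np.zeros(1000)})
        params = CallParams(fdr_permutations=50, seed=1)
        result = estimate_fdr(
            lambda d, z: call_differential_regions(
                bin_track(d, 200, 100), bin_track(z, 200, 100), params,
                "hyper", z_cutoff=2.0, min_region_len=500),
            (diff, zero), params)
        assert not result.significant

    def test_fdr_stable_under_more_permutations(self):
        rng = np.random.default_rng(21)
        values = rng.normal(0, 1, 600)
        values[100:140] += 3.0
        diff = _track(values)
        zero = diff.with_values({"chr1": np.zeros(600)})
        few = dataclasses.replace(CallParams(), fdr_permutations=60, seed=4)
        many = dataclasses.replace(CallParams(), fdr_permutations=120, seed=4)
        call = lambda d, z: call_differential_blocks(d, z, few, z_cutoff=1.5)
        r1 = estimate_fdr(call, (diff, zero), few)
        r2 = estimate_fdr(call, (diff, zero), many)
        assert abs(r1.fdr - r2.fdr) < 0.15  # within Monte-Carlo error
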