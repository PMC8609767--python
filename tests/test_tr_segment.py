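import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import ks_2samp

from gsascar import (
    candidate_breakpoints,
    kde_overlap,
    merge_across_centromere,
    merge_segments,
    segment_chromosome,
    union_segmentations,
)
from gsascar.config import MergeConfig, SegmentationConfig
from gsascar.tr_segment import Segment, TrackSegment


def optimal_breakpoints_sse(values, k):
    """Independent oracle: exhaustive SSE-minimizing k-split by dynamic programming."""
    x = np.asarray(values, dtype=float)
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x**2)])

    def sse(i, j):  # cost of segment x[i:j]
        s, s2, m = c1[j] - c1[i], c2[j] - c2[i], j - i
        return s2 - s * s / m

    cost = np.full((k + 1, n + 1), np.inf)
    back = np.zeros((k + 1, n + 1), dtype=int)
    cost[0] = [sse(0, j) if j > 0 else 0.0 for j in range(n + 1)]
    for splits in range(1, k + 1):
        for j in range(splits + 1, n + 1):
            best = np.inf
            for i in range(splits, j):
                c = cost[splits - 1][i] + sse(i, j)
                if c < best:
                    best, back[splits][j] = c, i
            cost[splits][j] = best
    bps = []
    j = n
    for splits in range(k, 0, -1):
        j = back[splits][j]
        bps.append(j)
    return sorted(bps), cost[k][n]


class TestCandidateBreakpoints:
    def test_step_up_signal(self):
        # hand-computed cumulative sums: -0.5, -1, -1.5, -1, -0.5, 0
        cb = candidate_breakpoints([0, 0, 0, 1, 1, 1])
        assert cb.index_min == 2
        assert cb.informative

    def test_step_down_signal(self):
        cb = candidate_breakpoints([1, 1, 1, 0, 0, 0])
        assert cb.index_max == 2

    def test_constant_flagged_uninformative(self):
        cb = candidate_breakpoints([3.0, 3.0, 3.0, 3.0])
        assert not cb.informative

    def test_matches_cumsum_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        s = np.cumsum(x - x.mean())[:-1]
        cb = candidate_breakpoints(x)
        assert cb.index_max == int(np.argmax(s))
        assert cb.index_min == int(np.argmin(s))


class TestSegmentChromosome:
    CFG = SegmentationConfig(min_bins=10, min_length_bp=0, alpha=0.01)

    def test_noiseless_two_level_exact_boundary(self):
        x = np.concatenate([np.full(200, 0.55), np.full(200, 0.75)])
        tree = segment_chromosome(x, self.CFG)
        leaves = tree.leaves()
        assert leaves == [(0, 200), (200, 400)]
        # oracle: exhaustive single-split SSE minimization agrees
        bps, _ = optimal_breakpoints_sse(x, 1)
        assert bps == [200]

    def test_constant_signal_single_leaf(self):
        tree = segment_chromosome(np.full(100, 0.5), self.CFG)
        assert tree.leaves() == [(0, 100)]

    def test_three_level_staircase_within_three_bins(self):
        rng = np.random.default_rng(7)
        x = np.concatenate(
            [np.full(150, 0.55), np.full(150, 0.70), np.full(150, 0.90)]
        ) + rng.normal(0, 0.02, 450)
        tree = segment_chromosome(x, self.CFG)
        got = sorted(lo for lo, hi in tree.leaves() if lo > 0)
        oracle, _ = optimal_breakpoints_sse(x, 2)
        assert len(got) == 2
        for g, o in zip(got, oracle):
            assert abs(g - o) <= 3

    def test_leaves_partition_chromosome(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1, 300)
        leaves = segment_chromosome(x, self.CFG).leaves()
        assert leaves[0][0] == 0 and leaves[-1][1] == 300
        for (a, b), (c, d) in zip(leaves[:-1], leaves[1:]):
            assert b == c

    def test_deterministic(self):
        rng = np.random.default_rng(11)
        x = np.concatenate([rng.normal(0.5, 0.02, 120), rng.normal(0.8, 0.02, 80)])
        l1 = segment_chromosome(x, self.CFG).leaves()
        l2 = segment_chromosome(x.copy(), self.CFG).leaves()
        assert l1 == l2

    def test_min_length_bp_respected(self):
        x = np.concatenate([np.full(50, 0.5), np.full(50, 0.9)])
        pos = np.column_stack([np.arange(100) * 1000, np.arange(1, 101) * 1000])
        cfg = SegmentationConfig(min_bins=10, min_length_bp=200_000, alpha=0.01)
        tree = segment_chromosome(x, cfg, positions=pos)
        assert tree.leaves() == [(0, 100)]  # each child would span only 50 kb

    def test_empty_input(self):
        assert segment_chromosome([], self.CFG).leaves() == [(0, 0)]


class TestMergeSegments:
    def seg(self, lo, hi):
        return TrackSegment(lo, hi, lo * 1000, hi * 1000)

    def test_same_distribution_merged(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(0.6, 0.02, 200)
        segs = [self.seg(0, 100), self.seg(100, 200)]
        merged = merge_segments(segs, vals)
        assert len(merged) == 1
        # oracle: two-sample KS fails to reject equality of distributions
        assert ks_2samp(vals[:100], vals[100:]).pvalue > 0.05

    def test_distinct_distributions_kept(self):
        rng = np.random.default_rng(4)
        vals = np.concatenate([rng.normal(0.55, 0.02, 100), rng.normal(0.90, 0.02, 100)])
        merged = merge_segments([self.seg(0, 100), self.seg(100, 200)], vals)
        assert len(merged) == 2
        assert ks_2samp(vals[:100], vals[100:]).pvalue < 0.05

    def test_single_segment_unchanged(self):
        vals = np.full(50, 0.5)
        assert merge_segments([self.seg(0, 50)], vals) == [self.seg(0, 50)]

    def test_contraction_and_bin_conservation(self):
        rng = np.random.default_rng(6)
        vals = rng.normal(0.6, 0.05, 300)
        segs = [self.seg(i * 30, (i + 1) * 30) for i in range(10)]
        merged = merge_segments(segs, vals)
        assert len(merged) <= 10
        assert sum(s.n_bins for s in merged) == 300

    def test_zero_variance_equal_segments_merge(self):
        vals = np.full(60, 0.5)
        merged = merge_segments([self.seg(0, 30), self.seg(30, 60)], vals)
        assert len(merged) == 1

    def test_zero_variance_distinct_segments_kept(self):
        vals = np.concatenate([np.full(30, 0.5), np.full(30, 0.9)])
        merged = merge_segments([self.seg(0, 30), self.seg(30, 60)], vals)
        assert len(merged) == 2


def bins_frame(values, col, start=0, width=500_000):
    n = len(values)
    starts = start + np.arange(n) * width
    df = pd.DataFrame(
        {
            "chrom": ["1"] * n,
            "start": starts,
            "end": starts + width,
            "baf": values if col == "baf" else np.nan,
            "lrr": values if col == "lrr" else np.nan,
        }
    )
    return df


class TestUnionSegmentations:
    CFG = SegmentationConfig(min_bins=4, min_length_bp=2_000_000, alpha=0.01)

    def arm(self, n=200):
        baf = bins_frame(np.full(n, 0.6), "baf")
        lrr = bins_frame(np.full(n, 0.0), "lrr")
        return baf, lrr

    def track_segs(self, cuts, n=200, width=500_000):
        bounds = [0] + cuts + [n]
        return [
            TrackSegment(a, b, a * width, b * width) for a, b in zip(bounds[:-1], bounds[1:])
        ]

    def test_union_of_breakpoint_sets(self):
        baf_bins, lrr_bins = self.arm()
        out = union_segmentations(self.track_segs([100]), self.track_segs([160]), baf_bins, lrr_bins, "1", self.CFG)
        assert [(s.start, s.end) for s in out] == [
            (0, 50_000_000),
            (50_000_000, 80_000_000),
            (80_000_000, 100_000_000),
        ]

    def test_identical_break_sets_unchanged(self):
        baf_bins, lrr_bins = self.arm()
        out = union_segmentations(self.track_segs([100]), self.track_segs([100]), baf_bins, lrr_bins, "1", self.CFG)
        assert [(s.start, s.end) for s in out] == [(0, 50_000_000), (50_000_000, 100_000_000)]

    def test_sliver_absorbed_into_closer_neighbor(self):
        # BAF break at bin 100, LRR break at bin 101 -> 1-bin sliver dissolves
        baf_bins, lrr_bins = self.arm()
        out = union_segmentations(self.track_segs([100]), self.track_segs([101]), baf_bins, lrr_bins, "1", self.CFG)
        assert len(out) == 2
        assert out[0].end == out[1].start

    def test_segment_means_come_from_member_bins(self):
        n = 200
        baf_vals = np.concatenate([np.full(100, 0.55), np.full(100, 0.75)])
        baf_bins = bins_frame(baf_vals, "baf")
        lrr_bins = bins_frame(np.full(n, 0.2), "lrr")
        out = union_segmentations(self.track_segs([100]), self.track_segs([]), baf_bins, lrr_bins, "1", self.CFG)
        assert out[0].mean_baf == pytest.approx(0.55)
        assert out[1].mean_baf == pytest.approx(0.75)
        assert out[0].mean_lrr == pytest.approx(0.2)


class TestMergeAcrossCentromere:
    def chrom_bins(self, toy_annotation, p_baf, q_baf, width=500_000):
        rows = []
        cs, ce = toy_annotation.centromeres["1"]
        for start in range(0, toy_annotation.lengths["1"] - width + 1, width):
            end = start + width
            if start < ce and end > cs:
                continue
            val = p_baf if end <= cs else q_baf
            rows.append(("1", start, end, val, 0.0))
        return pd.DataFrame(rows, columns=["chrom", "start", "end", "baf", "lrr"])

    def segments_for(self, bins, toy_annotation):
        cs, ce = toy_annotation.centromeres["1"]
        p = bins[bins["end"] <= cs]
        q = bins[bins["start"] >= ce]
        out = []
        for part in (p, q):
            if len(part):
                out.append(
                    Segment("1", int(part["start"].min()), int(part["end"].max()), len(part), float(part["baf"].mean()), 0.0)
                )
        return out

    def test_matching_flanks_merged(self, toy_annotation):
        rng = np.random.default_rng(8)
        bins = self.chrom_bins(toy_annotation, 0.6, 0.6)
        bins["baf"] += rng.normal(0, 0.02, len(bins))
        segs = self.segments_for(bins, toy_annotation)
        out = merge_across_centromere(segs, toy_annotation, bins, bins)
        assert len(out) == 1
        cs, ce = toy_annotation.centromeres["1"]
        pvals = bins[bins["end"] <= cs]["baf"]
        qvals = bins[bins["start"] >= ce]["baf"]
        assert ks_2samp(pvals, qvals).pvalue > 0.05  # oracle: same distribution

    def test_distinct_flanks_kept(self, toy_annotation):
        rng = np.random.default_rng(9)
        bins = self.chrom_bins(toy_annotation, 0.5, 0.67)
        bins["baf"] += rng.normal(0, 0.02, len(bins))
        segs = self.segments_for(bins, toy_annotation)
        out = merge_across_centromere(segs, toy_annotation, bins, bins)
        assert len(out) == 2
        cs, ce = toy_annotation.centromeres["1"]
        assert ks_2samp(bins[bins["end"] <= cs]["baf"], bins[bins["start"] >= ce]["baf"]).pvalue < 0.05

    def test_missing_q_arm_unchanged(self, toy_annotation):
        bins = self.chrom_bins(toy_annotation, 0.6, 0.6)
        cs, _ = toy_annotation.centromeres["1"]
        bins = bins[bins["end"] <= cs].reset_index(drop=True)
        segs = self.segments_for(bins, toy_annotation)
        out = merge_across_centromere(segs, toy_annotation, bins, bins)
        assert out == segs


class TestKdeOverlap:
    def test_identical_samples_full_overlap(self):
        rng = np.random.default_rng(10)
        x = rng.normal(0, 1, 100)
        assert kde_overlap(x, x) == pytest.approx(1.0, abs=0.02)

    def test_disjoint_samples_no_overlap(self):
        rng = np.random.default_rng(11)
        assert kde_overlap(rng.normal(0, 0.01, 100), rng.normal(5, 0.01, 100)) < 0.01

    @settings(derandomize=True, max_examples=25)
    @given(st.integers(0, 10_000))
    def test_bounded_in_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.01, 1), 50)
        y = rng.normal(rng.uniform(-1, 1), rng.uniform(0.01, 1), 50)
        assert -1e-6 <= kde_overlap(x, y) <= 1.0 + 1e-6
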