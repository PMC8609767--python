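"""Tree-recursion (TR) segmentation of BAF and LRR tracks.

Each chromosome arm is the root of a recursion: the cumulative run length of
the data about its mean, S_k = sum_{i<=k}(x_i - mean), peaks where the local
level changes, so its argmax and argmin are the candidate breakpoints.  A
candidate is recorded only when both resulting children are long enough (bin
count and bp span) and their means differ significantly; recursion then
continues inside each child.  The BAF and LRR tracks are segmented
separately, adjacent segments closest to the same distribution (by KDE
overlap) are merged, the two breakpoint sets are unioned, slivers are
dissolved into the more similar neighbor, and segments flanking the
centromere gap are rejoined when their distributions match.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import gaussian_kde

from .config import GsaConfig, MergeConfig, SegmentationConfig
from .tracks_io import BinTrack, GenomeAnnotation, Segment

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Candidate breakpoints
# ---------------------------------------------------------------------------

class CandidateBreakpoints(NamedTuple):
    """Argmax/argmin of the cumulative run length; ``informative`` is False
    for (near-)constant input, where the extrema carry no signal.

    A breakpoint at index k is the boundary between bins k and k+1.
    """

    index_max: int
    index_min: int
    informative: bool


def candidate_breakpoints(values: Sequence[float]) -> CandidateBreakpoints:
    """Locate the extrema of S_k = cumulative sum of (x_i - mean)."""
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 values")
    s = np.cumsum(x - x.mean())
    inner = s[:-1]  # boundary after the last bin is not a split
    informative = bool(np.max(np.abs(inner)) > _EPS * max(1.0, np.abs(x).max()))
    return CandidateBreakpoints(int(np.argmax(inner)), int(np.argmin(inner)), informative)


# ---------------------------------------------------------------------------
# Recursive segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentationNode:
    """Node of the recursion tree over bin index range [lo, hi)."""

    lo: int
    hi: int
    breakpoint: Optional[int] = None  # global index of first bin of right child
    children: list["SegmentationNode"] = field(default_factory=list)

    def leaves(self) -> list[tuple[int, int]]:
        if not self.children:
            return [(self.lo, self.hi)]
        out: list[tuple[int, int]] = []
        for c in self.children:
            out.extend(c.leaves())
        return out


def mean_diff_pvalue(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided Welch test p-value, robust to (near-)constant children.

    With essentially zero variance on both sides the test degenerates to an
    exact comparison of the means.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    diff = abs(a.mean() - b.mean())
    scale = max(np.abs(a).max(initial=0.0), np.abs(b).max(initial=0.0), 1.0)
    if (a.std() < _EPS * scale and b.std() < _EPS * scale) or min(len(a), len(b)) < 2:
        return 0.0 if diff > _EPS * scale else 1.0
    import warnings

    with warnings.catch_warnings():
        # near-identical children trip a scipy precision warning; the NaN
        # fallback below handles that case exactly
        warnings.simplefilter("ignore", RuntimeWarning)
        p = stats.ttest_ind(a, b, equal_var=False).pvalue
    if math.isnan(p):
        return 0.0 if diff > _EPS * scale else 1.0
    return float(p)


def segment_chromosome(
    values: Sequence[float],
    params: SegmentationConfig | None = None,
    positions: Optional[np.ndarray] = None,
) -> SegmentationNode:
    """Recursively segment one chromosome arm's value vector.

    ``positions`` (optional) gives each bin's (start, end) in bp as an
    (n, 2) array; without it the minimum-span rule is skipped.  Returns the
    recursion tree; its leaves partition [0, n).
    """
    cfg = params or SegmentationConfig()
    x = np.asarray(values, dtype=float)
    root = SegmentationNode(0, len(x))
    if len(x) == 0:
        return root

    def span_ok(lo: int, hi: int) -> bool:
        if hi - lo < cfg.min_bins:
            return False
        if positions is not None:
            if positions[hi - 1, 1] - positions[lo, 0] < cfg.min_length_bp:
                return False
        return True

    def build(node: SegmentationNode) -> None:
        lo, hi = node.lo, node.hi
        if hi - lo < 2:
            return
        cand = candidate_breakpoints(x[lo:hi])
        if not cand.informative:
            return
        # try both extrema; the split with the larger mean difference first
        mids = []
        for k in {cand.index_max, cand.index_min}:
            mid = lo + k + 1
            gap = abs(x[lo:mid].mean() - x[mid:hi].mean())
            mids.append((gap, mid))
        mids.sort(reverse=True)
        for _, mid in mids:
            if not (span_ok(lo, mid) and span_ok(mid, hi)):
                continue
            if mean_diff_pvalue(x[lo:mid], x[mid:hi]) >= cfg.alpha:
                continue
            node.breakpoint = mid
            node.children = [SegmentationNode(lo, mid), SegmentationNode(mid, hi)]
            for child in node.children:
                build(child)
            return

    build(root)
    return root


# ---------------------------------------------------------------------------
# Single-track segments and KDE-based merging
# ---------------------------------------------------------------------------

@dataclass
class TrackSegment:
    """A segment of one value vector: bin index range plus bp extent."""

    lo: int
    hi: int
    start: int
    end: int

    @property
    def n_bins(self) -> int:
        return self.hi - self.lo

    def mean(self, values: np.ndarray) -> float:
        return float(values[self.lo : self.hi].mean())


def _track_segments(node: SegmentationNode, positions: np.ndarray) -> list[TrackSegment]:
    return [
        TrackSegment(lo, hi, int(positions[lo, 0]), int(positions[hi - 1, 1]))
        for lo, hi in node.leaves()
    ]


def kde_overlap(x: np.ndarray, y: np.ndarray, bandwidth: str = "silverman") -> float:
    """Overlap coefficient (integral of the pointwise minimum) of two KDEs.

    Degenerate (constant or single-point) samples are treated as point
    masses: overlap 1 when the means coincide, 0 otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    scale = max(np.abs(x).max(initial=0.0), np.abs(y).max(initial=0.0), 1.0)
    degenerate = (
        len(x) < 2 or len(y) < 2 or np.ptp(x) < 1e-9 * scale or np.ptp(y) < 1e-9 * scale
    )
    if degenerate:
        return 1.0 if abs(x.mean() - y.mean()) <= 1e-9 * scale else 0.0
    kx = gaussian_kde(x, bw_method=bandwidth)
    ky = gaussian_kde(y, bw_method=bandwidth)
    bw = max(np.sqrt(kx.covariance[0, 0]), np.sqrt(ky.covariance[0, 0]))
    lo = min(x.min(), y.min()) - 3 * bw
    hi = max(x.max(), y.max()) + 3 * bw
    grid = np.linspace(lo, hi, 512)
    return float(np.trapezoid(np.minimum(kx(grid), ky(grid)), grid))


def merge_segments(
    segments: list[TrackSegment], values: np.ndarray, params: MergeConfig | None = None
) -> list[TrackSegment]:
    """Iteratively merge the most similar adjacent pair of segments.

    At each round the adjacent pair with the highest KDE overlap of their
    bin-value distributions is combined, provided the overlap reaches the
    merge threshold; statistics are recomputed and the loop repeats until no
    adjacent pair is similar enough.
    """
    cfg = params or MergeConfig()
    segs = list(segments)
    if len(segs) < 2:
        return segs
    vals = np.asarray(values, dtype=float)

    def overlap(i: int) -> float:
        a, b = segs[i], segs[i + 1]
        return kde_overlap(vals[a.lo : a.hi], vals[b.lo : b.hi], cfg.bandwidth)

    overlaps = [overlap(i) for i in range(len(segs) - 1)]
    while overlaps:
        i = int(np.argmax(overlaps))
        if overlaps[i] < cfg.kde_overlap:
            break
        a, b = segs[i], segs[i + 1]
        segs[i : i + 2] = [TrackSegment(a.lo, b.hi, a.start, b.end)]
        overlaps.pop(i)
        if i < len(overlaps):
            overlaps[i] = overlap(i)
        if i > 0:
            overlaps[i - 1] = overlap(i - 1)
    return segs


# ---------------------------------------------------------------------------
# Union of the BAF and LRR segmentations
# ---------------------------------------------------------------------------

@dataclass
class _UnionSegment:
    """Working representation during the union step: member bins of each track."""

    chrom: str
    start: int
    end: int
    baf_idx: np.ndarray  # indices into the BAF bin frame
    lrr_idx: np.ndarray

    def stats(self, baf_bins: pd.DataFrame, lrr_bins: pd.DataFrame) -> Segment:
        baf = baf_bins["baf"].to_numpy(dtype=float)[self.baf_idx]
        lrr = lrr_bins["lrr"].to_numpy(dtype=float)[self.lrr_idx]
        starts = set(baf_bins["start"].to_numpy()[self.baf_idx]) | set(
            lrr_bins["start"].to_numpy()[self.lrr_idx]
        )
        n_bins = len(starts)
        # a near-homozygous region keeps only a censored handful of SNP bins
        # after the homozygosity filter; such a mean BAF is a truncation
        # artifact, so the segment is marked BAF-uninformative instead
        baf_informative = len(baf) >= 5 and len(baf) >= 0.05 * n_bins
        return Segment(
            chrom=self.chrom,
            start=self.start,
            end=self.end,
            n_bins=n_bins,
            mean_baf=float(baf.mean()) if baf_informative else float("nan"),
            mean_lrr=float(lrr.mean()) if len(lrr) else float("nan"),
        )


def union_segmentations(
    baf_segments: list[TrackSegment],
    lrr_segments: list[TrackSegment],
    baf_bins: pd.DataFrame,
    lrr_bins: pd.DataFrame,
    chrom: str,
    params: SegmentationConfig | None = None,
) -> list[Segment]:
    """Union the BAF and LRR breakpoint sets over one chromosome arm.

    Segment boundaries are the union of both internal breakpoint sets; bins
    of each track are assigned to intervals by midpoint; intervals that end
    up too short or too sparse are iteratively removed — their span is
    absorbed by the neighbor with the closer mean (BAF preferred, LRR as
    fallback) but their data points are discarded as unreliable, so the
    absorbing segment's statistics stay uncontaminated.
    """
    cfg = params or SegmentationConfig()
    if not baf_segments and not lrr_segments:
        return []
    starts = [s.start for s in baf_segments] + [s.start for s in lrr_segments]
    ends = [s.end for s in baf_segments] + [s.end for s in lrr_segments]
    lo, hi = min(starts), max(ends)
    cuts = sorted(
        {s.start for s in baf_segments[1:]} | {s.start for s in lrr_segments[1:]}
    )
    bounds = [lo] + [c for c in cuts if lo < c < hi] + [hi]

    baf_mid = ((baf_bins["start"] + baf_bins["end"]) / 2).to_numpy()
    lrr_mid = ((lrr_bins["start"] + lrr_bins["end"]) / 2).to_numpy()
    segs: list[_UnionSegment] = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        segs.append(
            _UnionSegment(
                chrom,
                a,
                b,
                np.flatnonzero((baf_mid >= a) & (baf_mid < b)),
                np.flatnonzero((lrr_mid >= a) & (lrr_mid < b)),
            )
        )

    def too_small(u: _UnionSegment) -> bool:
        s = u.stats(baf_bins, lrr_bins)
        return s.n_bins < cfg.min_bins or s.length < cfg.min_length_bp

    def neighbor_distance(u: _UnionSegment, v: _UnionSegment) -> float:
        su, sv = u.stats(baf_bins, lrr_bins), v.stats(baf_bins, lrr_bins)
        if np.isfinite(su.mean_baf) and np.isfinite(sv.mean_baf):
            return abs(su.mean_baf - sv.mean_baf)
        if np.isfinite(su.mean_lrr) and np.isfinite(sv.mean_lrr):
            return abs(su.mean_lrr - sv.mean_lrr)
        return 0.0

    while len(segs) > 1:
        small = [i for i, u in enumerate(segs) if too_small(u)]
        if not small:
            break
        i = min(small, key=lambda i: (segs[i].stats(baf_bins, lrr_bins).n_bins, segs[i].end - segs[i].start))
        if i == 0:
            j = 1
        elif i == len(segs) - 1:
            j = i - 1
        else:
            j = i - 1 if neighbor_distance(segs[i], segs[i - 1]) <= neighbor_distance(segs[i], segs[i + 1]) else i + 1
        keeper, sliver = segs[j], segs[i]
        merged = _UnionSegment(
            chrom,
            min(keeper.start, sliver.start),
            max(keeper.end, sliver.end),
            keeper.baf_idx,  # the sliver's bins are dropped, not inherited
            keeper.lrr_idx,
        )
        segs[min(i, j) : max(i, j) + 1] = [merged]

    return [u.stats(baf_bins, lrr_bins) for u in segs]


# ---------------------------------------------------------------------------
# Centromere handling and whole-genome driver
# ---------------------------------------------------------------------------

def _segment_values(seg: Segment, bins: pd.DataFrame, col: str) -> np.ndarray:
    mid = ((bins["start"] + bins["end"]) / 2).to_numpy()
    vals = bins[col].to_numpy(dtype=float)
    sel = (mid >= seg.start) & (mid < seg.end)
    return vals[sel][np.isfinite(vals[sel])]


def _combine(a: Segment, b: Segment) -> Segment:
    def wmean(x: float, nx: int, y: float, ny: int) -> float:
        if not np.isfinite(x):
            return y
        if not np.isfinite(y):
            return x
        return (x * nx + y * ny) / max(nx + ny, 1)

    return Segment(
        chrom=a.chrom,
        start=a.start,
        end=b.end,
        n_bins=a.n_bins + b.n_bins,
        mean_baf=wmean(a.mean_baf, a.n_bins, b.mean_baf, b.n_bins),
        mean_lrr=wmean(a.mean_lrr, a.n_bins, b.mean_lrr, b.n_bins),
    )


def merge_across_centromere(
    segments: list[Segment],
    annotation: GenomeAnnotation,
    baf_bins: pd.DataFrame,
    lrr_bins: pd.DataFrame,
    params: MergeConfig | None = None,
) -> list[Segment]:
    """Rejoin the segments flanking the centromere gap of one chromosome.

    The last p-arm segment and the first q-arm segment are merged when their
    bin-value distributions pass the same KDE-overlap test used during
    within-arm merging; BAF is compared when both sides carry informative
    SNP bins, LRR otherwise.
    """
    cfg = params or MergeConfig()
    if not segments:
        return segments
    chrom = segments[0].chrom
    cs, ce = annotation.centromeres[chrom]
    p_side = [s for s in segments if s.end <= cs]
    q_side = [s for s in segments if s.start >= ce]
    if not p_side or not q_side:
        return segments
    left, right = p_side[-1], q_side[0]
    a_baf = _segment_values(left, baf_bins, "baf")
    b_baf = _segment_values(right, baf_bins, "baf")
    if len(a_baf) >= 2 and len(b_baf) >= 2:
        similar = kde_overlap(a_baf, b_baf, cfg.bandwidth) >= cfg.kde_overlap
    else:
        a_lrr = _segment_values(left, lrr_bins, "lrr")
        b_lrr = _segment_values(right, lrr_bins, "lrr")
        similar = kde_overlap(a_lrr, b_lrr, cfg.bandwidth) >= cfg.kde_overlap
    if not similar:
        return segments
    merged = _combine(left, right)
    out = p_side[:-1] + [merged] + q_side[1:]
    return out


def _arm_frames(bins: pd.DataFrame, cs: int, ce: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    mid = (bins["start"] + bins["end"]) / 2
    return (
        bins[mid < cs].reset_index(drop=True),
        bins[mid >= ce].reset_index(drop=True),
    )


def segment_genome(
    baf_track: BinTrack,
    lrr_track: BinTrack,
    annotation: GenomeAnnotation,
    config: GsaConfig | None = None,
) -> list[Segment]:
    """Segment preprocessed BAF and LRR tracks into genome-wide segments.

    ``baf_track`` must already be homozygous-filtered and mirrored;
    ``lrr_track`` outlier-filtered.  Each chromosome arm is segmented
    separately on each track, merged, unioned, and finally tested across
    the centromere gap.
    """
    cfg = config or GsaConfig()
    out: list[Segment] = []
    for chrom in annotation.chromosomes:
        baf_bins = baf_track.chromosome(chrom)
        lrr_bins = lrr_track.chromosome(chrom)
        if baf_bins.empty and lrr_bins.empty:
            continue
        cs, ce = annotation.centromeres[chrom]
        chrom_segs: list[Segment] = []
        for (baf_arm, lrr_arm) in zip(_arm_frames(baf_bins, cs, ce), _arm_frames(lrr_bins, cs, ce)):
            arm_pieces: dict[str, list[TrackSegment]] = {}
            for name, frame, col in (("baf", baf_arm, "baf"), ("lrr", lrr_arm, "lrr")):
                vals_all = frame[col].to_numpy(dtype=float)
                keep = np.isfinite(vals_all)
                frame_valid = frame[keep].reset_index(drop=True)
                vals = vals_all[keep]
                if len(vals) == 0:
                    arm_pieces[name] = []
                    continue
                pos = frame_valid[["start", "end"]].to_numpy()
                tree = segment_chromosome(vals, cfg.segmentation, positions=pos)
                pieces = _track_segments(tree, pos)
                arm_pieces[name] = merge_segments(pieces, vals, cfg.merge)
            baf_valid = baf_arm[np.isfinite(baf_arm["baf"].to_numpy(dtype=float))].reset_index(drop=True)
            lrr_valid = lrr_arm[np.isfinite(lrr_arm["lrr"].to_numpy(dtype=float))].reset_index(drop=True)
            chrom_segs.extend(
                union_segmentations(
                    arm_pieces["baf"], arm_pieces["lrr"], baf_valid, lrr_valid, chrom, cfg.segmentation
                )
            )
        chrom_segs.sort(key=lambda s: s.start)
        chrom_segs = merge_across_centromere(
            chrom_segs, annotation, baf_bins, lrr_bins, cfg.merge
        )
        out.extend(chrom_segs)
    return out
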