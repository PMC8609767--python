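"""Genomic scar counters (LOH / TAI / LST) and the ploidy-corrected HRD score.

All three counters run on segments carrying integer allele-specific copy
numbers (n_A, n_B):

* LOH — regions with minor allele copy 0 (and at least one copy retained)
  longer than 15 Mb, excluding regions spanning a whole chromosome;
* TAI — allelically imbalanced segments reaching a chromosome arm's
  outermost covered position, confined to one arm, longer than 11 Mb;
* LST — per arm, after dropping segments shorter than 3 Mb and merging
  equal neighbors, breakpoints whose two flanking segments are both at
  least 10 Mb.

The combined score deducts the genome ploidy: HRD = LOH + TAI + LST - K *
ploidy with K = 15.5, and a sample is called HRD-positive at score >= 30.
Higher ploidy inflates raw scar counts for reasons unrelated to repair
deficiency, which is what the deduction compensates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as _scipy_stats

from .config import ScarConfig
from .tracks_io import AllelicSegment, GenomeAnnotation

MB = 1_000_000


@dataclass
class ScarScores:
    loh: int
    tai: int
    lst: int
    ploidy: float
    k: float
    hrd_score: float
    hrd_status: str
    threshold: float

    def to_dict(self) -> dict:
        return {
            "loh": self.loh,
            "tai": self.tai,
            "lst": self.lst,
            "ploidy": self.ploidy,
            "k": self.k,
            "hrd_score": self.hrd_score,
            "hrd_status": self.hrd_status,
            "threshold": self.threshold,
        }


def _by_chromosome(
    segments: Sequence[AllelicSegment], annotation: GenomeAnnotation
) -> dict[str, list[AllelicSegment]]:
    out: dict[str, list[AllelicSegment]] = {}
    for s in segments:
        if s.cn < 0:
            continue
        out.setdefault(s.chrom, []).append(s)
    for c in out:
        out[c].sort(key=lambda s: s.start)
    return {c: out[c] for c in annotation.chromosomes if c in out}


def count_loh(
    segments: Sequence[AllelicSegment],
    annotation: GenomeAnnotation,
    params: ScarConfig | None = None,
) -> int:
    """Count LOH regions longer than the threshold, excluding whole-chromosome LOH.

    Consecutive segments with minor allele copy 0 and total copy number >= 1
    form one LOH region.  A region spanning the chromosome's entire covered
    extent reflects whole-chromosome loss rather than a focal scar and is
    not counted.
    """
    cfg = params or ScarConfig()
    n = 0
    for chrom, segs in _by_chromosome(segments, annotation).items():
        covered_start = segs[0].start
        covered_end = segs[-1].end
        is_loh = [s.minor_cn == 0 and s.cn >= 1 for s in segs]
        i = 0
        while i < len(segs):
            if not is_loh[i]:
                i += 1
                continue
            j = i
            while j + 1 < len(segs) and is_loh[j + 1]:
                j += 1
            start, end = segs[i].start, segs[j].end
            whole = start <= covered_start and end >= covered_end
            if (end - start) > cfg.loh_mb * MB and not whole:
                n += 1
            i = j + 1
    return n


def count_tai(
    segments: Sequence[AllelicSegment],
    annotation: GenomeAnnotation,
    params: ScarConfig | None = None,
) -> int:
    """Count telomeric allelic imbalances.

    A segment counts when (a) its outer boundary reaches the outermost
    covered position of its chromosome arm (targeted panels never reach the
    literal telomere), (b) it lies entirely within one arm and (c) it is
    longer than the threshold.
    """
    cfg = params or ScarConfig()
    n = 0
    for chrom, segs in _by_chromosome(segments, annotation).items():
        cs, ce = annotation.centromeres[chrom]
        covered_start = segs[0].start
        covered_end = segs[-1].end
        for s in segs:
            if s.n_a == s.n_b:
                continue
            if (s.end - s.start) <= cfg.tai_mb * MB:
                continue
            arm = annotation.arm_of(chrom, s.start, s.end)
            if arm == "pq":
                continue
            p_telomeric = arm == "p" and s.start <= covered_start
            q_telomeric = arm == "q" and s.end >= covered_end
            if p_telomeric or q_telomeric:
                n += 1
    return n


def count_lst(
    segments: Sequence[AllelicSegment],
    annotation: GenomeAnnotation,
    params: ScarConfig | None = None,
) -> int:
    """Count large-scale state transitions per chromosome arm.

    Within each arm, segments shorter than the filter threshold are removed,
    adjacent segments with identical (n_A, n_B) are merged, and every
    breakpoint whose two flanking segments are both at least the flank
    threshold long adds one.
    """
    cfg = params or ScarConfig()
    n = 0
    for chrom, segs in _by_chromosome(segments, annotation).items():
        cs, ce = annotation.centromeres[chrom]
        for arm in ("p", "q"):
            arm_segs = []
            for s in segs:
                # clip to the arm; a centromere-spanning segment contributes to both
                start = s.start if arm == "p" else max(s.start, ce)
                end = min(s.end, cs) if arm == "p" else s.end
                if end > start:
                    arm_segs.append((start, end, s.n_a, s.n_b))
            arm_segs = [t for t in arm_segs if (t[1] - t[0]) >= cfg.lst_filter_mb * MB]
            if cfg.merge_equal_neighbors:
                merged: list[list] = []
                for t in arm_segs:
                    if merged and (merged[-1][2], merged[-1][3]) == (t[2], t[3]):
                        merged[-1][1] = t[1]
                    else:
                        merged.append(list(t))
                arm_segs = [tuple(t) for t in merged]
            for a, b in zip(arm_segs[:-1], arm_segs[1:]):
                if (a[1] - a[0]) >= cfg.lst_flank_mb * MB and (b[1] - b[0]) >= cfg.lst_flank_mb * MB:
                    n += 1
    return n


def hrd_score(loh: int, tai: int, lst: int, ploidy: float, k: float = 15.5) -> float:
    """HRD score = LOH + TAI + LST - K * ploidy."""
    return float(loh + tai + lst - k * ploidy)


def classify_hrd(score: float, threshold: float = 30.0) -> str:
    """'positive' at score >= threshold, else 'negative'."""
    return "positive" if score >= threshold else "negative"


def compute_scar_scores(
    segments: Sequence[AllelicSegment],
    annotation: GenomeAnnotation,
    ploidy: float,
    params: ScarConfig | None = None,
) -> ScarScores:
    cfg = params or ScarConfig()
    loh = count_loh(segments, annotation, cfg)
    tai = count_tai(segments, annotation, cfg)
    lst = count_lst(segments, annotation, cfg)
    score = hrd_score(loh, tai, lst, ploidy, cfg.k)
    return ScarScores(
        loh=loh,
        tai=tai,
        lst=lst,
        ploidy=ploidy,
        k=cfg.k,
        hrd_score=score,
        hrd_status=classify_hrd(score, cfg.threshold),
        threshold=cfg.threshold,
    )


def summarize_scores(values: Sequence[float]) -> tuple[float, float, float, float]:
    """(mean, median, min, max) of a collection of HRD scores."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("need at least 1 value")
    return float(x.mean()), float(np.median(x)), float(x.min()), float(x.max())


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Sample Pearson correlation between two equally long score vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for constant input")
    return float(_scipy_stats.pearsonr(x, y)[0])
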