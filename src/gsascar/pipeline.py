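"""End-to-end orchestration: track -> segments -> purity/ploidy -> scar scores."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import GsaConfig
from .preprocess import FilterReport, filter_homozygous, filter_lrr_outliers, mirror_baf
from .purity_ploidy import (
    PurityPloidyFit,
    allelic_from_segments,
    assign_integer_cn,
    cluster_genotypes,
    compute_ploidy,
    fit_purity_ploidy,
)
from .scar_scores import ScarScores, compute_scar_scores
from .tracks_io import AllelicSegment, BinTrack, GenomeAnnotation, Segment
from .tr_segment import segment_genome


@dataclass
class PipelineResult:
    segments: list[AllelicSegment]
    fit: PurityPloidyFit
    scores: Optional[ScarScores]
    filter_reports: dict[str, FilterReport] = field(default_factory=dict)

    def report(self) -> dict:
        out = {
            "purity": self.fit.purity,
            "scale_factor": self.fit.scale_factor,
            "low_confidence": self.fit.low_confidence,
            "ploidy": None,
            "loh": None,
            "tai": None,
            "lst": None,
            "k": None,
            "hrd_score": None,
            "hrd_status": None,
        }
        if self.scores is not None:
            out.update(self.scores.to_dict())
        return out


def run_pipeline(
    track: BinTrack,
    annotation: GenomeAnnotation,
    config: GsaConfig | None = None,
) -> PipelineResult:
    """Run the full scar analysis on one BAF/LRR track.

    The BAF and LRR tracks are filtered and segmented separately, segments
    are clustered into genotypes, purity and scale factor estimated, integer
    allele-specific copy numbers assigned, and the scar scores computed.
    When purity cannot be estimated (no allelic imbalance anywhere) the
    sample is reported as-is with the headline fields present but null
    except ploidy-free counts.
    """
    cfg = config or GsaConfig()
    reports: dict[str, FilterReport] = {}

    baf_mask = np.isfinite(track.bins["baf"].to_numpy(dtype=float))
    baf_track = track.subset(baf_mask)
    baf_track, reports["homozygous"] = filter_homozygous(baf_track, cfg.homozygous_baf)
    baf_track = mirror_baf(baf_track)

    lrr_mask = np.isfinite(track.bins["lrr"].to_numpy(dtype=float))
    lrr_track = track.subset(lrr_mask)
    lrr_track, reports["lrr_outliers"] = filter_lrr_outliers(lrr_track, cfg.lrr_outlier_filter)

    segments = segment_genome(baf_track, lrr_track, annotation, cfg)
    allelic = allelic_from_segments(segments)

    clusters = cluster_genotypes(allelic, cfg.purity)
    fit = fit_purity_ploidy(clusters, cfg.purity)

    scores: Optional[ScarScores] = None
    if fit.purity is not None and fit.scale_factor is not None:
        allelic = assign_integer_cn(allelic, fit, cfg.purity.cn_max)
        fit.ploidy = compute_ploidy(allelic, annotation)
        scores = compute_scar_scores(allelic, annotation, fit.ploidy, cfg.scars)
    return PipelineResult(segments=allelic, fit=fit, scores=scores, filter_reports=reports)
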