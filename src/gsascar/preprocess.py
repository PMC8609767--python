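"""Noise-reduction filters applied to BAF and LRR tracks before segmentation.

Homozygous SNP bins (BAF >= 0.95 or <= 0.05) carry no allelic information
and are dropped from the BAF track; the remaining BAF values are mirrored
about 0.5 onto [0.5, 1] so that allele phase does not matter.  The LRR
track is optionally cleaned by removing bins whose kernel-density score is
in the lowest 30% — isolated depth outliers sit in low-density regions of
the LRR distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

from .config import HomozygousBafConfig, LrrOutlierConfig
from .tracks_io import BinTrack

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Bookkeeping for a filtering step: input/removed counts and per-chromosome retention."""

    n_input: int
    n_removed: int
    retained_fraction: dict[str, float] = field(default_factory=dict)

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


def _report(track: BinTrack, kept: np.ndarray) -> FilterReport:
    rep = FilterReport(n_input=len(kept), n_removed=int((~kept).sum()))
    chroms = track.bins["chrom"].to_numpy()
    for c in track.annotation.chromosomes:
        mask = chroms == c
        if mask.any():
            rep.retained_fraction[c] = float(kept[mask].mean())
    return rep


def filter_homozygous(
    track: BinTrack, config: HomozygousBafConfig | None = None
) -> tuple[BinTrack, FilterReport]:
    """Drop bins whose BAF marks a homozygous SNP (BAF >= high or <= low, inclusive).

    Operates on the BAF track only; callers keep their LRR track untouched.
    Bins with missing BAF are retained.
    """
    cfg = config or HomozygousBafConfig()
    baf = track.bins["baf"].to_numpy(dtype=float)
    homozygous = (baf >= cfg.high) | (baf <= cfg.low)
    homozygous &= ~np.isnan(baf)
    kept = ~homozygous
    return track.subset(kept), _report(track, kept)


def mirror_baf(track: BinTrack) -> BinTrack:
    """Fold BAF about 0.5: BAF -> |BAF - 0.5| + 0.5, mapping onto [0.5, 1]."""
    bins = track.bins.copy()
    bins["baf"] = np.abs(bins["baf"].to_numpy(dtype=float) - 0.5) + 0.5
    return BinTrack(bins, track.annotation)


def lrr_density_scores(lrr: np.ndarray, bandwidth: str = "silverman") -> np.ndarray:
    """Per-bin probability density of the genome-wide LRR distribution."""
    if np.ptp(lrr) < 1e-12:
        return np.ones_like(lrr)
    kde = gaussian_kde(lrr, bw_method=bandwidth)
    return kde(lrr)


def filter_lrr_outliers(
    track: BinTrack, config: LrrOutlierConfig | None = None
) -> tuple[BinTrack, FilterReport]:
    """Remove bins whose LRR density score is below the configured quantile.

    A Gaussian KDE (Silverman bandwidth) is fit to all LRR values genome-wide;
    each bin is scored by the density at its own LRR and bins scoring strictly
    below the 30th percentile of scores are removed (ties are kept, so the
    retained set is never empty).  With fewer than ``min_bins`` LRR values the
    filter is skipped with a warning.
    """
    cfg = config or LrrOutlierConfig(enabled=True)
    lrr = track.bins["lrr"].to_numpy(dtype=float)
    finite = np.isfinite(lrr)
    if not cfg.enabled or finite.sum() < cfg.min_bins:
        if cfg.enabled:
            logger.warning(
                "LRR outlier filter skipped: only %d bins (< %d)", finite.sum(), cfg.min_bins
            )
        kept = np.ones(len(track), dtype=bool)
        return track.subset(kept), _report(track, kept)
    scores = lrr_density_scores(lrr[finite], cfg.bandwidth)
    cutoff = np.percentile(scores, 100.0 * cfg.quantile)
    kept = np.ones(len(track), dtype=bool)
    kept[finite] = scores >= cutoff  # strict < removed; ties at cutoff kept
    return track.subset(kept), _report(track, kept)
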