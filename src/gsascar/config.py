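"""Configuration for the genomic scar analysis pipeline.

All tunable parameters live in small dataclasses bundled into
:class:`GsaConfig`.  Every threshold the pipeline uses is reachable from
here; a YAML file with the same nesting can override any subset of keys.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any

import yaml


@dataclass
class HomozygousBafConfig:
    """Bounds for the homozygous-SNP filter (inclusive on both sides)."""

    low: float = 0.05
    high: float = 0.95


@dataclass
class LrrOutlierConfig:
    """Density-based LRR outlier filter.

    Bins whose kernel-density score falls below the ``quantile`` percentile
    of all per-bin density scores are dropped.  The filter targets unimodal
    LRR with heavy-tailed scatter; on multi-state copy-number profiles a
    genome-wide density cut removes entire minority states, so the pipeline
    leaves it off by default.
    """

    enabled: bool = False
    quantile: float = 0.30
    bandwidth: str = "silverman"
    min_bins: int = 10


@dataclass
class SegmentationConfig:
    """Breakpoint acceptance rules for the tree-recursion segmenter.

    A candidate breakpoint is recorded only when both resulting children
    have at least ``min_bins`` bins, span at least ``min_length_bp`` and
    their means differ at Welch-test level ``alpha``.
    """

    min_bins: int = 10
    min_length_bp: float = 1e6
    alpha: float = 0.01


@dataclass
class MergeConfig:
    """KDE-based merging of adjacent segments.

    Adjacent segments are merged while the overlap coefficient of their
    bin-value kernel density estimates is at least ``kde_overlap``.
    """

    kde_overlap: float = 0.5
    bandwidth: str = "silverman"


@dataclass
class PurityConfig:
    """Joint purity / scale-factor search.

    The genotype grid spans n_A <= n_B with total copy number <= ``cn_max``;
    the scale factor is scanned over [``sf_min``, ``sf_max``] with step
    ``sf_step``.  DBSCAN on (BAF rank, CN rank) groups segments into
    genotype clusters.  Fits with purity below ``min_purity`` are flagged
    low-confidence.
    """

    cn_max: int = 8
    sf_min: float = 0.5
    sf_max: float = 2.5
    sf_step: float = 0.01
    purity_min: float = 0.05
    purity_step: float = 0.01
    dbscan_eps: float = 0.05
    dbscan_minpts: int = 3
    min_purity: float = 0.20


@dataclass
class ScarConfig:
    """Event-size thresholds and the HRD score parameters."""

    loh_mb: float = 15.0
    tai_mb: float = 11.0
    lst_flank_mb: float = 10.0
    lst_filter_mb: float = 3.0
    k: float = 15.5
    threshold: float = 30.0
    merge_equal_neighbors: bool = True


@dataclass
class GsaConfig:
    homozygous_baf: HomozygousBafConfig = field(default_factory=HomozygousBafConfig)
    lrr_outlier_filter: LrrOutlierConfig = field(default_factory=LrrOutlierConfig)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    purity: PurityConfig = field(default_factory=PurityConfig)
    scars: ScarConfig = field(default_factory=ScarConfig)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "GsaConfig":
        cfg = cls()
        for section, values in d.items():
            if not hasattr(cfg, section):
                raise KeyError(f"unknown config section: {section!r}")
            sub = getattr(cfg, section)
            for key, val in values.items():
                if not hasattr(sub, key):
                    raise KeyError(f"unknown config key: {section}.{key}")
                setattr(sub, key, val)
        return cfg

    @classmethod
    def from_yaml(cls, path: str) -> "GsaConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)
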