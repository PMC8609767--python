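"""Synthetic BAF/LRR track generator and packaged benchmark score tables.

Tracks are generated directly from the mixing model used by the estimator:
a piecewise-constant ground-truth profile of allele-specific copy numbers
(n_A, n_B) on a diploid-heterozygous (1, 1) background is mixed with a
1 - p fraction of diploid normal cells, giving per-bin expectations

    BAF = (1 - p + p b) / (p CN + 2 (1 - p)),   b in {n_A, n_B} by a fair coin
    LRR = log2((p CN + 2 (1 - p)) / (2 scale_factor)).

Gaussian noise (clipped to [0, 1] for BAF) emulates measurement scatter; a
binomial read-sampling mode is available as an alternative BAF noise model.
The generator works at the track level — it does not emulate read-level
artifacts (GC bias, mappability, FFPE degradation), so recovery results
speak to the estimator's correctness under the stated model, not to assay
chemistry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .tracks_io import BinTrack, GenomeAnnotation, load_grch37


@dataclass(frozen=True)
class SimEvent:
    chrom: str
    start: int
    end: int
    n_a: int
    n_b: int


@dataclass
class SimProfile:
    """Ground-truth allele-specific profile: events on a (1, 1) background."""

    events: list[SimEvent] = field(default_factory=list)
    purity: float = 1.0
    scale_factor: float = 1.0
    background: tuple[int, int] = (1, 1)

    def validate(self, annotation: GenomeAnnotation) -> None:
        by_chrom: dict[str, list[SimEvent]] = {}
        for e in self.events:
            if e.chrom not in annotation.lengths:
                raise ValueError(f"event on unknown chromosome {e.chrom}")
            if not (0 <= e.start < e.end <= annotation.lengths[e.chrom]):
                raise ValueError(f"event outside chromosome bounds: {e}")
            if e.n_a < 0 or e.n_b < 0:
                raise ValueError(f"negative allele copies: {e}")
            by_chrom.setdefault(e.chrom, []).append(e)
        for evs in by_chrom.values():
            evs.sort(key=lambda e: e.start)
            for a, b in zip(evs[:-1], evs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping events: {a} / {b}")

    def genotype_at(self, chrom: str, pos: float) -> tuple[int, int]:
        for e in self.events:
            if e.chrom == chrom and e.start <= pos < e.end:
                return (e.n_a, e.n_b)
        return self.background


@dataclass
class SimConfig:
    """Sampling density and noise levels of the generator.

    ``bins_per_mb`` emulates the probe density of a targeted SNP panel at
    desk scale; ``baf_sd``/``lrr_sd`` are per-bin Gaussian noise standard
    deviations; with ``baf_noise='binomial'`` BAF is instead a binomial
    fraction at ``depth`` reads.
    """

    bins_per_mb: float = 2.0
    baf_sd: float = 0.02
    lrr_sd: float = 0.05
    seed: int = 0
    baf_noise: str = "gaussian"  # or "binomial"
    depth: int = 500


def read_profile(path: str, purity: float = 1.0, scale_factor: float = 1.0) -> SimProfile:
    """Read a profile TSV `chrom start end nA nB`."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    events = [
        SimEvent(str(r["chrom"]), int(r["start"]), int(r["end"]), int(r["nA"]), int(r["nB"]))
        for _, r in df.iterrows()
    ]
    return SimProfile(events=events, purity=purity, scale_factor=scale_factor)


def simulate_track(
    profile: SimProfile,
    config: SimConfig | None = None,
    annotation: Optional[GenomeAnnotation] = None,
    rng: Optional[np.random.Generator] = None,
) -> BinTrack:
    """Generate a noisy BAF/LRR bin track from a ground-truth profile.

    Bins are laid uniformly along each chromosome, skipping the centromere
    gap (panels carry no probes there).  Per bin, the B-allele identity is
    an independent fair coin so the unmirrored BAF shows the bimodal pattern
    of imbalanced regions.  Homozygous deletions at purity 1 yield missing
    BAF and a floor LRR.
    """
    cfg = config or SimConfig()
    ann = annotation or load_grch37()
    profile.validate(ann)
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    p, sf = profile.purity, profile.scale_factor
    width = int(round(1_000_000 / cfg.bins_per_mb))
    rows = []
    for chrom in ann.chromosomes:
        length = ann.lengths[chrom]
        cs, ce = ann.centromeres[chrom]
        starts = np.arange(0, length - width + 1, width)
        for start in starts:
            end = int(start) + width
            mid = start + width / 2
            if cs < end and start < ce:  # overlapping the centromere gap
                continue
            n_a, n_b = profile.genotype_at(chrom, mid)
            cn = n_a + n_b
            mix = p * cn + 2.0 * (1.0 - p)
            b = n_b if rng.random() < 0.5 else n_a
            if mix <= 0:
                baf = np.nan
                lrr_mu = np.log2(1e-4 / (2.0 * sf))
            else:
                baf = (1.0 - p + p * b) / mix
                lrr_mu = np.log2(mix / (2.0 * sf))
            if np.isfinite(baf):
                if cfg.baf_noise == "binomial":
                    baf = rng.binomial(cfg.depth, baf) / cfg.depth
                elif cfg.baf_sd > 0:
                    baf = float(np.clip(baf + rng.normal(0.0, cfg.baf_sd), 0.0, 1.0))
            lrr = lrr_mu + (rng.normal(0.0, cfg.lrr_sd) if cfg.lrr_sd > 0 else 0.0)
            rows.append((chrom, int(start), end, baf, float(lrr)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "baf", "lrr"])
    return BinTrack(bins, ann)


def dilution_series(
    profile: SimProfile,
    purities: Sequence[float],
    config: SimConfig | None = None,
    annotation: Optional[GenomeAnnotation] = None,
) -> list[BinTrack]:
    """One track per purity; track i uses the seed stream ``seed + i``.

    Emulates mixing control reads into a tumor sample at known proportions.
    """
    cfg = config or SimConfig()
    out = []
    for i, p in enumerate(purities):
        if not 0.0 < p <= 1.0:
            raise ValueError(f"purity {p} outside (0, 1]")
        prof = SimProfile(
            events=profile.events,
            purity=p,
            scale_factor=profile.scale_factor,
            background=profile.background,
        )
        rng = np.random.default_rng(cfg.seed + i)
        out.append(simulate_track(prof, cfg, annotation, rng=rng))
    return out


# ---------------------------------------------------------------------------
# Packaged benchmark score tables
# ---------------------------------------------------------------------------

def _load_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("gsascar.data") / name
    with resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t")


def load_platform_comparison() -> pd.DataFrame:
    """Published scores of 40 FFPE tumor samples on a SNP array and the targeted panel.

    Columns: sample plus {array,panel}_{purity,loh,tai,lst,ploidy,hrd_score}.
    """
    return _load_fixture("ffpe_platform_scores.tsv")


def load_cell_line_scores() -> pd.DataFrame:
    """Published scores of 17 ovarian / breast cancer cell lines.

    Columns: cell_line, cancer_type, loh, tai, lst, ploidy, hrd_score,
    brca_mutation, brca1_methylation_pct.
    """
    return _load_fixture("cell_line_scores.tsv")
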