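"""Genotype clustering and joint tumor purity / ploidy estimation.

The mixing model: a tumor fraction p of cells carries the aberrant genotype
(n_A, n_B) while the remaining 1-p are diploid heterozygous, so the measured
total copy number CN* and the measured (mirrored) BAF* of a segment obey

    CN* . scale_factor = CN . p + 2 (1 - p)
    BAF* = (1 - p + p n_B) / (CN* . scale_factor)       with CN = n_A + n_B.

Inverting the second relation for an imbalanced genotype gives the
per-cluster purity estimate

    p = (1 - 2 BAF*) / (BAF* . CN - 2 BAF* + 1 - baf . CN)

with baf = n_B / CN the theoretical BAF.  Segments are first grouped into
genotype clusters by DBSCAN on the percentile ranks of their mean BAF and
measured CN; a grid search over (purity, scale_factor) assigns each cluster
the small-integer genotype that best explains its (BAF*, CN*) pair and the
winning solution minimizes the genome-length-weighted dispersion of the
per-cluster purity estimates.  Whole-genome-doubled alternatives that fit
equally well are broken toward the lower-ploidy solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.cluster import DBSCAN

from .config import PurityConfig
from .tracks_io import AllelicSegment, GenomeAnnotation, Segment

_BAF_SCALE = 0.25  # typical dynamic range of mirrored BAF, for residual weighting
_CN_SCALE = 2.0


class BalancedGenotypeError(ValueError):
    """Purity is undefined for a balanced genotype (theoretical BAF = 0.5)."""


# ---------------------------------------------------------------------------
# Elementary relations
# ---------------------------------------------------------------------------

def theoretical_cn(lrr: float | np.ndarray) -> float | np.ndarray:
    """Measured total copy number implied by an LRR value: CN* = 2^LRR * 2."""
    return 2.0 ** np.asarray(lrr, dtype=float) * 2.0


def expected_baf(p: float, n_a: int, n_b: int) -> float:
    """Measured BAF of a genotype (n_A, n_B) mixed with diploid cells at purity p."""
    cn = n_a + n_b
    denom = p * cn + 2.0 * (1.0 - p)
    if denom == 0.0:
        raise ZeroDivisionError(
            "homozygous deletion at purity 1: no reads, BAF undefined"
        )
    return (1.0 - p + p * n_b) / denom


def expected_lrr(p: float, cn: float, scale_factor: float = 1.0) -> float:
    """LRR of a region with tumor copy number cn at purity p."""
    mix = p * cn + 2.0 * (1.0 - p)
    return float(np.log2(np.maximum(mix, 1e-4) / (2.0 * scale_factor)))


def purity_from_cluster(baf_star: float, cn: float, baf: float) -> float:
    """Invert the mixing model: purity from a cluster's measured mean BAF.

    ``cn`` and ``baf`` are the candidate genotype's total copy number and
    theoretical BAF (n_B / CN).  Undefined for balanced genotypes.
    """
    denom = baf_star * cn - 2.0 * baf_star + 1.0 - baf * cn
    if abs(denom) < 1e-12:
        raise BalancedGenotypeError(
            "balanced genotype: purity not identifiable from BAF"
        )
    return (1.0 - 2.0 * baf_star) / denom


def rank_percentiles(values: Sequence[float]) -> np.ndarray:
    """Fractional percentile ranks (rank - 0.5)/n, ties sharing the mean rank."""
    x = np.asarray(values, dtype=float)
    if len(x) == 0:
        raise ValueError("need at least 1 value")
    return (rankdata(x, method="average") - 0.5) / len(x)


# ---------------------------------------------------------------------------
# Genotype clusters
# ---------------------------------------------------------------------------

@dataclass
class GenotypeCluster:
    """Segments sharing a genotype, with length-weighted summary statistics."""

    members: list[int]
    mean_baf_star: float
    mean_cn_star: float
    baf_rank: float
    cn_rank: float
    weight: float  # total bp length
    label: int = -1
    genotype: Optional[tuple[int, int]] = None
    purity: Optional[float] = None


def cluster_genotypes(
    segments: Sequence[AllelicSegment], params: PurityConfig | None = None
) -> list[GenotypeCluster]:
    """Group segments of the same genotype by DBSCAN in percentile-rank space.

    Each segment is a point (rank of mean BAF, rank of measured CN); DBSCAN
    noise points become singleton clusters so every segment is used.
    """
    cfg = params or PurityConfig()
    segs = [s for s in segments if np.isfinite(s.mean_baf) and np.isfinite(s.cn_star)]
    if len(segs) < 1:
        return []
    baf_ranks = rank_percentiles([s.mean_baf for s in segs])
    cn_ranks = rank_percentiles([s.cn_star for s in segs])
    pts = np.column_stack([baf_ranks, cn_ranks])
    if len(segs) == 1:
        labels = np.array([0])
    else:
        labels = DBSCAN(eps=cfg.dbscan_eps, min_samples=cfg.dbscan_minpts).fit(pts).labels_
    # noise points (-1) become singleton clusters
    next_label = labels.max() + 1 if len(labels) else 0
    labels = labels.copy()
    for i in np.flatnonzero(labels == -1):
        labels[i] = next_label
        next_label += 1
    clusters: list[GenotypeCluster] = []
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        w = np.array([segs[i].length for i in idx], dtype=float)
        w = np.maximum(w, 1.0)
        clusters.append(
            GenotypeCluster(
                members=[int(i) for i in idx],
                mean_baf_star=float(np.average([segs[i].mean_baf for i in idx], weights=w)),
                mean_cn_star=float(np.average([segs[i].cn_star for i in idx], weights=w)),
                baf_rank=float(np.average(baf_ranks[idx], weights=w)),
                cn_rank=float(np.average(cn_ranks[idx], weights=w)),
                weight=float(w.sum()),
                label=int(lab),
            )
        )
    clusters.sort(key=lambda c: c.label)
    return clusters


# ---------------------------------------------------------------------------
# Joint purity / scale-factor fit
# ---------------------------------------------------------------------------

@dataclass
class PurityPloidyFit:
    """Result of the joint search: purity, scale factor and diagnostics."""

    purity: Optional[float]
    scale_factor: Optional[float]
    ploidy: Optional[float] = None
    cluster_purities: list[float] = field(default_factory=list)
    cluster_genotypes: list[tuple[int, int]] = field(default_factory=list)
    residual: float = float("nan")
    dispersion: float = float("nan")
    low_confidence: bool = False


def _genotype_grid(cn_max: int) -> tuple[np.ndarray, np.ndarray]:
    """All (n_A, n_B) with 0 <= n_A <= n_B and n_A + n_B <= cn_max."""
    na, nb = [], []
    for a in range(cn_max + 1):
        for b in range(a, cn_max + 1):
            if a + b <= cn_max:
                na.append(a)
                nb.append(b)
    return np.array(na), np.array(nb)


def _weighted_median(x: np.ndarray, w: np.ndarray) -> float:
    order = np.argsort(x)
    cw = np.cumsum(w[order])
    return float(x[order][np.searchsorted(cw, 0.5 * cw[-1])])


def fit_purity_ploidy(
    clusters: Sequence[GenotypeCluster], params: PurityConfig | None = None
) -> PurityPloidyFit:
    """Grid search over (purity, scale_factor) and per-cluster genotypes.

    For each candidate (p, sf) every cluster is assigned the genotype whose
    predicted (BAF*, CN*) is nearest its measured pair; the solution score is
    the weighted median absolute deviation of the per-cluster purity
    estimates from imbalanced clusters, plus a small model-residual term and
    a tiny mean-copy-number penalty that breaks whole-genome-doubling ties
    toward the lower-ploidy solution.  The reported purity is the
    genome-length-weighted mean of the per-cluster estimates.
    """
    cfg = params or PurityConfig()
    clusters = list(clusters)
    if not clusters:
        return PurityPloidyFit(None, None, low_confidence=True)

    baf_star = np.array([c.mean_baf_star for c in clusters])
    cn_star = np.array([c.mean_cn_star for c in clusters])
    weights = np.array([c.weight for c in clusters], dtype=float)
    weights = weights / weights.sum()

    # a sample with no allelic imbalance anywhere cannot constrain purity
    if np.all(baf_star < 0.5 + 0.02):
        return PurityPloidyFit(None, None, low_confidence=True)

    na, nb = _genotype_grid(cfg.cn_max)
    cn_g = (na + nb).astype(float)
    baf_g = np.where(cn_g > 0, nb / np.maximum(cn_g, 1), 0.5)
    imbalanced = na != nb

    # Mirroring folds BAF noise upward, so a balanced cluster's measured
    # mean sits at 0.5 + sigma*sqrt(2/pi), not at 0.5.  The baseline level
    # of the large clusters estimates sigma; predictions are folded-normal
    # means so that balanced genotypes are not spuriously penalized.
    big = weights >= np.median(weights)
    b0 = float(baf_star[big].min()) if big.any() else float(baf_star.min())
    sigma_baf = max(b0 - 0.5, 0.0) * np.sqrt(np.pi / 2.0)

    def folded(mu: np.ndarray) -> np.ndarray:
        if sigma_baf <= 0:
            return mu
        from scipy.stats import norm

        return mu * (1.0 - 2.0 * norm.cdf(-mu / sigma_baf)) + sigma_baf * np.sqrt(
            2.0 / np.pi
        ) * np.exp(-(mu**2) / (2.0 * sigma_baf**2))

    sf_grid = np.linspace(
        cfg.sf_min, cfg.sf_max, int(round((cfg.sf_max - cfg.sf_min) / cfg.sf_step)) + 1
    )
    p_grid = np.linspace(
        cfg.purity_min, 1.0, int(round((1.0 - cfg.purity_min) / cfg.purity_step)) + 1
    )

    best = None
    for p0 in p_grid:
        mix = p0 * cn_g + 2.0 * (1.0 - p0)  # (G,)
        pred_baf = np.where(mix > 0, (1.0 - p0 + p0 * nb) / np.maximum(mix, 1e-12), np.nan)
        pred_baf = 0.5 + folded(pred_baf - 0.5)
        d_baf = (pred_baf[None, :] - baf_star[:, None]) / _BAF_SCALE  # (C, G)
        # CN residual: pred_cn*(g, sf) = mix / sf
        pred_cn = mix[None, :] / sf_grid[:, None]  # (S, G)
        d_cn = (pred_cn[None, :, :] - cn_star[:, None, None]) / _CN_SCALE  # (C, S, G)
        cost = d_baf[:, None, :] ** 2 + d_cn**2  # (C, S, G)
        cost = np.where(np.isfinite(cost), cost, np.inf)
        g_best = np.argmin(cost, axis=2)  # (C, S)
        c_idx = np.arange(len(clusters))[:, None]
        best_cost = cost[c_idx, np.arange(len(sf_grid))[None, :], g_best]  # (C, S)
        resid = (weights[:, None] * best_cost).sum(axis=0)  # (S,)

        for si in range(len(sf_grid)):
            gsel = g_best[:, si]
            imb = imbalanced[gsel]
            if not imb.any():
                continue
            p_hat = np.empty(len(clusters))
            p_hat.fill(np.nan)
            for ci in np.flatnonzero(imb):
                g = gsel[ci]
                denom = baf_star[ci] * cn_g[g] - 2.0 * baf_star[ci] + 1.0 - baf_g[g] * cn_g[g]
                if abs(denom) < 1e-12:
                    continue
                p_hat[ci] = (1.0 - 2.0 * baf_star[ci]) / denom
            # estimates just above 1 are noise around a pure sample; clip
            valid = np.isfinite(p_hat) & (p_hat > 0.0) & (p_hat <= 1.1)
            if not valid.any():
                continue
            p_hat = np.minimum(p_hat, 1.0)
            # an imbalanced assignment whose implied purity is impossible
            # marks an inconsistent explanation of that cluster
            invalid = imb & ~valid
            invalid_weight = float(weights[invalid].sum())
            # clusters whose BAF clearly exceeds the balanced baseline but
            # were assigned a balanced genotype are imbalance explained away
            margin = max(0.01, 0.5 * sigma_baf)
            unexplained = float(weights[(baf_star > b0 + margin) & ~imb].sum())
            pv, wv = p_hat[valid], weights[valid]
            wv = wv / wv.sum()
            med = _weighted_median(pv, wv)
            dispersion = float(np.sum(wv * np.abs(pv - med)))
            p_mean = float(np.sum(wv * pv))
            mean_cn = float(np.sum(weights * cn_g[gsel]))
            score = (
                dispersion
                + 1.0 * resid[si]
                + 0.05 * abs(p_mean - p0)
                + 0.5 * invalid_weight
                + 0.5 * unexplained
                # near-diploid preference: breaks genome-doubling (and
                # genome-deletion) ties toward the solution closest to CN 2
                + 0.05 * abs(mean_cn - 2.0)
            )
            if best is None or score < best[0]:
                best = (
                    score,
                    float(sf_grid[si]),
                    p_mean,
                    dispersion,
                    float(resid[si]),
                    [(int(na[g]), int(nb[g])) for g in gsel],
                    [float(x) if np.isfinite(x) else float("nan") for x in p_hat],
                )

    if best is None:
        return PurityPloidyFit(None, None, low_confidence=True)
    score, sf, p_mean, dispersion, resid, genos, p_hat = best
    p_final = min(max(p_mean, 0.0), 1.0)
    for c, g, ph in zip(clusters, genos, p_hat):
        c.genotype = g
        c.purity = ph if np.isfinite(ph) else None
    return PurityPloidyFit(
        purity=p_final,
        scale_factor=sf,
        cluster_purities=p_hat,
        cluster_genotypes=genos,
        residual=resid,
        dispersion=dispersion,
        low_confidence=p_final < cfg.min_purity,
    )


# ---------------------------------------------------------------------------
# Integer copy number assignment and ploidy
# ---------------------------------------------------------------------------

def assign_integer_cn(
    segments: Sequence[AllelicSegment], fit: PurityPloidyFit, cn_max: int = 8
) -> list[AllelicSegment]:
    """Invert the mixing model per segment to integer (n_A, n_B).

    CN = (CN* . sf - 2(1-p)) / p rounded to the nearest non-negative integer;
    n_B = ((BAF* . CN* . sf) - (1-p)) / p rounded and clipped to [0, CN];
    n_A = CN - n_B, then mirrored so n_B >= n_A.  Segments whose pre-rounding
    CN falls below -0.5 are flagged inconsistent.
    """
    if fit.purity is None or fit.scale_factor is None:
        raise ValueError("fit does not contain a valid purity/scale factor")
    p, sf = fit.purity, fit.scale_factor
    out = []
    for s in segments:
        if not np.isfinite(s.cn_star):
            out.append(
                AllelicSegment(
                    chrom=s.chrom, start=s.start, end=s.end, n_bins=s.n_bins,
                    mean_baf=s.mean_baf, mean_lrr=s.mean_lrr, cn_star=s.cn_star,
                    inconsistent=True,
                )
            )
            continue
        cn_raw = (s.cn_star * sf - 2.0 * (1.0 - p)) / p
        inconsistent = cn_raw < -0.5
        cn = int(min(max(round(cn_raw), 0), cn_max))
        if np.isfinite(s.mean_baf):
            nb_raw = (s.mean_baf * s.cn_star * sf - (1.0 - p)) / p
            nb = int(min(max(round(nb_raw), 0), cn))
        else:
            # a covered segment stripped of all informative SNP bins by the
            # homozygosity filter has lost one haplotype: call it homozygous
            nb = cn
        n_a, n_b = cn - nb, nb
        if n_b < n_a:
            n_a, n_b = n_b, n_a
        out.append(
            AllelicSegment(
                chrom=s.chrom,
                start=s.start,
                end=s.end,
                n_bins=s.n_bins,
                mean_baf=s.mean_baf,
                mean_lrr=s.mean_lrr,
                cn_star=s.cn_star,
                n_a=n_a,
                n_b=n_b,
                cn=cn,
                inconsistent=bool(inconsistent),
            )
        )
    return out


def compute_ploidy(
    segments: Sequence[AllelicSegment], annotation: GenomeAnnotation
) -> float:
    """Genome-proportion-weighted mean copy number, uncovered genome diploid.

    ploidy = sum_i Segs_i . CN_i + (1 - sum_i Segs_i) . 2, with Segs_i the
    fraction of the annotated genome covered by segment i.
    """
    total = float(annotation.total_length)
    covered = 0.0
    weighted = 0.0
    for s in segments:
        if s.cn < 0:
            continue
        frac = s.length / total
        covered += frac
        weighted += frac * s.cn
    return weighted + (1.0 - covered) * 2.0


def allelic_from_segments(segments: Sequence[Segment]) -> list[AllelicSegment]:
    """Attach measured CN* = 2^LRR * 2 to plain segments."""
    out = []
    for s in segments:
        out.append(
            AllelicSegment(
                chrom=s.chrom,
                start=s.start,
                end=s.end,
                n_bins=s.n_bins,
                mean_baf=s.mean_baf,
                mean_lrr=s.mean_lrr,
                cn_star=float(theoretical_cn(s.mean_lrr)) if np.isfinite(s.mean_lrr) else float("nan"),
            )
        )
    return out
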