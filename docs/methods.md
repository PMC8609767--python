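# Methods

This note records the model assumptions, the tunable parameters, the design
choices made where the problem statement was genuinely open, and what the
synthetic-data validation does and does not establish.

## Data model and assumptions

Input is a per-bin track of B-allele frequency (BAF) and log R ratio (LRR)
over a genome annotation (chromosome lengths and centromere intervals;
GRCh37 for chromosomes 1–22 and X is packaged). Coordinates are 0-based
half-open throughout. The tumor is assumed to contain a single primary
clone with integer allele-specific copy numbers (n_A, n_B) per segment,
mixed with a fraction 1 − p of normal cells that are diploid heterozygous
everywhere. Subclonal copy number is out of scope. Measured values obey

    CN* · sf = CN · p + 2 (1 − p),   CN* = 2^LRR · 2
    BAF* = (1 − p + p n_B) / (CN* · sf)

with `sf` a multiplicative scale factor absorbing the depth normalization.
The printed form of the purity inversion contains the product of the
*theoretical* BAF (n_B/CN) and CN in its last term; this is the only reading
under which the forward and inverse relations are mutual inverses, and it is
enforced by a property test at 1e−10.

## Preprocessing

* Homozygous-SNP filter: bins with BAF ≥ 0.95 or ≤ 0.05 (inclusive) leave
  the BAF track; the LRR track is untouched. Surviving BAF is mirrored:
  BAF ← |BAF − 0.5| + 0.5.
* LRR density-outlier filter: a Gaussian KDE (Silverman bandwidth) is fit to
  all LRR values; bins whose density score falls strictly below the 30th
  percentile of scores are dropped (ties kept, so the track never empties;
  skipped below 10 bins). **Default: off in the pipeline.** A genome-wide
  density cut necessarily removes entire minority copy-number states — any
  state holding less than roughly the cut fraction of bins sits in a
  low-density region of the LRR mixture — which destroys the CN estimate of
  exactly the segments the method is about. The filter is appropriate for
  unimodal LRR with heavy-tailed scatter and can be enabled via
  `lrr_outlier_filter.enabled`.

## Tree-recursion segmentation

Per chromosome arm and per track, the cumulative run length
S_k = Σ_{i≤k}(x_i − x̄) is computed; its argmax and argmin are candidate
breakpoints (the boundary behind bin k). The candidate with the larger
between-child mean difference is tried first; a split is recorded only when
both children have ≥ `min_bins` (default 10) bins, span ≥ `min_length_bp`
(default 1 Mb) and differ by a two-sided Welch test at α = 0.01 (children
with numerically zero variance are compared exactly). Recursion proceeds
depth-first into both children. These acceptance rules are this package's
concrete choice of the "appropriate trade-offs" the procedure requires; all
three are configurable.

Adjacent segments are then merged while the overlap coefficient of their
bin-value KDEs (Gaussian, Silverman bandwidth; degenerate segments treated
as point masses) is ≥ 0.5. The BAF and LRR breakpoint sets are unioned;
intervals that end up with < 10 bins or < 1 Mb are iteratively removed —
their *span* is absorbed by the neighbor with the closer mean BAF (LRR as
fallback) but their data points are discarded, so the absorbing segment's
statistics remain those of its own bins. Keeping the sliver's bins instead
was tried and measurably contaminates segment means, which propagates into
biased purity estimates. Finally, the last p-arm and first q-arm segments
are re-tested with the same KDE-overlap criterion and joined across the
centromere gap when they match.

A consequence of the minimum-size rules: a true boundary closer than
`min_bins` bins to an arm end cannot be recovered, and the flanking bins
fold into the adjacent segment. Resolution is therefore one segment per
`min_bins` bins / `min_length_bp`, whichever is coarser.

Segments whose surviving BAF bins number < 5 or < 5% of their bins are
marked BAF-uninformative (mean BAF = NaN): after the homozygosity filter a
censored handful of SNPs is a truncation artifact, not a measurement. At
integer-assignment time such segments are called fully homozygous
(n_B = CN) — over a covered segment, the only way essentially all SNPs read
homozygous is loss of one haplotype. For input tracks with genuine SNP
deserts (not produced by this package's own preprocessing) this reading
would overcall LOH; targeted HRD panels are designed not to have such
deserts.

## Genotype clustering

Segments are points (percentile rank of mean mirrored BAF, percentile rank
of CN*), ranks computed as (rank − 0.5)/n with ties averaged. DBSCAN
(eps = 0.05, minPts = 3, both configurable) groups them; noise points become
singleton clusters so every segment contributes. Rank-space density
clustering groups segments only when their statistics are (near-)tied:
under continuous measurement noise the ranks of same-genotype segments
spread apart and most clusters are singletons. That is acceptable here —
clustering is a variance-reduction step, and the purity search below is
written to work cluster-by-cluster, singletons included.

## Purity and scale-factor search

Grid search over purity p ∈ [0.05, 1.0] step 0.01 and sf ∈ [0.5, 2.5] step
0.01. For each (p, sf), every cluster is assigned the genotype
(n_A ≤ n_B, CN ≤ 8) minimizing a scaled squared residual in (BAF*, CN*),
with BAF residuals scaled by 0.25 and CN residuals by 2.0 (their respective
dynamic ranges). Predicted BAF uses the *folded-normal mean*: mirroring
folds zero-mean noise upward, so a balanced genotype's measured mean sits at
0.5 + σ√(2/π); σ is estimated from the lowest mean BAF among
at-least-median-weight clusters. Without this correction the truly balanced
genome fraction appears slightly imbalanced and the search drifts toward
spurious half-purity solutions.

Each imbalanced assignment yields a purity estimate via the inversion
formula. The solution score is

    weighted MAD of estimates (genome-length weights)
    + 1.0 · weighted model residual
    + 0.05 · |weighted-mean estimate − p|
    + 0.5 · weight of imbalanced assignments with impossible purity (≤ 0 or > 1.1)
    + 0.5 · weight of visibly imbalanced clusters assigned balanced genotypes
    + 0.05 · |genome-mean CN − 2|

Estimates in (1.0, 1.1] are clipped to 1 (noise around a pure sample). The
"visibly imbalanced" margin is max(0.01, σ/2) above the balanced baseline;
without that term the search can reach dispersion zero by explaining away
all but one imbalanced cluster. The final near-diploid preference breaks the
exact whole-genome-doubling degeneracy — (1,2) at purity 1 and (1,3) at
purity 0.5 produce identical (BAF*, CN*) — toward the lower-ploidy solution,
the standard convention. Reported purity is the genome-length-weighted mean
of the per-cluster estimates; fits below 0.20 carry `low_confidence: true`,
the method's validated operating floor. A sample with no visible allelic
imbalance has no purity information at all and is reported with purity
undefined.

Integer copy numbers per segment invert the mixing relations directly:
CN = round((CN*·sf − 2(1−p))/p) clipped to [0, 8], n_B from the analogous
BAF inversion clipped to [0, CN], mirrored so n_B ≥ n_A; pre-rounding
CN < −0.5 flags the segment inconsistent. Ploidy is Σ Segs_i·CN_i +
(1 − Σ Segs_i)·2 with Segs_i the fraction of the annotated genome covered —
uncovered genome counts as diploid, and the printed formula's extra
denominator is read as 1 (the weights are already proportions; any other
reading fails the whole-genome-diploid = 2.0 identity).

## Scar scores

* **LOH**: maximal runs of adjacent segments with minor allele 0 and CN ≥ 1
  form regions; regions > 15 Mb count, except a region spanning the
  chromosome's entire covered extent (whole-chromosome loss is excluded by
  definition — that is how "exceeding LOH regions which do not cover the
  whole chromosome" is operationalized, matching the standard HRD-LOH rule).
  Homozygous deletions (CN 0) do not qualify.
* **TAI**: segments with n_A ≠ n_B, entirely within one arm, longer than
  11 Mb, whose outer boundary reaches the outermost covered position of the
  arm. "Subtelomere contact" means the arm's outermost covered bin —
  targeted panels never reach the literal telomere.
* **LST**: per arm (segments spanning the centromere are clipped into both
  arms), segments < 3 Mb are removed, adjacent equal-genotype segments
  merged (configurable), and each breakpoint with both flanks ≥ 10 Mb adds
  one.
* **HRD score** = LOH + TAI + LST − K·ploidy with K = 15.5, positive at
  ≥ 30 (the boundary is taken inclusive). K and the threshold are cohort
  calibrations taken as parameters; re-deriving them requires clinical data
  outside this package's scope.

All length thresholds follow the printed wording (strict > for LOH/TAI
lengths, ≥ for LST flanks, < for the LST filter) and sit in the config.

## Gene-level LOH caller

A SNP is informative when the control variant fraction lies in
[0.35, 0.65] (inclusive); at such a site a tumor fraction strictly outside
(0.35, 0.65) marks LOH, inside marks non-LOH; the gene verdict is LOH iff
LOH sites strictly outnumber non-LOH sites (a tie is no-LOH), and
"insufficient" with zero informative sites. The "meets both conditions" rule
is read as the conjunction of the control-heterozygosity and
tumor-homozygosity conditions.

## Synthetic data

The generator lays uniform bins along each chromosome (default 2 per Mb, a
desk-scale stand-in for panel probe density), skips the centromere gap,
looks up the ground-truth genotype per bin and emits the mixing-model BAF
(allele phase an independent fair coin, so imbalanced regions are bimodal)
and LRR, plus Gaussian noise (defaults: BAF sd 0.02, LRR sd 0.05; BAF noise
clipped to [0, 1]; a binomial read-sampling mode at configurable depth is
available). Identical seeds give byte-identical tracks; a dilution series
derives track i's stream from seed + i.

What the simulator emulates: piecewise-constant allele-specific profiles,
normal-cell dilution, phase ambiguity, centromere coverage gaps, and (at
high purity) the censoring of near-homozygous regions by the BAF filter.
What it does not: GC/mappability waves, FFPE artifacts, germline-homozygous
SNPs (all simulated bins are informative), read-level sampling of LRR,
subclonality, and real dilutions' read-level mixing. Passing recovery tests
therefore demonstrates correctness of the estimator under its own model, not
robustness to assay chemistry.

Validation highlights (all computed by the test suite): exact inversion of
noise-free tracks for purity ≥ 0.2 (genotypes, purity, scale factor);
purity recovery R² ≥ 0.98 across a noisy 0.2–1.0 dilution with ploidy
variation < 0.1; BAF density modes of a pure ABB region at 0.33/0.67;
scar counters equivalent to an independent brute-force evaluator on 1000
randomized segment lists; segmentation breakpoints equal to exhaustive
SSE-minimizing splits on noiseless staircase signals.

Two packaged reference tables (40 FFPE samples scored on a SNP array and the
targeted panel; 17 breast/ovarian cell lines) are transcriptions of
published per-sample scores, checksum-pinned, used to verify the score
arithmetic, cross-platform correlations and cohort statistics.

## Known limitations

* Whole-genome-doubled tumors whose every genotype is the double of a
  diploid one are mathematically indistinguishable from the undoubled
  sample at a different purity; the near-diploid tie-break then reports the
  lower-ploidy interpretation.
* Purity is undefined without allelic imbalance, and unreliable below 0.20.
* At purity ≳ 0.9, copy-neutral LOH regions lose (nearly) all BAF bins to
  the homozygosity filter; they are recovered via the BAF-desert rule, but
  their mean BAF, where it survives, is truncation-biased.
* Breakpoints within `min_bins` of an arm end are unrecoverable by design.
* LST/TAI/LOH operate on the final integer calls; no subclonal fractions.
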