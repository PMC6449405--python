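# Methods

This note documents the models, conventions, and numerical choices behind
`hicdyn`, and what the synthetic-data generator does and does not emulate.

## Contact-matrix model and normalization

A contact map is a symmetric matrix of counts over uniform genomic bins
(0-based half-open intervals; dense bin ids). On disk it is an
upper-triangle triplet text file plus a companion bin BED — symmetry is
implicit in the storage. Bins carry a validity mask; a masked bin is excluded
from every downstream statistic.

**ICE balancing.** Before iterating, bins with a zero marginal plus the
lowest `mask_quantile` (default 2%) of marginals are masked — a low-coverage
filter in the spirit of standard Hi-C pipelines, whose exact cutoff those
pipelines rarely document; it is exposed as a parameter. Iterative
correction then rescales rows and columns by their marginal relative to the
mean marginal until the maximum relative deviation is below `tol` (default
1e-5, max 200 iterations; non-convergence warns and flags the result rather
than raising). The returned weights are multiplicative:
`balanced(i,j) = w_i · w_j · raw(i,j)`, and the balanced matrix is rebuilt
from the weights so this identity holds exactly.

**Expected and O/E.** The expected value of a cis pair is the mean balanced
value at its bin distance on its chromosome, with the diagonal (distance 0)
excluded; the expected value of any trans pair is the global trans mean.
O/E divides by these. By construction the mean O/E at every cis distance is
1. Pairs whose expected value is zero are set to zero and take no part in
downstream statistics.

## Compartment calling

Per chromosome, the PC1 score is the leading eigenvector of the Pearson
correlation matrix of the O/E contact profiles, scaled by the square root of
its eigenvalue. Two conventions matter:

* **The diagonal is excluded pairwise.** O/E structural zeros on the
  diagonal sit at a different column position in every row and badly distort
  row correlations; the correlation is therefore computed with
  pairwise-complete observations after NaN-ing the diagonal. On a zero-noise
  two-block genome this recovers an exactly two-block correlation matrix,
  which plain row correlations do not.
* **Sign orientation.** The eigenvector sign is arbitrary per chromosome; it
  is flipped so the correlation with an activity proxy (gene density from
  the annotation, by default) is positive, making A scores positive. The
  orientation rule is a package choice — eigendecompositions have no
  intrinsic A/B direction.

Chromosomes with fewer than 10 unmasked bins are skipped with a warning;
zero-variance bins are dropped before the correlation.

## Switch classification

For each bin, a one-way ANOVA F-test across time points on the replicate PC1
scores. A bin is *switching* when p < alpha (default 0.05) **and** at least
one time-point mean is positive and one negative. The category is the
sequence of time-point mean signs with consecutive duplicates collapsed;
four-segment sequences (A–B–A–B, B–A–B–A) are merged into the two-segment
category of their first and last sign. Numerical edge cases: bins whose
values are identical across all samples get p = 1 (avoiding 0/0 in F); exact
zero means inherit the previous sign (ties break toward "no transition"); a
sign change that fails the ANOVA is classified stable by the grand-mean
sign. Bins missing any replicate score are excluded and counted.

## Saddle plots and decay curves

Bins are assigned to deciles of the sample's own PC1 track (edges computed
per sample, not shared across samples — the alternative of joint edges is a
defensible reading, but per-sample edges keep each saddle self-contained).
Cell (q1, q2) is the log₂ mean O/E over unmasked pairs in that decile pair;
empty cells are NaN, never zero. The delta saddle between two samples is the
difference of the log₂ grids — the published phrasing for this quantity is
ambiguous between log₂-of-difference and difference-of-log₂; the latter is
implemented because it is well-defined for all positive grids and symmetric
under sample exchange.

Decay curves stratify cis pairs by the compartment labels of both bins
(A–A, B–B, A–B, from the sign of the track) and divide each class's mean
contact at a distance by the all-pairs mean at that distance; the
count-weighted mean of the three classes is exactly 1 at every distance.
Distances with fewer than 20 pairs are dropped.

## TAD boundaries

**Directionality index.** For each 40 kb bin, A and B are the summed
balanced contacts to bins within a window (default 2 Mb) upstream and
downstream; DI = sign(B−A)·((A−E)²/E+(B−E)²/E), E=(A+B)/2. Domains are
segmented by deterministic run-length thresholds: a domain opens at the
start of a downstream-biased stretch (DI ≥ the 0.9 DI quantile by default)
and closes at the end of the next upstream-biased stretch (≤ the 0.1
quantile). The original HMM-based segmentation is intentionally not
reimplemented — thresholded runs are reproducible, testable, and recover
planted block junctions within one bin on synthetic matrices.

**Insulation.** A square of side 500 kb (the window is a package default;
published analyses rarely state theirs) slides along the diagonal; the score
is log₂(square mean / chromosome mean of that statistic), defined only where
the full square fits. Masked rows/columns are excluded from the square mean
(the center bin itself is never inside the square, so a masked center bin
still gets a score). Boundaries are local minima whose rise to the nearest
flanking maxima is at least `min_strength` (default 0.1) on both sides —
raising the threshold can only remove boundaries.

**Comparison.** Boundary sets are matched greedily nearest-first, each
boundary used at most once, within ±80 kb (replicates) or ±200 kb (time
points); Jaccard = shared / (|A|+|B|−shared). Greedy one-to-one matching is
a package choice; the alternative (count every within-tolerance pair) can
count one boundary twice.

TADs take the compartment-dynamics category covering the majority of their
span; boundary-class enrichment compares a class's category distribution
against the union boundary set with a chi-squared test on counts.

## Trans statistics

Per-locus profiles take all inter-chromosomal balanced counts of an anchor
bin, drop the top 0.5% of values (computed on the anchor's own trans vector;
ties broken by stable sort, retaining ⌊0.995·n⌋ bins), and Z-score the rest
(population SD). The gene-set score sums balanced counts over all unordered
gene pairs on different chromosomes, mapping each gene to the bin of its
promoter (TSS); genes sharing a bin each count in their own pairs. The null
redraws, per chromosome, the same number of genes from the universe without
replacement, excluding the seed genes; the empirical p uses the add-one
correction (1+#{null ≥ obs})/(n+1) and is never zero. Whether the universe
is all genes or a filtered set (e.g. constitutive-A genes) is the caller's
choice via the `universe` argument.

Ties in the null (different drawn sets hitting identical bin multisets) make
the empirical p conservative; this becomes visible only when the universe is
tiny relative to the genome (a few dozen genes on a handful of bins). At
realistic gene densities the p-value is uniform under the no-hub generator
(checked by KS test over 200 simulated datasets).

Network edges are flagged for display when their late-time-point count
strictly exceeds the genome-wide median trans count of the late map; the
fold-change annotation is log₂ of the median-normalized count ratio, with a
pseudocount (flagged) when the early count is zero.

## FISH statistics

Diploid cells have exactly two spots in each locus channel (focus-channel
counts are unconstrained). The minimum of the four green–orange center
distances is normalized by the cube-root volume rule
X_norm = X_raw · ref^{1/3} · V^{−1/3}, with the reference volume the mean
nuclear volume of a chosen reference condition. Proximity is a normalized
minimum distance strictly below 2 µm (twice the 1 µm spot diameter of the
imaging convention); locus–focus overlap
is a *raw* center distance strictly below 1 µm, because that threshold
encodes the physical spot size — applying volume normalization there is
optional and off by default. Periphery distances are taken from the input
table (image distance-transform exports) and, by default, normalized by the
same cube-root rule; a flag disables this. Group comparisons are rank-based:
Wilcoxon rank-sum for two groups, Kruskal–Wallis plus Dunn's pairwise
post-hoc (implemented directly from the rank-based z statistic with tie
correction, Holm-adjusted) for more.

## Synthetic-data generator

The generator emulates the *structure* of a differentiation Hi-C study on a
toy genome — by default 4 chromosomes × 50 bins at 500 kb, 4 time points ×
2 replicates:

* **Compartments**: alternating A/B blocks with geometric block lengths
  (mean 5 bins, random starting label per chromosome). Irregular block sizes
  matter: with perfectly periodic blocks, label identity becomes a
  deterministic function of distance and O/E normalization erases the
  checkerboard entirely.
* **Cis expectation**: depth · d^(−α) (α = 1), times a homotypic boost
  (default 1.8) when both bins share the current label, times a
  stage-ramped long-range B–B gain (default +0.2 per stage beyond 10 Mb,
  emulating heterochromatin compaction).
* **Trans expectation**: flat depth, boosted 1.5× for A–A pairs, with an
  optional hub gain ramping linearly over the time course between the bins
  of a designated hub gene set.
* **Switching**: a configurable fraction of bins (default 19%) change label
  at random change points, with categories drawn from a configurable mix
  (default 0.33/0.49/0.08/0.10 over A–B/B–A/A–B–A/B–A–B).
* **Counts**: negative-binomial around the expectation
  (var = µ + φµ², φ = 0.05 — overdispersed like real Hi-C, cheap to
  sample); φ = 0 returns the rounded expectation itself. Default depths
  (cis 100 at one-bin distance, trans 5) give adjacent-bin counts in the
  hundreds and far-cis counts of a few, comparable to a moderately deep
  experiment after binning.
* **Annotation and tracks**: ~2 genes per bin (genome-like density at
  500 kb), placed 2:1 in constitutively-A bins — this density gradient is
  what orients PC1; genes peak at one stage with FPKM baseline 1 + peak 30
  and 10% log-normal noise; genes in planted B→A bins peak late with odds
  4; stage-specific peak sets land in switching bins with configurable odds.
* **TAD matrices**: separate single-chromosome 40 kb maps with block-boosted
  contacts (8 blocks × 1 Mb, 3× within-block boost).
* **FISH**: ellipsoidal nuclei (axis ratios 1.2:1:0.8, log-normal volumes,
  CV 15% around 600 µm³), two spots per channel placed uniformly; a
  Bernoulli(p_true) fraction of cells gets one pair planted below the
  normalized 2 µm threshold, all other pairs are rejection-sampled to stay
  above it, so p_true is the exact planted proximity probability; aneuploid
  cells carry a third spot; periphery distances are the radial distance to
  the ellipsoid surface along the spot's own direction.

What the generator does **not** emulate: read-level noise and mappability,
restriction/ligation artifacts, translocations, copy-number variation,
distance-dependent trans structure (chromosome territories), gene-length
effects, FISH segmentation error, or z-axis anisotropy. Passing
recovery tests therefore demonstrates the correctness of the statistical
machinery on data satisfying the model's assumptions, not robustness to
every artifact of real experiments.

All randomness derives from the config seed; a fixed seed reproduces every
output byte-identically.

## Problem sizes and runtime

Tests and the acceptance script run at desk scale: switch recovery on 2000
bins (4 × 500), type-I control over 50 null datasets of 200 bins, null
calibration of the permutation test over 200 datasets of 120 bins with 199
permutations each, TAD recovery on five 100-bin 40 kb matrices, and FISH on
500 nuclei. These sizes put each check in the seconds-to-a-minute range
while leaving the recovered quantities well inside their tolerances.

## Known limitations

* The DI domain caller uses quantile thresholds, not the original HMM; on
  very noisy matrices the two can segment differently even when boundary
  positions agree.
* The X-chromosome exclusion applied in sex-mixed human data is a
  data-specific choice and is simply not part of the toy genome; callers
  analysing real data should subset their bin table accordingly.
* The empirical permutation p is conservative under heavy score ties (tiny
  universes); see the trans section.
* Decile edges are per-sample; cross-sample saddle deltas therefore compare
  each sample against its own quantile grid.
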