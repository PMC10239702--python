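# Methods

This note records the models and procedures `cohescan` implements, the
assumptions behind them, the parameter choices that matter, and what the
synthetic cohorts do and do not emulate.

## CAS identification

Consensus sites are maximal runs of per-sample peaks overlapping by ≥ 1 bp
(half-open coordinates throughout), retained when contributed by at least
`min_occupancy = 2` samples; chromosomes Y and M are excluded by default.
The occupancy test is two-sided Fisher on the 2×2 table of
(with peak, without peak) × (cancer, normal); the intensity test is
Welch's unequal-variance t on per-sample log2 intensities (logFC is the
difference of group means of logs).  Both are BH-adjusted over all
consensus sites within one tissue comparison, never per chromosome.  The
CAS filter is `|POC| > 0.5 ∧ q_occ < 0.01 ∧ |logFC| > 1 ∧ q_int < 0.01`
with sign concordance; discordant sites (occupancy up, intensity down, or
vice versa) are excluded rather than assigned arbitrarily — the
conservative reading of a dual-evidence design.  Zero-variance intensity
rows with equal means are defined as p = 1, not an error.

Raw count matrices can be library-size normalised to a fixed constant and
log2(x+1)-transformed by `normalize_intensity`; matrices supplied already
on a log scale pass through untouched.

Sensitivity at the default synthetic conditions is governed by the exact
occupancy test: with 20 + 20 samples, surviving BH at q < 0.01 over 10,000
sites requires Fisher p ≲ 3·10⁻⁴, which draws with observed |POC| around
0.55–0.65 cannot produce; measured sensitivity is therefore ≈ 0.79 while
the false-discovery rate is essentially zero and direction accuracy is
exact.  Larger cohorts relax this limit quickly; the filter thresholds
themselves are treated as fixed conventions, not tuning knobs.

## DEG enrichment

*Nearby model.*  Each gene counts once, at its nearest selected site
(midpoint-to-TSS distance, zero when the TSS lies inside the site).  The
profile f(x) is the per-bin DEG fraction over 10 kb bins to 200 kb; S is
its discrete integral (empty bins contribute zero; the constant bin width
cancels in DRS).  A cumulative variant of f(x) is available but the
per-bin form is the default, matching a ratio-vs-distance reading of the
curve.  The background resamples |CAS| sites from all cohesin sites
without replacement, 500 times by default; DRS uses the mean background S,
and the full draw vector is kept so an empirical 97.5% envelope can be
reported.  Chromosome-matched resampling is available as a flagged option
but off by default.

*Loop model.*  Sites connect to genes through loops whose midpoint span
lies in 200 kb–5 Mb, with a 5 kb anchor pad (anchor tolerance is a
convention of this implementation).  R is the DEG fraction among the
union of connected genes.  The observed R is compared to size-matched
random draws by the exact rank of one observation among the draws —
the form Wilcoxon's rank-sum takes at n₁ = 1 — because the usual normal
approximation is degenerate there and a one-sample signed-rank against
the draw vector is badly anti-conservative.  p-values live on the grid
2k/(n_draws+1); 500 draws are needed before p < 0.01 is reachable, which
is why power runs use the full draw count.

*CAS-DEG partition.*  DEGs within 5 kb of a CAS (nearest-site distance)
versus the rest, compared on |log2FC| by two-sided Mann–Whitney; empty
partitions yield a flagged undefined result.

## 3D genome

PC1 tracks arrive sign-oriented (positive = compartment A); orientation is
upstream of this package.  E per condition is the nan-mean over replicate
tracks at the site's midpoint bin; the switch rule is
`E_c × E_n < 0 ∧ |E_c − E_n| > 0.05`, classes are exhaustive and
undefined where either E is missing.  The insulation score is
`log2(diamond_i / mean(diamonds))` with a 10-bin (500 kb at 50 kb
resolution) diamond {i−w..i−1}×{i+1..i+w}; edge bins are missing, and an
all-zero matrix is an error.  Because the diamond excludes its own bin,
a sharp two-TAD junction produces a one-bin tie: boundary positions are
meaningful to ±1 bin.  Boundaries are local minima below
mean − 1·sd, greedily thinned to the deepest within 3 bins.  ISC is the
per-bin difference of condition insulation tracks at the site's bin (bin
value, not a window mean); the boundary stratum is ±1 bin around a called
boundary.

APA aggregates (2·flank+1)² submatrices (flank 10 bins) centered on loop
pixels, skipping pixels nearer than the flank to an edge or the diagonal;
the score is the center over the mean of the 3×3 lower-left corner, and
condition comparisons divide per-sample scores by the normal-condition
mean (normal ≡ 1) with a one-sided Welch test.  On backgrounds with steep
distance decay the raw center/corner score understates the planted pixel
fold (the corner sits nearer the diagonal and is brighter); the
condition-ratio statistic is unaffected because the background cancels.
`vc_sqrt_normalize` provides square-root vanilla-coverage balancing for
single-region raw matrices.

## Regulatory and orthogonal evidence

TF enrichment is one-sided Fisher (enrichment direction) of CAS overlap
against non-CAS cohesin sites, per TF, with the overlap proportion
reported alongside −log10 p.  A site's chromatin state is its
majority-bp label over the 200 bp segmentation; the active set defaults
to states {1, 2, 6, 7} (active promoter/flanking/enhancer in a
15-state model) and is configurable.  Depletion response counts genes
with negative log2FC *and* a significance flag; group ratios are compared
pairwise by Fisher.  Methylation differential is a two-sided Mann–Whitney
per locus on beta values with the p < 10⁻⁷ significance convention,
direction-split into hyper/hypo by median difference; the CAS overlap
ratio is compared against 500 size-matched random cohesin-site draws
(mirroring the DRS background convention).  Conserved sites are those
present in ≥ 90% of cancer **and** normal datasets.  Mutation analysis
reports per-class per-bp rates with two-proportion z-tests and
site-anchored density profiles.

## Clinical statistics

Clustering operates on the per-gene standardized submatrix of the chosen
gene list: hierarchical with correlation distance (1 − Pearson between
sample profiles) and average linkage, or k-means with 50 restarts and a
fixed seed; k defaults to the number of true label classes.  The adjusted
Rand index is computed from the contingency table exactly as
(Σ C(n_ij,2) − E) / (½[Σ C(a_i,2) + Σ C(b_j,2)] − E) with
E = Σ C(a_i,2)·Σ C(b_j,2)/C(n,2); the degenerate all-one-cluster case
returns 0.  Gene-set sample scores are mean per-gene z-scores — a
deterministic, linear stand-in for sample-level set scoring whose
contract (two patient groups from a median split, ties to the low group)
is what the survival stage consumes; the scorer is pluggable.  Survival
uses Kaplan–Meier product-limit curves and the two-group log-rank test;
zero events flag the result undefined.  Over-representation is one-sided
hypergeometric with BH across sets.

## The synthetic cohorts

The generator emulates the statistical structure of a multi-tissue
cohort study, fully determined by one root seed with named substreams per
modality (so adding one modality never perturbs another).

Default study conditions: 3 tissues, 10,000 non-overlapping 400 bp sites
on a 240 Mb three-chromosome genome, 20 cancer + 20 normal samples per
tissue, 2% gained + 2% lost sites planted independently per tissue,
baseline presence probability 0.15, occupancy effect 0.7, intensity
effect 1.5 log2 units with per-sample noise sd 0.5 (log2 intensities are
lognormal draws around a per-site baseline).  These clear the |POC| > 0.5
and |logFC| > 1 conventions with realistic noise.

Expression: 10,000 genes — a realistic transcriptome size kept on the
compressed genome, because the variance of ratio statistics like DRS is
controlled by the number of genes entering the ratio, not by genome
length.  A gene's DE probability decays linearly from 0.6 at a planted
CAS to a background of 0.2 at 100 kb and beyond; the background rate
matches the double-digit DEG percentages of cancer-vs-normal cohort
comparisons at the |log2FC| > 1, FDR < 0.01 convention.  DE direction
follows the nearest planted site's direction with 0.9 concordance.
Planted log2FCs are applied to that tissue's cancer samples in one
genes × samples matrix, which is what the clustering stage consumes.

3D tracks: a sinusoidal compartment baseline (period 2 Mb) clamped away
from zero, with planted bins forced to flip sign at magnitude ≥ 0.15;
insulation baselines carry boundary dips every 1 Mb with ±0.4
cancer-normal perturbations at planted bins; replicate noise 0.02 (PC1)
and 0.05 (IS).  Contact matrices have 1/(1+d) decay, 2× TAD blocks every
25 bins, loop pixels at fold 5 over their local background, a 2× cancer /
normal fold ratio at gained-CAS-anchored loops, and symmetric 5%
multiplicative noise.  Where opposite-direction sites share a 50 kb bin,
the gained class takes the bin; the per-bin switch truth, not the
per-site class, is the recovery surface.

Clinical: exponential survival with a planted hazard ratio (default 3)
in half the patients and uniform administrative censoring; methylation
betas Beta(2,8) with planted Beta(8,2) hypermethylation at lost-CAS loci
only (the asymmetric truth — gained-CAS hypomethylation is deliberately
absent); TF peaks preferring CASs (p 0.5 vs 0.05) for half the factors;
uniform mutations with optional class-restricted enrichment; depletion
tables with a planted excess of decreased genes (0.6 vs 0.25) in a chosen
group.

What the generator does **not** emulate: read-level noise and mapping
artefacts, copy-number structure, GC/accessibility biases in peak
calling, batch effects across the heterogeneous datasets a real cohort
pools, correlated gene co-expression modules, and non-exponential
survival.  Passing tests therefore demonstrate that the statistics
recover the effects they target under their stated noise model — not
that real-cohort confounders are handled.

## Numerical conventions

Coordinates are 0-based half-open everywhere; site position for distance
models is the interval midpoint; promoter windows are (−2000, +500) bp
around the strand-aware TSS with precedence promoter > exonic > intronic >
intergenic.  Missing track bins propagate as NaN, never as zero.  Fisher
p-values are cached by table (cohort margins repeat heavily) and match
integer-arithmetic enumeration to better than 10⁻¹⁰; BH matches the
step-up rule exactly (note BH is *not* idempotent — re-adjusting adjusted
values is a user error the API cannot detect).  The Simpson index counts
intersections on the smaller set, making it symmetric.  Median splits
send ties to the low group.  All randomized procedures take either a seed
or a `numpy.random.Generator`; seeds derived from a root stay below 2³¹.

## Problem sizes

Tests and the acceptance script run the default 10,000-site cohort for
recovery checks, a 2,000-site universe with 1,500 loops and 3,000 genes
for loop-model calibration (500 null replicates), 50 seeds for the null
DRS check, 2,000/1,000 replicates for log-rank calibration, and 200×200
matrices for the insulation oracle — sizes at which every Monte-Carlo
bound in the suite is stable across seeds.
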