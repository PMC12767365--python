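# Methods

`osmoloop` re-implements, as a tested library, the quantitative core of a
hyperosmotic-stress 3D-genome analysis: differential chromatin-loop testing
on deliberately unscaled counts, aggregate Hi-C (APA) with a corner-background
enrichment statistic, DBSCAN-based loop merging and anchor classification,
covariate-matched null loop sets, and coupled loop/expression time-course
analysis. Because the full experiment (multi-billion-read Hi-C, deep RNA-seq)
is not reproducible at desk scale, every stage is exercised on a synthetic
generator that emulates the data's statistical structure with known ground
truth; the package's claims are therefore *property* claims (recovery,
calibration, monotone phenomenology), not numerical reproductions of the
original study's counts.

## Coordinate and storage conventions

All intervals are 0-based half-open (BED/BEDPE). Bin index =
`floor(pos / resolution)`; an anchor is snapped to the single bin containing
its midpoint, and a midpoint lying exactly on a boundary goes to the
right-hand bin. Contact matrices are stored per chromosome as sparse
upper-triangular integer counts; queries are symmetric. Inter-chromosomal
entries are rejected at read time (the analysis excludes them regardless).
The canonical on-disk form is a text triple file (`chrom  bin1  bin2  count`
with a `#resolution=` header); everything else is TSV, BED, or BEDPE.

## Synthetic data model

**Contacts.** The background is Poisson with a distance-decay mean
λ(d) = A·(1 + d/d₀)^(−α) per pixel; defaults A = 120, d₀ = 5 bins, α = 1 on
one 20-Mb chromosome at 10-kb bins, giving loop-pixel background means of
roughly 7–25 counts at 250 kb–1 Mb spans — comparable to a deeply sequenced
map, and small enough that every experiment runs in seconds. Per-sample
log-normal depth factors (σ = 0.08) induce the mild extra-Poisson replicate
variance the NB stage must absorb; the paired replicate design absorbs their
mean, leaving a residual dispersion ≈ e^{σ²} − 1 ≈ 0.0064.

**Loops.** A loop multiplies the background by three components: a focal
Gaussian kernel `1 + (a − 1)·exp(−r²/2σ²)/σ²` truncated at 3σ (the 1/σ²
scaling makes the *integrated* added signal independent of σ, so σ is a pure
punctateness knob: at σ = 1 the center multiplier equals the amplitude `a`;
sharper loops concentrate the same signal into fewer pixels); a domain factor
over the square between the anchors; and a stripe factor along the square's
borders. Overlapping loops compose multiplicatively.

**Classes and trajectories.** Treated-condition amplitudes follow per-class
trajectories over the 8-point course (0 h, 10 min, 30 min, 1 h, 3 h, 6 h,
12 h, 24 h): *gained* loops rise from 1 (absent) to 5 at 1 h and decay to
1.5 by 24 h; *pre-existing* loops collapse from 5 to ~1.3 by the first
treated points and partially recover from 3 h; *static* loops hold at 4.
Control maps use each loop's baseline amplitude throughout. Gained loops are
longer-range, more punctate (σ = 1 vs 2) and sit on weaker domains/stripes
than pre-existing loops, and about half are placed to reuse one pre-existing
anchor (repurposed architectural nodes). The two-condition differential
population uses ×3 (gained), ÷3 (lost) and ×1 (static) amplitude ratios.

**Expression and occupancy.** Gene counts are negative binomial
(default dispersion 0.05, base means 50–500) with class trajectories:
gained-anchor genes show late induction reaching ≥ 4.5-fold by 24 h;
lost/static-anchor genes change little; off-anchor genes are flat, transient
(peak 2.5× at 1 h), or sustainedly repressed (0.25× by 24 h). A
per-replicate log-normal factor (σ = 0.1), constant across time, is absorbed
by the design's replicate term. Occupancy peaks sit at gained-loop anchors
and inside loop interiors; treated means are scaled by retention factors
0.85 (at anchor) vs 0.35 (within loop), reproducing global loss with anchor
retention. Promoters are placed at anchors with class-dependent
probabilities (0.674 gained, 0.231 lost, 0.328 static) plus random
background promoters.

All randomness flows from one master seed through named `SeedSequence`
child streams; outputs are bit-reproducible.

**What the generator does not emulate:** compartments and TAD hierarchy
beyond the loop-square model, restriction-fragment or read-level noise,
mappability/GC bias, mean-dependent dispersion trends, and inter-chromosomal
contacts. Passing tests therefore demonstrate that the *methods* behave as
claimed under the assumed model, not that real libraries meet those
assumptions.

## Differential testing (nb_diff)

Counts are modeled per feature as NB(μ, α) with log link and **no size
factors** (offsets 0): under osmotic stress, global interaction and
occupancy levels genuinely change, and library-size normalization would
absorb exactly the effect under study. The cost, accepted deliberately, is
that technical depth differences are attributed to condition; the generator
mirrors this regime with paired replicates.

Fitting is IRLS, batched across features sharing a design matrix.
Dispersion is estimated per feature by Cox–Reid-adjusted profile ML on a
44-point log-spaced grid (10⁻⁸–30) with quadratic interpolation at the
optimum, then stabilized by an empirical-Bayes squeeze of log-dispersions
toward a common value: the common value is the argmax of the *pooled*
adjusted profile likelihood (summing per-feature maxima instead would be
selection-biased toward large estimates), per-feature sampling variances
come from the local profile curvature, and the between-feature variance τ²
is a DerSimonian–Laird moment estimate. Features with flat profiles (little
dispersion information) shrink fully to the common value; genuinely
heterogeneous dispersions (τ² > 0) retain their individuality. No
mean-dispersion trend is fitted, and no log-fold-change shrinkage is applied
— effect sizes are unshrunk MLEs with Wald SEs, which affects ranking of
borderline features but not the threshold logic used here.

Wald tests use the normal reference; LRTs compare nested designs with
2·Δlog-likelihood against χ² with df = the column difference, computing both
fits at the full model's dispersions. With few residual degrees of freedom,
these references are only calibrated when dispersion is effectively known;
the EB squeeze supplies that (measured on 5,000-feature nulls: Wald
rejection 0.050–0.056 at α = 0.05; LRT p-values pass a KS uniformity test).
Multiplicity is controlled by Benjamini–Hochberg throughout.

Classification presets mirror the analysis thresholds: loops padj < 0.1
(sign of log₂FC splits gained/lost); genes per timepoint padj < 0.05 and
|log₂FC| > 2; occupancy peaks padj < 0.05 and |log₂FC| > 1, relaxed to
padj < 0.1 for low signal-to-noise factors. Count filters: genes ≥ 50 counts
in ≥ 4 samples (a lenient ≥ 10-in-≥ 4 preset is also shipped); peaks mean
count ≥ 15.

## Aggregate analysis (apa)

APA extracts raw-count ±10-bin windows centered on gridded loop pixels and
averages them (normalization by loop number only). Exclusions, each tallied:
inter-chromosomal loops; windows overlapping the diagonal (span ≤ 2w+1 bins
— short-range windows are decay-dominated and would contaminate the mean);
out-of-bounds windows; windows whose center row or column sums below 1
(dead anchor bins — our reading of the row/column-sum rule). Raw counts are
used for all statistics; iterative-proportional-fitting balancing exists
only for display matrices.

The enrichment score is exactly `median(fg + 1) / median(bg + 1)` with
foreground the center pixel (or 3×3) and background the top-left plus
bottom-right 3×3 corners — which sit at roughly the loop's genomic distance,
controlling for decay — or the ring at Chebyshev distance w.
`background_normalize` divides `(M + 1)` by `(corner median + 1)`, so the
normalized center equals the enrichment score identically; the +1 guards
mean exact scale invariance holds only for uniform blocks.

Domain aggregates take a window spanning the loop ± 0.5·span, restricted to
loops ≥ 150 kb, bilinear-resize it to 100×100 on corner-aligned grids,
normalize each window to unit total, and average. Diagonal profiles divide
the main diagonal by the corner-median background. `standardize_loops`
recenters every loop to a uniform 150-kb span (span, not anchor width, is
our reading of "uniform width") about the loop-pixel midpoint.

## Anchor operations (anchors)

Loop calls are merged across replicate/condition sets by DBSCAN on the 2-D
points (anchor1 start, anchor2 start), Manhattan metric, ε = 20 kb
*inclusive*, min_samples = 1 — so clusters are exactly the transitive
closure of the within-ε relation and no call is discarded as noise (the aim
is consolidation, not outlier removal). Cluster representatives are
member-wise median anchors snapped to the grid; output ordering and cluster
ids are deterministic and permutation-invariant.

A treated loop is *pre-existing* when some reference loop matches both
anchors within one bin (order-respecting), else *de novo*; it *shares an
anchor* when at least one reference anchor falls within the slack of either
anchor. Both loop-denominator and anchor-denominator shared fractions are
reported, since the headline statistic is ambiguous between them. Peak
location labels give precedence to at-anchor over within-loop.

## Matched null loops (matching)

Covariates are log loop span and log aggregated contact frequency (loop
pixel count summed over both conditions; zero sums are missing and excluded
with a tally). Control loops are drawn without replacement from quantile
strata of an estimated propensity score (logistic regression of
focal-vs-pool membership on the covariates; 20 bins). We moved from joint
covariate-quantile strata to propensity strata after measuring that coarse
covariate bins leave residual imbalance ≈ 0.2 SMD under a 1-sd covariate
shift; the propensity score's balancing property brings the matched design
below 0.1 SMD, and is also what the reference implementation of stratified
interval matching stratifies on. Focal loops in strata with an exhausted
pool are reported unmatched rather than reassigned; balance (standardized
mean differences) is assessed on the matched design — matched focal subset
vs drawn controls — with shortfalls tallied per stratum.

## Time-course couplings

Per-class APA enrichment curves are computed at every time point from the
treated maps; the Pearson correlation between the gained and
collapsing-class curves summarizes their opposition. For expression,
replicate-averaged log₂(x+1) profiles are z-scored per gene (zero-variance
genes map to the zero vector) and clustered by k-means (k = 3, 20 restarts,
fixed seed) as a variance-stabilizing-transform stand-in; per-class median
log₂FC trajectories are tested per timepoint with one-sample t-tests,
BH-adjusted across timepoints, starred at 0.05/0.01/0.001.

## Problem sizes and numerical choices

Validation experiments use one 20-Mb chromosome at 10-kb bins (2,000 bins),
30–200 loops, 4 replicates per condition, 5,000-feature null panels, and
500-gene expression panels — sizes at which every experiment completes in
seconds while Monte-Carlo error stays well inside the asserted margins.
IRLS converges at |Δβ| < 10⁻⁹ (cap 60 iterations; non-convergence is
flagged, the feature retained); dispersions are floored at 10⁻⁸ and the NB
likelihood switches to its Poisson limit below 10⁻⁷; η is clipped at ±30;
balancing stops at max relative row-sum deviation < 10⁻⁵ or 200 iterations
with zero-coverage bins masked. All-zero features are excluded from testing
but kept, flagged, in outputs. k-means ties are broken by the fixed seed.

## Known limitations

* Dispersion stabilization shrinks to a single common value; strongly
  mean-dependent dispersion would be better served by a trend, which is
  deliberately out of scope.
* Unshrunk log-fold-changes overstate effect sizes for low-count features.
* The exclusion rules around the APA diagonal and dead bins are reasonable
  conventions, not uniquely determined by any specification of the assay.
* The simulator's Poisson pixel noise understates the heavy tails of real
  Hi-C maps; calibration results transfer only to the extent that residual
  overdispersion is captured by the NB stage.
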