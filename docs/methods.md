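# Methods notes

This document records the statistical models `lownsel` implements, the
choices made where the design was genuinely open, and what the synthetic
data can and cannot tell you about real panels.

## Adjusted means

Grain yield is analysed separately per environment × N level with

    y = Xβ + Zu + ε,   u ~ N(0, I σ_b²),   ε ~ N(0, I σ²)

where β holds the intercept, replicate and genotype fixed effects and u
the random effects of incomplete blocks (blocks nested in replicates; an
8×8 lattice is represented simply as "block within replicate", with no
row/column recovery beyond the random block term). The variance ratio
γ = σ_b²/σ² is estimated by profiled REML: the restricted log-likelihood
is maximized over γ by bounded 1-D optimization on a log scale (γ ∈
[10⁻⁶, 10⁴]) with the γ = 0 boundary evaluated explicitly, so a
zero-block-variance fit reduces exactly to ordinary least squares.
Genotype BLUEs are read off a design with full genotype dummies and
sum-to-zero replicate contrasts, i.e. the adjusted mean sits at the
average replicate. A line absent from a trial gets a missing value,
never a fabricated one. With a single replicate the block variance is
inestimable; the default policy is to raise, with an explicit opt-in to
raw means.

Parameter-recovery simulations (200 replicate trials, σ_b = 400,
σ = 200 kg ha⁻¹) in the test-suite show the BLUEs are unbiased and beat
raw plot means on RMSE — the practical payoff of block adjustment in
incomplete designs.

## LNAE

The low-N agronomic efficiency index is computed from the IN/LN adjusted
means as

    LNAE = GY_LN · (GY_LN / GY_IN) = GY_LN² / GY_IN   (kg ha⁻¹)

— absolute low-N yield weighted by the low-N : optimal-N ratio. The index
function is pluggable should a program prefer another stress index. The
per-line "combined" LNAE is the arithmetic mean over environments; for
balanced data this equals the least-squares line mean of the two-way
ANOVA model (asserted in the tests), and both views are exposed because
either convention is defensible when environments are unbalanced.

The LNAE ANOVA is a fixed-effects two-way model (environment + line) fit
by OLS (statsmodels); its residual mean square and degrees of freedom are
the default error term for the Scott–Knott test, with the number of
environments as the per-mean replication.

## Scott–Knott grouping

The divisive procedure of Scott & Knott (1974): order the g means, find
the contiguous 2-way cut maximizing the between-group sum of squares B₀,
and accept it when

    λ = π/(2(π−2)) · B₀/σ̂₀² > χ²(α; ν₀),   ν₀ = g/(π−2)

with σ̂₀² = (Σᵢ(ȳᵢ−ȳ)² + ν·s²_ȳ)/(g+ν), s²_ȳ = error_ms/r and ν the
error degrees of freedom; the fractional ν₀ uses the continuous χ²
quantile. Accepted cuts recurse on both sides; groups are numbered in
descending mean order. Ties are handled deterministically: means are
sorted with line-id tie-breaks and a cut never separates exactly equal
means, so a group of identical values is never split. Null calibration
(1,000 two-way layouts with no line effect) puts the root-split
rejection rate at the nominal 5% within binomial error.

One behavioural note: the procedure is consistent, so with a very small
error mean square *any* real differences among means are split apart —
groups multiply as error → 0. "Two clear clusters → exactly two groups"
therefore holds when the separation dwarfs the error SD while the
within-cluster spread does not, which is the regime the tests exercise.
When more than two groups emerge but a two-group contrast is needed
downstream, the **root split** (the single best 2-way cut) is the
natural partition and is what the pipeline's scan stage falls back to;
it coincides with the full partition whenever that partition has two
groups.

## Marker QC and LD pruning

Call-rate and MAF thresholds are inclusive for keeps (≥ 0.90, ≥ 0.05 by
default); allele frequencies count each inbred line as a single allele
draw. LD is the squared Pearson correlation of allele-count codes over
pairwise-complete lines — for fully inbred material genotype r² equals
haplotype r², so no haplotype phase is needed. Pruning slides a window
(default 50 markers, step 5) along each chromosome; within a window the
strongest violating pair (r² strictly > threshold, default 0.13) loses
its lower-MAF member (position tie-break toward the later marker), and
sweeps repeat to a fixpoint so the surviving set contains no
within-window violating pair. The removal rule favors informative
markers and is deterministic.

Note that at 64 lines the null distribution of r² puts ~0.3% of
*independent* marker pairs above 0.13, so pruning a linkage-free
simulated panel at that threshold removes a sizable random fraction; the
demo configuration therefore prunes at 0.8 (near-duplicates only), while
0.13 remains the default intended for real array data with true LD.

## Diversity

IBS between two lines at a locus is the probability that one allele
drawn from each matches: 1/0 for identical/opposite homozygotes, fixed
at ½ when either call is heterozygous (impossible in inbred data, but
the convention is pinned because upstream tools vary). Distance is
1 − mean IBS over markers called in both lines; a pair sharing no
markers is flagged missing. PCoA is Gower's classical scaling — square,
double-center, eigendecompose, scale eigenvectors by √eigenvalue —
reporting negative eigenvalues but dropping their axes. An optional
standardization flag divides distances by their maximum first; it is off
by default since it changes only the scale of the embedding.

The Evanno ΔK summary consumes a plain (K, run, logL) table from
external model-based clustering runs: ΔK(K) = mean over run-aligned
replicates of |L(K+1) − 2L(K) + L(K−1)|, divided by the SD of L(K)
across runs. Endpoints get no value and a zero-SD K is flagged
undefined. Because the numerator and denominator are both noise-driven
when L is linear in K, ΔK is O(1) rather than 0 in the no-structure
case; what identifies the number of groups is a *peak* that stands far
above that baseline.

## Selection scan

The contrast statistic is the two-population Weir–Cockerham θ with
haploid coding: fully homozygous diploids carry no within-individual
information, so each line contributes one allele draw (group sample size
= number of called lines). The implementation follows the moment
estimator (T₁/T₂ as in the README) and is verified against an
independent step-by-step computation to 10⁻¹², against relabelling
invariance (p → 1−p), and against the published worked contrasts: at
group sizes (29, 35), frequencies (0.43, 0.03) give θ = 0.3666 → 0.37
and (0.33, 0.03) give 0.2559 → 0.26 at two decimals. Negative estimates
(expected under no differentiation at finite samples) are reported as
computed, with an optional clamp at zero. Monomorphic markers and
markers where a group has fewer than two called lines are flagged, not
silently dropped. No multiple-testing correction is applied: the scan is
a fixed-threshold design (θ > 0.2, strict), and the genome-wide mean θ
is reported alongside.

The favorable allele at an outlier marker is the allele *enriched in the
high-tolerance group relative to the low group* — it can be, and in the
strongest published example is, a minority allele in both groups — so
FFA_H ≥ FFA_L by construction; an exact between-group tie excludes the
marker with a warning. NFA counts outlier loci at which a line is
homozygous for the favorable allele (loci, not allele dosage, since the
lines are inbred); a missing call counts 0 by default, with a
"scale-by-completeness" alternative. The NFA–LNAE association reports
the Pearson correlation with its two-sided t-test p-value and the simple
LNAE-on-NFA regression; R² = r² is asserted as an internal identity.

## Synthetic data

The generator emulates the study design the package targets: 64 fully
homozygous lines split a priori 29 H / 35 L, 12,050 biallelic SNPs over
10 chromosomes (240 Mb each, sorted distinct positions, random distinct
ref/alt nucleotides), uniform(0.05, 0.95) neutral allele frequencies
shared between groups (so MAF filtering removes little), a handful of
planted loci with group-specific favorable-allele frequencies (default
four loci at 0.45 vs 0.05), and uniform missingness (default 2%).

Two deliberate design points:

- **Planted loci realize their configured frequencies by exact counts**
  (round(n_g·f) favorable alleles permuted within each group) under the
  default `"exact"` sampling, so a "0.45 vs 0.05 contrast" is what the
  panel actually carries and recovery tests measure the estimator rather
  than binomial draw noise. A `"binomial"` mode draws each line
  independently for calibration studies.
- **A priori truth labels.** Lines are assigned H/L before phenotypes
  exist, giving an unambiguous ground truth for contrast-scan power
  tests; the phenotypic grouping the pipeline estimates can then be
  compared against it.

Phenotypes are plot-level yields: baseline per N level (5,500/2,800
kg ha⁻¹ IN/LN), evenly spaced environment offsets (span 500 kg ha⁻¹;
dose pairs 150/60 then 100/35 kg N ha⁻¹ across seasons), random
partition of lines into blocks of 8 per environment × N level ×
replicate, block effects N(0, 250²), residuals N(0, 350²), and — the
genetic signal — `effect_per_favorable_allele` (default 150 kg ha⁻¹)
added to LN plots per favorable allele carried. The default effect size
targets an NFA–LNAE correlation of roughly 0.7 at panel scale; no
published effect sizes exist to calibrate against, so this is a
qualitative, not quantitative, match. The demo configuration uses 400
kg ha⁻¹ ("strong effect") so planted loci are unambiguous at reduced
marker counts.

All draws flow from the single config seed through independent child
streams (genotypes stream 0, phenotypes stream 1), so each operation is
bit-reproducible on its own and phenotypes can be re-simulated on fixed
genotypes.

What the generator does **not** emulate — and hence what passing tests
do not show about real data: linkage disequilibrium and haplotype
structure (markers are independent given group, so LD pruning on
simulated panels removes only chance correlation), population
substructure beyond the two-group contrast, genotyping error beyond
uniform missingness, spatial field trends, genotype × environment
interaction, and any polygenic background beyond the planted loci.

## Numerical conventions and edge cases

- Genotype calls are int8 codes {0, 2, −1}; positions 1-based; alleles
  stored as given (array data are strand-ambiguous, nothing is flipped).
- Heterozygous VCF calls are set missing with a warning by default
  ("strict" raises); multiallelic records are rejected.
- QC keeps are inclusive (≥), LD removal and outlier calling strict (>).
- θ at a pooled-monomorphic marker is NaN + flag; mean Fst averages
  defined values only.
- PCoA eigenvalues below 10⁻¹⁰ of the leading one are treated as null
  axes; proportions are relative to the positive eigenvalue sum.
- Scott–Knott with error_ms = 0 and a positive B₀ declares the split
  (λ = ∞) unless all means are equal.

## Problem sizes in the test-suite

Simulation-based checks run at reduced scale chosen to keep the whole
suite fast while leaving comfortable statistical margins: 2,004-marker
panels for planted-locus recovery (20 replicates), 1,000 null
replicates for Scott–Knott size, 200 trials for adjusted-mean recovery,
1,500-marker null panels for the scan baseline. The full-scale default
(12,050 markers) runs in the same code paths and is exercised by the
generator's own tests.

## Known limitations

- The REML profile assumes a single block variance per trial; more
  structured designs (row–column, spatial) are out of scope.
- The Evanno summary requires run-aligned replicates; unpaired run
  tables must be aligned by the caller.
- LD pruning recomputes window correlation matrices per sweep; for
  panels far beyond ~10⁵ markers a dedicated tool is the better choice.
- The scan assumes exactly two groups; multi-group differentiation
  statistics are not implemented.
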