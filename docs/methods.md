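# Methods

This note documents the statistical procedures implemented in `omicdiv`,
the choices made where the methodology was genuinely open, and what the
synthetic-data tests do and do not demonstrate.

## Differentiation statistic

For a variant with allele frequencies p₁…p_k in k populations, the package
computes

F_ST = (k − 1)·σ² / (k·p̄·(1 − p̄)),

where σ² is the **sample** variance of the frequencies (divisor k − 1) and
p̄ their unweighted mean. The divisor matters: the published
pharmacogenomic benchmark values only reproduce with the sample variance
(the population-variance form deflates every value by (k−1)/k ≈ 33% at
k = 3). A variant monomorphic in all populations has an undefined ratio and
is reported as F_ST = 0 with a `monomorphic` flag. Frequencies are computed
from non-missing chromosomes only; a population with no called genotype at
a variant makes that variant's F_ST NaN rather than silently using fewer
populations.

Two properties worth noting. The statistic is invariant under allele
relabelling (p → 1 − p), and for frequencies drawn from a divergence model
with parameter F (below) its expectation is ≈ (k−1)/k · F, not F — the
sample variance of k draws estimates the per-population drift variance, and
the (k−1)/k factor comes from the p̄(1−p̄) denominator using the mean
frequency. Parameter-recovery tests therefore check monotonicity in F and a
band around (2/3)F, not equality with F.

**HLA classical alleles** are treated one-vs-rest: each observed allele at
a locus becomes the alternate allele of a pseudo-biallelic variant whose
per-population frequency is its count over called chromosomes. Frequencies
across alleles at one locus sum to 1 per population.

**Driving pair.** Each k = 3 statistic is attributed to the population pair
with the largest two-population F_ST (same formula at k = 2), ties broken
by the declared population order. The attribution rule is our
interpretation — published analyses state attributions without defining the
rule — and it reproduces the published attribution of the benchmark
variants.

**Empirical p-values** are strict exceedance fractions against the
genome-wide null: p = #{null > observed}/#null, exactly as defined, with no
pseudocount. An observation above the null maximum gets p = 0 (flagged); a
"+1" corrected mode exists but is off by default because the uncorrected
form is what reproduces published columns. Variants at p < 10⁻⁴ are
flagged, the conventional threshold for pharmacogenomic panels scanned
against genome-wide content.

## Window scan

Chromosomes are tiled into non-overlapping windows of 100,000 bp indexed
from the chromosome start (SNP at 1-based position pos falls in window
⌊(pos−1)/W⌋), so the tiling is reproducible and independent of SNP
content. A SNP is "high" when its F_ST exceeds the (1 − 0.01) quantile of
the genome-wide distribution; the background rate q is the realized high
fraction (equal to 1% up to ties). Each occupied window with n SNPs and x
high SNPs is scored with the exact upper tail P(X ≥ x), X ~ Bin(n, q),
computed by log-space summation of the pmf (matches the survival function
to ~10⁻¹⁴ relative). Significance is Bonferroni at α = 0.05 over occupied
windows; maximal runs of adjacent significant windows merge into regions
reported as 0-based half-open BED intervals. The top-1% cutoff and the
Bonferroni level are exposed as options (`--high-quantile`, `--alpha`)
because the published procedure does not state them; the scan is one-sided
(over-representation only), no mid-p correction.

## Group contrasts

Each feature y is fitted by OLS with treatment-coded factors:
y ~ population + covariates (sex and batch or RT plate in the shipped
pipelines). The population effect is the partial F comparing this model to
the covariate-only model — with main effects only this equals the Type
II/III sum-of-squares test, and with no covariates and balanced groups it
reduces exactly to textbook one-way ANOVA (verified against a
sums-of-squares oracle at 10⁻¹⁰). Missing y drops the sample featurewise;
a missing covariate drops the sample platform-wide; a feature with an
entirely missing population is skipped with a flag; a covariate collinear
with population raises an error naming it.

**Least-squares means** are model predictions per population averaged over
a balanced grid of the other factor levels: lsm(g) = intercept + β_g +
Σ_f (Σ β_f)/L_f. Continuous covariates (none in the shipped pipelines)
would be held at their mean. On balanced designs lsm differences equal raw
mean differences; on confounded designs they equal the prediction-grid
average (tested against a statsmodels prediction oracle).

**Fold change** between groups a, b on log2-scale data is
2^(lsm_a − lsm_b), so FC(a,b)·FC(b,a) = 1 exactly. Bonferroni correction
is min(1, m·p) with m the number of features actually tested on the
platform (skipped features do not count). The driving pair for
quantitative features is the pair with the largest |lsm difference|.

## Lipid tagging

Within one population, squared Pearson correlation r² is computed for every
feature pair on log2 concentrations, complete-case per pair (minimum 3
jointly observed samples; sparser or zero-variance pairs are undefined and
force singletons). Tags are selected by deterministic greedy set cover at
r² > 0.8: repeatedly promote the feature with the most uncovered
above-threshold neighbours (ties: higher mean r² to those neighbours, then
lexicographic ID); its uncovered neighbours become its tagged members.
Tagging is **direct** — every member exceeds the threshold against its own
tag, mirroring tag-SNP semantics — with a transitive-closure mode available
(`--tag-algorithm transitive`) since the original clustering software's
mode is not documented. The reports satisfy, by construction and by test:
tags + tagged + singletons partition the panel; every tagged member has
r² > threshold to its tag; n_representative = K − n_tagged; and
n_representative is non-decreasing in the threshold.

## Ordination

PCA is an SVD of the standardised sample×feature matrix. Genotype mode
centres each SNP at 2p̂ and scales by √(p̂(1−p̂)) — the population-genetics
convention that weights SNPs by drift information; quantitative mode
z-scores columns, chosen over centre-only because clinical/dietary matrices
mix units (a centre-only mode would let high-variance units dominate).
Missing entries are column-mean imputed for the decomposition only and
never written back; constant columns are dropped with a record. Component
signs are fixed (largest-|loading| positive). Variance fractions are
eigenvalues over total standardised variance and sum to 1 at full rank.
LD thinning is a single greedy pass in position order dropping SNPs with
genotype r² above a cutoff to any retained SNP within a bp window, followed
by seeded down-sampling. Iterative outlier removal as done by some
eigenanalysis tools is deliberately not replicated.

## QC cascade

Filters are pure functions returning a new matrix plus a report stage;
counts are conserved (removed + retained = input) at every stage and the
configured order is preserved. Thresholds follow the conventional array
workflow: samples with missingness > 2% removed, SNPs with missingness
> 5% removed (both strict inequalities), SNPs at Hardy–Weinberg exact
P < 10⁻³ **within any single population** removed (a fail-all mode is
available; the within-population rule is deliberately conservative for
genotyping artefacts). The HWE test is the exact conditional test: given
the observed allele counts, the heterozygote count's conditional pmf is
evaluated over its full support and the two-sided p is the total mass of
outcomes no more probable than the observed one — robust at the low minor
allele counts typical of exome-array content, and verified against an
independent recurrence-based enumeration for every configuration up to 200
samples. Sidedness is a choice (the convention of genotyping-QC exact
tests); whether founders only should be tested is moot for unrelated
cohorts. Call-rate filters implement both published boundary conventions:
assay panels remove at call rate ≤ threshold (a feature at exactly 90%
call rate is removed), clinical variables at missingness > threshold (a
variable at exactly 20% missingness is retained). Duplicate/related-sample
and population-label-mismatch removals require genetic inference outside
this package's scope and are applied as user-supplied exclusion lists.
Array merging keeps, per overlapping SNP, the copy with less missingness
(ties keep the first input); panel concordance removes SNPs agreeing with
a reference genotyping on < 95% of jointly called samples.

## Synthetic cohort generator

The generator exists so that every downstream stage is exercised with known
ground truth; its defaults mirror the motivating cohort: 122/120/122
samples in three populations, genome-wide divergence F = 0.01 (matching
the 1–3% pairwise F_ST range typical of the three source populations),
282 lipid species in 20 correlated blocks, 274 miRNAs, and a desk-scale
4,000-SNP, 400-transcript genome (full-scale feature counts would add
nothing statistically and would slow the suite).

- **SNPs**: Balding–Nichols — per-population frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around an ancestral p ~ U(0.05, 0.95);
  one parameter maps directly to expected differentiation. Genotypes are
  binomial (Hardy–Weinberg) within population; positions lie at a fixed
  5-kb stride (20 SNPs per 100-kb window, deterministic tiling). No
  linkage disequilibrium between loci is simulated.
- **HLA-style loci**: ancestral allele simplex ~ Dirichlet(1,…,1);
  population simplexes ~ Dirichlet(ancestral·(1−F)/F), the multi-allelic
  analogue of the beta draw; two independent allele draws per sample.
- **Quantitative platforms**: unit-SD normal features around log2
  baselines ~ N(18, 2). Lipid blocks share a latent factor with loading
  block_r2^¼, so pairwise within-block correlation is √block_r2 and the
  pairwise **squared** correlation hits the block_r2 target (an earlier
  √block_r2-loading draft landed at block_r2², visibly below the tagging
  threshold). Population shifts of `effect_size` SD are planted on
  trailing features (rotating the shifted population), and sex (+0.5 SD on
  every 5th free feature) and batch/plate offsets (N(0, 0.4) per level on
  every 3rd) are added **outside** the blocks so block correlations stay
  at their design value. Uniform missingness at `missing_rate`.
- Sexes are balanced within population; batches assigned round-robin —
  minimal confounders that exercise the covariate adjustment without
  creating collinearity.

A single seeded generator drives all draws; a fixed design reproduces the
cohort byte-for-byte. No published generative model exists for any of
these platforms: all distributions are implementer choices, recorded as
such in the cohort's truth metadata.

**What the synthetic tests show** — that the estimators recover planted
structure under their own model assumptions (divergence monotonicity,
planted-window detection with Bonferroni-clean backgrounds, full power on
1.5-SD shifts with controlled false positives, tag-block recovery) and
that type-I error is calibrated under the null. **What they do not show** —
performance under real LD structure, non-normal lipid distributions,
platform-specific missingness mechanisms, or population substructure;
cohort-scale result inventories from the motivating study depend on its
access-controlled data and are out of scope.

## Numerical choices and degenerate inputs

Binomial tails and the HWE pmf are computed in log space (gammaln +
log-sum-exp); the HWE p-value includes ties with a 10⁻⁹ relative tolerance
so exactly symmetric outcomes are never split by rounding, and the per
allele-count distribution is cached. Empirical p-values use sorted-search
counting. F_ST at p̄ ∈ {0, 1} is 0 by convention; windows with no SNPs emit
no probability; PCA drops constant columns; fold changes require finite
lsm. Greedy ties everywhere (driving pairs, tags, array merges, LD
thinning) break by fixed declared order so outputs are reproducible.

## Problem sizes in the shipped checks

The test and acceptance runs use desk-scale sizes chosen to make the
statistical assertions sharp rather than to mimic production volumes:
10⁶ random frequency triplets for range/symmetry; all ≤ 200-sample HWE
configurations (~1.4M genotype configurations) against the enumeration
oracle; binomial tails to n = 1000; 1,000 null features for ANOVA
calibration; 20 planted-window and 50 planted-shift replicates at the
cohort's own sample sizes.

## Known limitations

Only the frequency-variance F_ST estimator is provided (no
Weir–Cockerham/Hudson family; the package reproduces one published
analysis style, not the estimator literature). The window scan assumes
independent SNPs when interpreting the binomial model — under real LD the
tail probabilities are anti-conservative and the Bonferroni correction
partially compensates. ANOVA assumes homoscedastic normal errors within
groups; no nonparametric fallback is provided. Binary clinical variables
are not given a dedicated proportion test. The tagging cover is greedy,
not minimal; the exact minimum-cover can be smaller in adversarial
correlation structures.
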