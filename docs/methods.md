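# Methods

`magicqtl` implements haplotype-based QTL mapping for an eight-founder
MAGIC (Multi-parent Advanced Generation Inter-Cross) wheat population,
together with a simulator that generates populations with known ground
truth so every inference stage can be validated end to end. This note
records the models, the defaults and why they were chosen, the numerical
decisions, and the known limits of what the simulations demonstrate.

## Population simulator

**Breeding design.** Each recombinant inbred line (RIL) descends from one
funnel: four 2-way crosses, two 4-way crosses, one 8-way cross (three
rounds of intercrossing), then five generations of selfing by single-seed
descent. One line is drawn per random funnel permutation. Default
population size is 208 lines with two replicates per line, the core-set
scale of the NIAB elite wheat panel this design emulates.

**Meiosis.** Crossovers are a Poisson process at 1 per 100 cM (Haldane
model, no interference), with the starting homolog chosen uniformly.
Interference models, epistasis and genotype-by-environment effects are
out of scope. Expected residual heterozygosity after five selfing rounds
is 2^-5 ≈ 3.1% per locus, which the simulator reproduces.

**Founder haplotypes.** Biallelic, drawn so that a random founder pair
differs at a marker with probability `divergence` (default 0.5, roughly
the information content of a well-designed array in an elite panel).
Monomorphic draws are redrawn. Rates above 0.5 are reached by mixing in
balanced bipartitions and are capped by the combinatorial maximum
k(S−k)/C(S,2) (0.571 for S = 8; 1.0 is attainable only for S = 2).

**Genotyping.** Marker calls count alternate-allele copies (0/1/2); each
allele flips independently with `error_rate` (default 0.005) and whole
calls are masked with `missing_rate` (default 0.0219, the missing-data
fraction reported for the real array data).

**Phenotypes.** A trait with a planted QTL takes the mean of its two
founder means at the QTL marker (alleles act additively; residual
heterozygotes score halfway), plus Gaussian residual scaled so the locus
explains `h2_locus` of the variance of replicate-averaged line values.
Companion traits are generated from a Gaussian copula *conditional on the
standardized line values of the QTL traits*, so the target phenotypic
correlation matrix (default: the published pairwise correlations of the
phenology suite, e.g. FLS–GS39 = 0.79, completed with mild plausible
values and projected to the nearest valid correlation matrix) holds
between QTL traits and companions. Correlations between two traits that
both carry planted QTLs are governed by the genetics, not enforced.
Replicate deviations are drawn with variance 0.5× the residual line
variance and centered within line, so line means — the level at which the
published statistics were computed — carry the planted h2 and correlation
targets exactly while replicate rows still show realistic scatter. The
stress score SM is discretized onto a right-skewed 0–4 ordinal scale
(cumulative shares 0.35/0.65/0.85/0.95/1), a declared convention since
the original infection-type conversion table is not public.

With multiple QTLs on one trait, later loci enter centered on the first
locus's scale and the residual is scaled so the loci jointly explain the
sum of their h2 values; per-locus shares then follow the founder-mean
spreads (exact per-locus h2 is only guaranteed for single-QTL traits,
which is what the recovery studies use).

## Founder-descent reconstruction

A hidden Markov chain per chromosome with the founder of origin as the
hidden state. Over d cM the ancestry is redrawn uniformly from the S
founders with probability 1 − exp(−g·d/100):

    P(stay)   = exp(−g d/100) + (1 − exp(−g d/100))/S
    P(switch) = (1 − exp(−g d/100))/S        per alternative founder

`g` is the effective meiosis count (default 8: three funnel crosses plus
five selfings; the realized breakpoint density after single-seed descent
is somewhat lower, ~4 per 100 cM per homolog, but posterior accuracy is
insensitive to g in the 6–12 range). Emissions compare the observed call
with the founder allele: homozygous calls match with probability 1 − ε
(default ε = 0.01), heterozygous calls are uninformative (0.5) in the
haploid model, missing calls contribute 1. The haploid S-state space is
the default because F5+ RILs are nearly inbred; a diplotype mode with S²
ordered-pair states (independent switching per homolog, allele-wise
emission errors) provides the pair probabilities needed by the
full-interaction scan model.

Posteriors are exact (forward–backward) with per-locus rescaling, so no
underflow occurs even for maps with tens of thousands of loci; the
genotype log-likelihood is a by-product. A chromosome with no calls
yields uniform posteriors and a logged warning. Viterbi decoding breaks
ties toward the lower founder index. Its label accuracy is bounded by an
identifiability limit, not by noise: around each true breakpoint the two
adjoining founders are locally allele-identical over a geometric window
of markers, costing ~5% of markers at 1 marker/cM and shrinking with
density; allele-level agreement exceeds 99.5% regardless.

## Genome scan

At each locus the (replicate-averaged) phenotype is regressed on the
expected founder dosages from the posteriors. Haploid dosage rows sum to
one, so the intercept is absorbed and coefficients read directly as
per-founder trait means; with covariates, effects are reported at the
covariate mean. The locus is tested with a nested-model ANOVA F-test
against the covariate-only null; degrees of freedom come from numerical
ranks (SVD), so rank-deficient designs degrade gracefully. The full
interaction model has one column per unordered founder pair,
S(S−1)/2 + S in total. Missing phenotypes are dropped casewise per trait.

**Variance explained.** `var_explained` estimates the population fraction
of phenotypic variance attributable to the locus: incremental
omega-squared — (SS_locus − df·MSE)/(TSS + MSE) — rather than raw
incremental R², whose upward bias of roughly (S−1)/n ≈ 0.02 at n = 208
would systematically distort recovery; the raw incremental R² is also
reported (`r2`). Because the regressors are posterior *expected* dosages,
the locus share is further attenuated by posterior uncertainty (a classic
errors-in-variables effect, factor ≈ 0.96 under the default map); we
divide by the mean squared dosage-row norm, the same device as
imputation-INFO corrections in dosage-based association. The corrected
estimator recovers planted h2 without detectable bias in the validation
study. Founder-effect estimates need no such correction: because the
posterior dosage is the conditional expectation of the true state, the
normal equations leave coefficient estimates approximately unbiased.

## Significance

**Permutation null.** Phenotypes are shuffled across lines (genotypes
untouched), the whole-genome scan repeated, and the maximum −log10 P
recorded; the empirical (1 − α) quantile (order statistic taken from
above) is the genome-wide threshold, and observed maxima get the add-one
empirical p-value (r + 1)/(n_perm + 1). Per-locus orthonormal bases are
cached once, so each permutation costs one tensor contraction; 1000
permutations of a 208 × 300 scan take about a second. When covariates are
present the raw-data (Manly) scheme is used — y is shuffled against the
fixed covariate and genotype bases — which is exact without covariates
(the standard use) and a recognized approximation with them.

**FDR.** Storey q-values with the smoother π₀ estimate (cubic fit of
π₀(λ) over λ = 0.05…0.95, evaluated at λ = 0.95, capped at 1); for
p-vectors shorter than 100, or when the fit is unstable, the conservative
π₀ = 1 (Benjamini–Hochberg-equivalent) is used and logged. The p-value
corresponding to q = 0.05 is linearly interpolated on the sorted (q, p)
pairs and omitted when no q-value falls below 0.05.

**Calling.** A marker is called when −log10 P ≥ 4 and q ≤ 0.05 (both
configurable). Contiguous qualifying markers on one chromosome — allowing
one sub-threshold gap marker — merge into a single QTL region with its
peak marker, reflecting that a run of close peaks on a chromosome arm
typically represents one QTL; no formal support-interval method is
attempted.

## Composite scanning

Forward selection of marker covariates: scan conditional on the selected
set, admit the genome-wide top marker if its conditional −log10 P clears
the entry threshold (default 4, the same as single-locus calling), stop
at `max_covariates` (default 10) or when nothing qualifies. Covariate
blocks are the additive dosage columns with the first founder dropped
(avoiding forced collinearity with the intercept); a candidate whose
block adds no rank is skipped with a warning. Markers within 10 cM of a
selected covariate are ineligible — they re-describe the same QTL; the
window is configurable and the value is our default, chosen to exceed
the typical localization error of a peak at this map density. There is
no backward elimination.

## Phenotype preparation

Derived intervals d1 = GS55 − GS39, d2 = GS65 − GS55, d3 = FLS − GS55
(days); missing operands propagate, negative intervals are kept but
logged as possible scoring errors. Outliers beyond 4 SD are flagged,
never altered. Missing values are imputed by chained equations
(scikit-learn's iterative imputer with posterior sampling) m = 5 times
and the completions averaged per cell; observed cells are never touched.
Replicates are averaged after imputation. Correlations are reported both
pairwise-complete (pre-imputation) and on the completed table. Trait PCA
standardizes traits to unit variance. The kinship matrix uses VanRaden
frequency scaling, W W′ / (2 Σ p(1−p)) on mean-centered dosages with
missing calls contributing no deviation; the share of the leading
eigenvalue in the (non-negative) spectrum is the structure statistic. The
multiple-regression screen of FLS predictors keeps d3 in the default
predictor set — it is the screen's headline predictor — while logging a
circularity warning (d3 = FLS − GS55 contains the response
arithmetically); `exclude_derived=True` gives the stricter model.

## Validation studies and their problem sizes

The recovery study plants published QTL rows (founder means and h2) into
100 replicate populations of 208 lines on the three-chromosome desk map
(~1 marker/cM, with the published peak markers inserted at their printed
cM positions), runs inference plus the additive scan, and averages the
estimates at each replicate's genome-wide top marker. Recovered founder
effects and h2 agree with the planted values within two Monte-Carlo
standard errors.

Permutation calibration uses 400 null datasets of 100 lines on a
three-chromosome 50-marker map with 200 permutations each; the exceedance
rate of the 95% threshold is a scale-free statistic, so the reduced sizes
only widen its Monte-Carlo error (expected ~5% ± 2%).

The structure check uses a 21-chromosome map in hexaploid-wheat
proportions: the leading-eigenvalue share depends on the number of
independently segregating segments relative to the number of lines, and a
3-chromosome genome is far too small to mirror a genome-wide statistic
(random-matrix considerations put its null PC1 share near 8%, versus ~2%
at 21 chromosomes). A two-subpopulation construction from disjoint
founder draws serves as the positive control.

## What the simulations do and do not show

The generator reproduces the breeding design, marker missingness, planted
locus effects and the trait-suite correlation structure, and is the basis
for all validation. It does not attempt crossover interference, epistasis,
genotype-by-environment interaction, longitudinal growth curves, shared
founder ancestry (founder haplotypes are drawn independently), or linkage
disequilibrium structure within founder genomes. Passing recovery tests
therefore demonstrates correctness of the inference machinery under the
stated generative model, not robustness to every idiosyncrasy of real
array data.

## Numerical and degenerate-input conventions

Posterior vectors are renormalized per locus; a constant phenotype yields
F = 0 and −log10 P = 0; rank-deficient designs fall back to
pseudo-inverse effects with rank-adjusted df and a warning; a divergence
of 0, a repeated founder in a funnel, an unmapped QTL or covariate
marker, an entirely missing phenotype column, and an all-monomorphic
genotype matrix are errors that name the offender. All randomness flows
through explicit seeds; pipeline runs with the same config are
byte-identical (manifests carry SHA-256 hashes and no timestamps).
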