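# Methods

This note documents the statistical models the package implements, the
defaults and why they were chosen, what the synthetic-data generator does
and does not emulate, and the numerical conventions that affect results.

## Association model and cis inference

All association tests are simple linear regressions of an adjusted
phenotype on allelic dosage. Phenotypes are adjusted once, before any
scan: residualised on the top expression principal components (and any
user covariates), then rank-normal transformed, Φ⁻¹((rᵢ − 0.5)/n) with
average ranks for ties. Because adjustment precedes the scan, nominal
tests use df = n − 2 rather than n − 2 − k; this matches the common
two-stage practice and shifts p-values slightly relative to a joint fit.
Conditional scans residualise both phenotype and dosages on the selected
lead variants (Frisch–Waugh) and use df = n − 2 − k.

The cis window is ±1,000,000 bp around the strand-aware TSS (annotation
start for +, end for − strand), bounds inclusive. Variant QC removes SNPs
with MAF < 0.04, 1-df χ² HWE p < 1e−6 on hard-called (rounded) genotypes,
or missingness > 2%; missing dosages are mean-imputed only after QC.
Copy-number loci are exempt from SNP QC.

**Permutation gene-level p.** For each phenotype the observed statistic is
the minimum nominal p over the cis window. Sample labels are permuted
(default 10,000 times; at least 50 are required for a stable fit), each
permutation yielding a null minimum p. A Beta(a, b) is fitted to the null
sample by maximum likelihood from a method-of-moments start, and
p_beta = Beta-CDF(p_min_obs; a, b); the empirical p,
(1 + #{null ≤ obs})/(n_perm + 1), is retained as a cross-check. No
effective-degrees-of-freedom correction is fitted to the nominal p before
the Beta fit — a deliberate simplification of the original scheme that the
calibration suite shows is accurate at these window sizes (null p_beta is
uniform by KS test at 200 genes × 1,000 permutations).

Permutation RNG streams are derived per phenotype from
(global seed, CRC32 of the phenotype id), so results do not depend on the
order phenotypes are processed or on parallelisation. `map_cis` sorts
samples into a canonical order first, making the whole pipeline invariant
to sample ordering; rank-normalisation makes it invariant to affine
rescaling of the raw phenotypes.

**FDR.** Storey q-values with π₀ estimated on the λ grid 0.05–0.95 via a
cubic smoothing spline evaluated at λ = 0.95; estimates outside (0, 1)
fall back to π₀ = 1, i.e. Benjamini–Hochberg. Multiple probes per gene are
collapsed *before* FDR by keeping the probe with the most significant
nominal lead association (ties: smaller lead position, then probe id).

**Conditional signals.** The per-gene nominal threshold is the Beta(a, b)
quantile, under the gene's own permutation fit, of a gene-level
significance level taken as the midpoint between the largest p_beta among
FDR-passing genes and the smallest among failing genes (1.0 if all pass).
The midpoint matters: taking the level exactly at the last passing gene
makes that gene's own lead p equal to — not below — its threshold, and the
forward pass then finds no signals at boundary genes. Forward selection
adds lead variants while the best conditional p beats the threshold (up to
`max_signals`, default 10); the backward pass re-tests each signal
conditioning on all others, reassigns leads, and drops failures.

## Trans inference

Eligible pairs are variant–probe combinations more than 5 Mb apart
(TSS-to-variant, strand-aware) or on different chromosomes. The genome-wide
threshold comes from joint permutations of the phenotype-matrix sample
labels (default 1,000), which preserve phenotype–phenotype correlation
while breaking genotype links; FDR(t) is the ratio of the mean null hit
count to the observed hit count at nominal threshold t, and the reported
threshold is the largest t with FDR ≤ 0.05. A candidate pre-filter at
p < 1e−5 bounds the permutation bookkeeping; it cannot affect results at
any plausible final threshold. Per gene, only the most significant probe's
hits are kept, mirroring the cis probe collapsing. Permutation matrix
products run in float32 (the observed scan in float64); at the |r|
magnitudes involved this affects counts at the 1e−7 level, far below the
granularity of a 1,000-permutation null.

The cross-mapping screen is an exact ungapped minimum-Hamming-distance
search of the probe sequence (both strands) across a window — by default
the 10 Mb region centred on the trans eSNP; ≤ 6 mismatches flags the hit
as a potential paralogous-cis artefact. Indel-tolerant alignment is out of
scope. Same-gene eSNPs within 1 Mb chain-link into loci; a locus is called
single-signal when conditioning on its peak eSNP leaves no member below
the trans threshold. Copy-number dosages (0–4) run through the identical
machinery, including conditioning.

## Colocalisation and specificity

Per-variant evidence is the Wakefield log-ABF with prior effect variance
W = 0.15² for quantitative traits and 0.2² (log-odds) for case-control —
the conventional choices. Pairwise colocalisation uses priors
p1 = p2 = 1e−4, p12 = 1e−5, with the H3 term computed exactly as
S1·S2 − S12 in log space (zero for single-variant regions).

Multi-trait analysis enumerates every assignment of 2–5 traits to
"inactive" or to sharing blocks (5, 15, 52, 203 configurations for 2–5
traits). Block evidence is the per-variant sum of products of member ABFs;
distinct blocks exclude same-variant placements through pairwise
corrections, which is exact for up to two active blocks and a first-order
approximation beyond (three-way collision terms are ignored; with ≤ 5
traits and the block priors below, three-block configurations carry prior
mass ≤ 1e−12 of the total, so the approximation is immaterial). Per-variant
block priors are 1e−4, 1e−6, 1e−7 for block sizes 1–3 (the multi-trait
convention) and extend the decade-per-trait decay as 10⁻⁷·⁵ and 1e−8 for
sizes 4–5, since no published default exists; all priors are arguments.

The specificity rule: a focal-cell eQTL is **specific** when the summed
posterior of configurations in which the focal trait is active and shares
with no other cell type exceeds 0.8 *and* the single most probable
configuration has the focal trait alone; **shared** when the summed
posterior of focal-sharing configurations exceeds 0.8; otherwise
**ambiguous**.

RTC residualises the phenotype on each SNP of a supplied interval in turn,
re-tests the eSNP on the residual, ranks SNPs by residual |statistic|
ascending (rank 0 = eQTL most completely abolished) and reports
(N − rank)/N. The interval is caller-supplied (hotspot-delimited intervals
are the natural choice); the cis window is the fallback. Mediation of a
trans signal is a pairwise colocalisation of the mediator's cis statistics
against the target's trans statistics over the mediator's window, called
at PP4 > 0.8.

Allele harmonisation matches variants on (chrom, pos), flips effect signs
for swapped alleles and drops strand-ambiguous A/T and C/G variants.

## Enrichment

Density profiles count (eSNP, annotation-instance) pairs by signed
distance to the nearest interval edge in 1 kb bins to ±1 Mb. Overlap
enrichment permutes phenotype identities across the tested universe
(keeping lead-position geometry fixed), with p = (1 + #{null ≥ obs})/(B+1)
and the odds ratio contrasting observed vs mean-null overlap odds. The
GWAS colocalisation enrichment is a two-sided Fisher exact test of
colocalised/not counts for a trait against a null trait, cross-product OR
(Haldane 0.5 on zero margins), eligibility requiring at least 5 eQTL near
the trait's loci, and BH correction across eligible traits only. Pathway
enrichment is the upper-tail hypergeometric against the tested-gene
background.

## TWAS

The GRM is XXᵀ/m on column-standardised cis dosages. Heritability is
estimated by single-variance-component REML on the eigendecomposition of
the GRM with the total variance profiled out; the LRT against h² = 0 uses
the 50:50 χ²₀:χ²₁ boundary mixture, which is conservative (verified by
simulation), and genes pass at p < 0.05. Weights are learned on the
standardised-dosage scale under four predictors — single best eQTL,
ridge (a BLUP-style fixed penalty m/2, avoiding a nested CV), lasso and
elastic net (α = 0.5) with internally cross-validated penalties — and
compared by pooled out-of-fold R² over a shared seeded 5-fold split; the
Bayesian sparse linear mixed model of the original 5-model menu is not
implemented, its sparse/dense coverage being provided by the lasso/ridge
pair. Association is Z = w′z/√(w′Rw) with R the in-sample LD correlation;
no ridge term is added by default so that Z is exactly the analytic form
(a `ridge` argument exists for ill-conditioned panels). Conditional
pruning greedily selects the largest |Z| and residualises the rest through
the predicted-expression correlation with partial-correlation updates;
|ρ| ≥ 0.999 marks collinear genes. Novelty is the distance rule only — no
significant GWAS variant (p < 5e−8) within an inclusive 1 Mb of the gene
footprint; locus-to-gene scoring is out of scope and the flag should be
read as "positionally novel".

## Analytic power

For a causal variant at minor allele frequency m under HWE the genotype
variance is 2m(1−m). σ_y is the *total* outcome SD, so the residual SD is
√(σ_y² − β²·2m(1−m)) and the noncentrality of the slope t-test is
β√(n·2m(1−m))/σ_e with df = n − 2; power is the two-sided noncentral-t
tail beyond t_{1−α/2}. The alternative reading of σ_y as the residual SD
is rejected because only the total-SD reading reproduces the design
thresholds the power model is validated against. scipy's noncentral-t CDF
returns NaN in the far-tail regime this design lives in (df ≈ 243,
ncp ≈ 6.5); the implementation falls back to quadrature over the
chi-square mixing variable, validated against R's `pt(..., ncp=)` to 1e−6.

`min_maf_for_power` exploits monotonicity of power in MAF on (0, 0.5]: it
finds the continuous root of power(m) = target by Brent's method and
reports it truncated down to the 0.01 grid — the returned value is the
largest grid MAF for which power is still below target, i.e. the study is
powered for every MAF strictly above it. This matches the uniroot
convention of the standard eQTL power calculator; note that the power *at*
the returned grid value is below target by construction.

## Synthetic data: what it does and does not emulate

Genotypes are two latent haplotypes per sample with allele frequencies
uniform on `maf_range` and a first-order copying process for LD: each
haplotype's allele copies the previous variant's allele with probability
`ld_rho`, else is a fresh Bernoulli draw. Marginals are exactly HWE and,
for equal adjacent frequencies, the adjacent dosage correlation is exactly
`ld_rho`; the chain restarts at chromosome boundaries. Cost is O(nm) and
the process is fully characterised — but it is *not* human LD: no
recombination hotspots, no allele-frequency–dependent LD decay, no
population structure, no imputation uncertainty.

Expression is Gaussian: planted additive dosage effects (optionally
restricted to listed cell types), an optional two-level batch term with
N(0, batch_effect_sd) gene coefficients, optional low-rank PC noise
(k factors, N(0, pc_noise_sd) loadings) and iid N(0, noise_sd) noise.
Trans edges add slope × mediator *expression* to the target, so trans
signals are genuinely cis-mediated; copy-number effects add
slope × copies. Array-specific artefacts (probe GC, intensity-dependent
variance) are not modelled; since the pipeline rank-normalises, this
mainly limits what the tests say about raw-intensity pathologies.
Default cohort dimensions mirror a 245-sample study; planted slopes are
configuration choices (the source studies do not report effect-size
distributions), set in the strong-effect regime (standardised effects of
roughly 0.4–1.2) for recovery tests and to zero for calibration tests.

GWAS summary statistics propagate the causal z through sample LD,
z_j = r_j·z_c + ε_j, with ε built by projecting white noise through the
standardised genotype matrix so that its covariance is the sample LD —
marginally N(0,1) per variant and internally consistent for
colocalisation. se = 1/√(2·maf·(1−maf)·n) places betas on the
standardised-per-allele scale.

Passing tests therefore demonstrate correctness of the inference machinery
under a well-specified additive Gaussian world with Markovian LD; they do
not certify behaviour under real LD structure, non-Gaussian expression, or
mis-specified covariates.

## Problem sizes and numerical conventions

The test suite's end-to-end run uses 500 samples × 5,000 variants ×
200 genes × 2 cell types with 1,000 permutations in both cis and trans —
sizes chosen so every stage (including the genome-wide trans permutation
null) runs on a single CPU in a few minutes while leaving planted effects
comfortably detectable. Calibration suites use 200 replicates/loci;
recovery suites 20–40 seeded replicates against ≥ 90% thresholds.

Ties in lead-variant selection break by (smaller p, smaller position,
lexicographic id). Degenerate inputs are explicit: constant dosages are
flagged untestable and excluded from minima; constant phenotypes,
empty variant sets, rank-deficient covariates, single-variant RTC
intervals and identity GRMs raise errors rather than returning silently.
BED intervals are 0-based half-open on disk and converted to 1-based
inclusive internally; phenotype BED rows carry the TSS as (tss−1, tss).
All randomness flows through explicitly threaded numpy Generators; no
global RNG state is used anywhere.

## Known limitations

- Trans locus grouping is per gene; loci sharing SNPs across genes are
  reported separately, not merged.
- The moloc-style distinct-block correction is first-order beyond two
  blocks (negligible at the default priors, see above).
- Genotype PCs are not included as eQTL covariates by default (expression
  PCs only); pass them via `covariates` if population structure is a
  concern.
- The X chromosome receives no special dosage handling; the intended scope
  is autosomal.
- RTC interval boundaries are caller-defined; no recombination-hotspot map
  ships with the package.
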