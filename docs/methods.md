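# Methods

## Model

The unit of analysis is the inbred line. Replicated measurements (year ×
replicate) are averaged to one phenotype per line and trait before
modelling; with two years and two replicates this is the mean of four
points, which halves the year-to-year and residual noise entering the
genetic analysis. The genomic mixed model is

    y = 1μ + g + e,   g ~ N(0, A σ²g),   e ~ N(0, I σ²e),

with an intercept as the only fixed effect (no covariates are modelled)
and `A` the genomic relationship matrix of the lines.

### Genomic relationship matrix

For SNP i with counted-allele frequency `p_i` and dosage `x` (copies of the
counted allele, 0/1/2, concentrated on {0, 2} in fully inbred material),

    A_jk = (1/m_jk) Σ_i (x_ij − 2p_i)(x_ik − 2p_i) / (2 p_i (1 − p_i)),

summed over SNPs called in both lines (`m_jk` of them). Missing data are
handled pairwise-complete, which keeps `A` exactly symmetric without
imputation. SNPs with more than 2 % missing calls (configurable
`grm_missing_max`) are excluded at this stage — a stricter bar than the
5 % marker-QC threshold, mirroring the common practice of building the
relationship matrix only from the best-called markers. Monomorphic SNPs
are skipped, never divided by.

Two diagonal conventions are exposed. `yang` (the default) uses the
lower-noise self-relatedness estimator
`A_jj = 1 + (1/m) Σ_i [x² − (1+2p)x + 2p²] / (2p(1−p))`; `standard` applies
the cross-product formula to j = k so that with complete data `A = W Wᵀ/m`
holds exactly for the column-standardized dosage matrix `W`. The
`standard` form is what the ridge SNP-BLUP equivalence requires, so the
tests that exercise that identity use it; analysis defaults to `yang`.

### REML

Variance components maximize the restricted log-likelihood

    ℓR = −½ [(n−1) log 2π + log|V| + log|1ᵀV⁻¹1| + yᵀPy],
    V = A σ²g + I σ²e,   P = V⁻¹ − V⁻¹1(1ᵀV⁻¹1)⁻¹1ᵀV⁻¹.

A one-time eigendecomposition `A = U Λ Uᵀ` turns every evaluation of ℓR,
its gradient and the average-information matrix into O(n) diagonal
arithmetic. This makes the optimizer cheap and, just as importantly, makes
a brute-force validation affordable: the test suite checks the returned
optimum against a dense 50×50 likelihood grid evaluated with independent
dense linear algebra.

The optimizer runs 3 EM warm-up iterations, then AI (average-information)
updates. An AI step that leaves the feasible region or decreases ℓR is
step-halved; if no acceptable AI step exists, the iteration falls back to
EM. Components are floored at `1e-6 · Var(y)` so `V` stays invertible;
touching the floor is flagged in the result message. Convergence requires
`|Δℓ| < 1e-8` and a maximum relative parameter change `< 1e-6`;
non-convergence after 200 iterations returns `converged=False` with
diagnostics rather than raising. If `A` is numerically a multiple of the
identity only `σ²g + σ²e` is identified; the fit warns and returns the
equal-split solution on the exactly-maximized total variance. Standard
errors come from the inverse average-information matrix; `se(h²)` by the
delta method.

### Heritability scale

Heritability is reported as V(G)/V(P) with

    V(G) = σ̂²g · (tr A − 1ᵀA1/n) / (n − 1),

the expected sample variance of `g` under the fitted model. When the GRM
diagonal averages 1 this reduces to the familiar `σ²g/(σ²g+σ²e)`. The
distinction matters here: under the `2p(1−p)` standardization a fully
inbred panel has GRM diagonal ≈ 2, so the naive ratio would understate the
genetic fraction of variance roughly twofold. With the sample-variance
scale, simulated panels with target h² = 0.5 are recovered with mean bias
< 0.05 (n = 500, trait generated under the infinitesimal working model).
Under a sparse causal architecture (e.g. 100 causal SNPs among 2,000, with
linkage) the estimate shows the mild downward bias known for
relationship-based REML under model misspecification; this is a property
of the estimator, not of the implementation.

### BLUP and SNP-coefficient back-solving

Given fitted components, `μ̂ = (1ᵀV⁻¹1)⁻¹1ᵀV⁻¹y` and
`ĝ = σ̂²g A V⁻¹(y − 1μ̂)`; prediction-error variances follow the standard
mixed-model expressions. Per-SNP effects are obtained without refitting by

    û = (σ̂²g/m) Wᵀ V⁻¹ (y − 1μ̂),

with `m` the number of polymorphic SNPs (matching the GRM denominator) and
missing dosages imputed at their mean `2p_i` before standardizing. The
persistent model stores, per SNP: the scored allele, the dosage-scale
coefficient `b_i = û_i / sqrt(2p_i(1−p_i))`, and the training allele
frequency. With the `standard` GRM and complete data, scoring the training
lines reproduces `ĝ` exactly up to an additive constant (the centering
term `−Σ 2p_i b_i`), and `W û` equals the GBLUP values with ridge penalty
`λ = σ̂²e/σ̂²g`; both identities are asserted numerically at 1e-8.

### Scoring, cross-validation and inference

Scoring a panel with a coefficient model reconciles alleles by label:
coefficients whose scored allele matches the panel's other allele are
applied to `2 − dosage`; SNPs absent or with irreconcilable labels are
dropped with a warning (more than 50 % dropped is an error). Scores are
plain sums over SNPs; correlation-based evaluation is invariant to this
affine convention.

Cross-validation partitions the lines once into k folds (sizes differing
by at most one — 149 lines in 5 folds gives 30/30/30/30/29, so a 30-line
test fold trains on 119 lines) and the same partition serves all traits.
Every training-set quantity — allele frequencies, GRM, variance
components, SNP coefficients, and the frequencies used to impute missing
test dosages — is computed from the training lines only; a dedicated test
perturbs held-out phenotypes and asserts the trained model is bit-identical.
Accuracy per fold is the Pearson correlation between scores and observed
test-line means, with `tanh(atanh r ± z/√(n−3))` confidence intervals and
two-sided p-values from `t = r√(n−2)/√(1−r²)`. A trait is declared
significant when at least one fold beats the adjusted threshold (0.001,
i.e. roughly 0.05 Bonferroni-corrected for 35 fold-level tests, kept as a
fixed constant) and every fold beats the nominal 0.05. REML
non-convergence in a fold flags it and excludes it from the trait mean.

### Response to selection

On the breeding-value scale the response to selecting the k best lines is
`mean BV(selected) − mean BV(population)` — BVs are already genetic values,
so no heritability weighting applies. On the phenotype scale the breeder's
equation gives `R = (P_top − P_mean)·h²`, where the selected set is either
the top-k by estimated BV (genomic selection) or by observed line mean
(phenotypic selection); the top-k is taken per trait. Ties at the cutoff
resolve to the earlier line in sample order, deterministically.

## Synthetic panels

The generator emulates a variety-collection study: n inbred lines genotyped
at m array SNPs on c chromosomes, with T correlated traits measured in
`n_years × reps_per_year` cells. Defaults mirror the target design — 149
lines, 11,405 SNPs, 21 chromosomes, 7 element-content traits with means of
(4500, 450, 1200, 45, 40, 30, 5) mg/kg for K, Ca, Mg, Mn, Fe, Zn, Cu, four
measurements per line (596 phenotype rows per trait).

Genotypes: per-SNP allele frequencies are uniform on `[maf_low, maf_high]`
(default [0.01, 0.5], a post-QC spectrum). Within each chromosome a
first-order autoregressive latent Gaussian (adjacent correlation `ld_rho`,
default 0.6) is thresholded at the frequency quantile, giving haplotypes
whose dosage-scale linkage has a closed form checkable by Monte-Carlo
integration of the latent bivariate normal; the process restarts at
chromosome boundaries. Lines are fully inbred by default (dosages {0, 2});
a heterozygosity rate and a missingness rate are available for generality.

Traits: each trait has `n_causal` causal SNPs (default 100) with effects
i.i.d. `N(0, 1/n_causal)` on standardized genotypes — an infinitesimal-like
architecture matching the GBLUP working model. A fraction
`pleiotropy_frac` (default 0.3) of causal SNPs, with their effect sizes, is
shared across traits, inducing positive genetic correlation. True breeding
values are rescaled so Var(BV)/Var(line mean) hits the target h² (default
0.5, a mid-range value for grain mineral content) given the non-genetic
variance of the mean, `year_sd²/n_years + resid_sd²/(n_years·reps)`. Year
effects are drawn per (line, year) cell — not globally per year — so
averaging the four points reduces but does not remove non-genetic
variance, as in a real multi-year trial; defaults are 5 % (year) and 8 %
(residual) of the trait mean. At h² = 1 all noise terms are zero; at
h² = 0 the true BVs are exactly zero. Everything is deterministic given
the config seed, which is split into independent genotype and phenotype
streams.

### What the generator does not emulate

The simulated lines are mutually unrelated: there is no pedigree,
population structure, or family clustering (out of scope by design, along
with selection/drift dynamics, epistasis, and genotyping-error models
beyond random missingness). This has a visible consequence at the default
study scale: with ~11k markers and only 149 unrelated lines the effective
number of independent chromosome segments is in the thousands, so
cross-validated accuracies are low (~0.1) and REML heritability is barely
identified (se(h²) ≈ 0.4–0.6, with boundary estimates that the likelihood
grid confirms are genuine optima). Real variety panels are networks of
related material, where prediction largely rides on close relatives and
much higher accuracies are attainable at the same sample size. Passing
tests on synthetic panels therefore validate the estimator's algebra and
calibration, not the accuracy levels to expect on a structured panel.

## Problem sizes used in the test suite

Identity and oracle checks run on panels of 5–50 lines where brute-force
dense algebra is exact; parameter-recovery checks use 300–500 lines and
600–2,000 SNPs over 6–20 seeds; calibration checks use 2,000 Monte-Carlo
replicates at n = 30. The acceptance script runs the full default design
(149 × 11,405, 35 CV models). These sizes keep the whole suite in the
tens of seconds while leaving every statistical band comfortably
resolvable.

## Numerical choices

- GRM symmetry is enforced exactly (`(A + Aᵀ)/2` after vectorized
  accumulation); eigenvalues are clipped at zero before REML.
- Variance floor `1e-6·Var(y)`; AI steps halved up to 20 times; EM steps
  guarded against float-level likelihood decreases.
- Coefficient exports use `%.17g`, which round-trips float64 exactly, so
  a re-loaded score file reproduces in-memory scores bit-for-bit (the
  loader must read with round-trip float parsing, as
  `SNPEffectModel.from_tsv` does).
- QC repeats its three steps (marker missingness 5 % → MAF 1 % → sample
  missingness 5 %) until a fixed point, making the filter idempotent;
  counts are cumulative. MAF uses non-missing calls only.
- Text PLINK reading assigns the lexicographically smaller observed allele
  as the counted allele (deterministic); the binary dialect stores both
  alleles and round-trips any panel bit-exactly.
- k-fold assignment gives the first `n mod k` folds the extra line;
  partitions are uniform given the seed.
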