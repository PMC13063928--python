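# Methods

This note records the statistical models implemented in gardscan, the
defaults and why they were chosen, the numerical decisions, what the
synthetic cohorts do and do not emulate, and known limitations.

## Variant-to-gene assignment and QC

A variant belongs to a gene's marker set if it lies in the gene body
(1-based inclusive interval), within 500 bp of either end (promoter and
termination regions), or inside an enhancer interval linked to that
gene. Enhancer intervals of the same gene that overlap or are book-ended
(end + 1 = next start) are fused first; a variant may belong to several
genes (e.g. inside one gene's body and another's enhancer) and then
contributes to every such marker set. Flank boundaries are inclusive at
exactly 500 bp. BED inputs (0-based half-open) are converted to the
internal 1-based inclusive convention on read, so the flank arithmetic
has a single coordinate system.

Variant inclusion requires all of: missing rate < 10%; exact-test HWE
p > 10⁻⁴; relative heterozygote excess (H_obs − H_exp)/H_exp within
[−0.30, +0.20] (undefined for monomorphic variants, which pass this rule
by convention); and, for imputed variants, imputation r² ≥ 0.5,
Iam_HWE ≥ 0.5 and hiQ ≥ 0.5, with an absent field counting as a pass
(the latter two are consumed as supplied per-variant quality fields, not
computed). HWE and heterozygote excess are computed on hard calls
(dosages rounded half away from zero) over all samples, cases and
controls pooled. Survivors are LD-pruned: scanning left to right, for
any pair of common markers (both MAF > 0.01) at most 15,000 bp apart
with D′ > 0.8 (strict), the lower-MAF member is removed and takes no
part in later comparisons; the distance bound is exclusive above 15,000
and a D′ exactly at 0.8 keeps both.

D′ is estimated from unphased dosage pairs: hard-called two-locus
genotype tables feed an EM iteration for the four haplotype frequencies
(only the double heterozygote is phase-ambiguous; convergence when the
largest frequency change is < 10⁻⁸, at most 1000 iterations), then
D′ = |D|/D_max with the standard frequency-dependent bound. A
non-convergent pair is flagged and never pruned.

## Single-SNP models

Markers are tested log-additively by logistic regression (IRLS via the
binomial GLM), unadjusted and adjusted for sex, smoking (former/current
indicators against a never-smoker reference) and 4 ancestry PCs; a third
model adds standardized age and a marker×age product, whose Wald p is
the interaction p-value. Missing dosages are mean-imputed per variant
inside the fit only and never persisted. Effect sizes are reported as
OR = exp(β) with 95% CI exp(β ± 1.959964·se). Non-convergence and
(quasi-)separation produce flagged rows with no p-value rather than
errors; a constant dosage is inestimable and raises. Constant covariate
columns are dropped before fitting, so the adjusted model coincides
exactly with the unadjusted one when all covariates are constant.

A Rao score test of each marker at the covariate-only null — one null
fit shared by all markers — is the kernel reused by the gene-level
tests; it agrees with the Wald test to first order and costs one
matrix-vector product per marker.

## Gene-level aggregation tests

All six tests for a gene consume the identical post-QC marker set.

**Burden family.** Per-sample score s_i = Σ_j w_j·g̃_ij with: `add` —
w = 1 on raw dosage; `zeggini` — w = 1 on min(g, 1) (carrier
collapsing); `fp` — w_j = 1/√(p̂_j(1−p̂_j)) on raw dosage, p̂_j the
pooled MAF. The score is tested by the shared Rao kernel. An all-zero
burden is flagged, not an error.

**SKAT.** Q = r'GW²G'r with r the null-model residuals and W diagonal
Beta(1,25)-density weights of MAF (the reference default; configurable,
and the common-variant analyses in the tests use flat weights — see
below). The null is the mixture Σ λ_k χ²₁ with λ the eigenvalues of
Z₁'Z₁, Z₁ = V^{1/2}(I − X(X'VX)⁻¹X'V)GW, so no n×n projection matrix is
ever formed.

**Mixture tails.** P(Q > q) is computed by Imhof's
characteristic-function inversion, evaluated by a panel-marching
composite Simpson rule: panels track the fastest oscillation still
active, so large quantiles retire early and the slow tail is only walked
for small ones; eigenvalues are normalised to mean 1 (scale
equivariance) and eigenvalues carrying < 0.2% of the total mass are
dropped with their expected contribution subtracted from q (they stall
the integrand's decay while perturbing the distribution below working
accuracy). Truncation uses the exact oscillation envelope. Verified to
~10⁻⁹ against closed-form χ²_k cases. Below p ≈ 10⁻⁶ the inversion's
absolute accuracy is exhausted and the Liu–Tang–Zhang moment-matching
approximation is used instead; the fallback is recorded on the result.

**Small-sample correction.** The mixture null assumes Gaussian scores.
For a binary outcome at modest n the exact permutation distribution of
Q (phenotype permuted, covariate rows fixed) has the same shape family
but different first two moments; gardscan computes the exact permutation
mean and variance of Q = r'BB'r in closed form (pattern sums that reduce
to the m×m Gram matrix of the column-centred factor; validated against
exhaustive permutation enumeration at n = 7) and maps the observed Q
onto the asymptotic scale before inversion. Single-marker genes skip the
correction so that SKAT reduces exactly to the score test.

With strongly informative MAF weights and rare variants at small n, one
variant's weight can exceed another's by 10⁵ and Q degenerates to a
single discrete score whose permutation law no χ² mixture matches in the
distribution bulk; the correction narrows but cannot close that gap.
Oracle comparisons in the test suite therefore use common-MAF fixtures
with flat weights — the regime of common-variant marker sets, where
agreement with 100,000-draw permutation oracles is ~0.004 across the
whole p range.

**SKAT-O.** Q_ρ = (1−ρ)Q_SKAT + ρQ_burden over the grid
ρ ∈ {0, 0.01, 0.04, 0.09, 0.16, 0.25, 0.5, 1}; each Q_ρ receives the
permutation-moment correction (the combined form is r'(AL_ρ)(AL_ρ)'r
with L_ρ the Cholesky factor of (1−ρ)I + ρ11'), the per-ρ p-values come
from the mixture tails, and the overall p integrates the joint tail of
the minimum-p statistic over the shared χ²₁ factor (ρ = 1 is evaluated
at 0.9999 to avoid the degenerate mixing matrix; per-ρ quantiles at the
minimum p use moment-matched inversion; the κ-mixture CDF inside the
integrand is tabulated once by the vectorised Imhof pass and
interpolated monotonically). Safeguards clamp the result into
[min_ρ p_ρ, grid·min_ρ p_ρ]. Degenerate grids collapse to the pure
tests: {1} returns the unweighted additive burden result and {0} the
SKAT result; single-marker genes return the score test under either.

**Permutation set test.** Per-variant 1-df score χ² at the
covariate-only null; variants with per-variant p < 0.05 are selected in
decreasing χ² order, skipping any with squared dosage correlation > 0.5
to an already-selected variant, up to 5; the statistic is the mean χ² of
the selection (0 if empty). Phenotypes are permuted with covariate rows
fixed, the null refitted (batched IRLS across permutations; a closed-form
fast path when no covariates are present, where the fitted mean is the
permutation-invariant phenotype mean) and selection redone per
permutation. p = (1 + #{perm ≥ obs})/(n_perm + 1), so p = 0 is
impossible — required downstream by the logit transform. Permuted
phenotypes and their refitted nulls are cached once per battery run and
shared across genes.

## Calibration

logit_adjust clamps p to [ε, 1−ε] (ε = 10⁻¹⁵, so ties at p = 1 stay
ties), transforms z = ln(p/(1−p)), subtracts the median z, and maps
back. The median, not the mean, is the default centre: the motivating
pathology is a mass of p-values near 1, which would dominate a mean;
the mean is available behind a flag. The transform is strictly monotone,
so ranks — and everything rank-based downstream, including D⁺ — are
unchanged. Adjusted values are clamped back into [ε, 1−ε] after the
inverse transform: recentering can push an extreme logit past float
resolution at the ends of (0, 1), and at those saturated boundaries
distinct raw p-values may tie.

## Gene-set enrichment

Two-sample (set vs. non-set), one-sided toward small p: enrichment means
the member genes' p-values are stochastically smaller. The two-sample
form was chosen over one-sample-vs-uniform because the statistic is then
purely rank-based and robust to global miscalibration of the gene-level
p-values. D⁺ is evaluated at each distinct pooled value (ties handled by
stepping both CDFs after all tied observations). The p-value uses the
exact one-sided path-counting distribution whenever m·n ≤ 2×10⁶ — the
asymptotic tail exp(−2D⁺²mn/(m+n)) is measurably conservative for sets
of a few dozen genes (type-I ≈ 0.031 at a nominal 0.05 with 20-gene
sets), while the exact computation is calibrated (≈ 0.05) — with the
asymptotic formula beyond that size and a label-permutation p for sets
with fewer than 10 scored members; the formula alone remains available
via ``method="asymptotic"``. The leading edge is every member
gene at or before the smallest pooled value attaining the supremum (all
tied genes included; empty when D⁺ ≤ 0). Terms whose scored members
cover the whole background, or with fewer than 2 scored members or
2 background genes, are dropped from the catalog scan. Term-level
p-values are logit-calibrated across terms per gene-level test source
before classification against the significance scheme.

## Significance scheme

nominal = α; bonferroni = α/k (k tests actually run); suggestive =
1/k_tot; genome_wide = α/k_tot, with k_tot the assumed number of
independent tests genome-wide (defaulting to k when no genome-wide count
applies, as for gene-set catalogs). Suggestive expects one false
positive per scan, genome-wide α per scan. Threshold comparisons use ≤
(a p exactly at a threshold is significant). The QQ inflation factor
λ_GC divides the median observed χ²₁-equivalent by the exact χ²₁ median
(0.45494), so an exactly uniform grid gives λ = 1 to machine precision.

## Synthetic cohorts

The generator emulates the data structure the pipeline assumes, not a
population-genetic history:

* **LD** is a first-order copy chain: one allele frequency per block
  (drawn uniformly from maf_range), each haplotype allele copying its
  left neighbour with probability equal to the target D′. With equal
  within-block frequencies the expected pairwise D′ of adjacent markers
  equals the copy probability exactly; blocks are independent. This
  gives controllable pairwise LD for pruning and multi-marker tests but
  no realistic genealogy, recombination gradient or allele-frequency
  spectrum.
* **Phenotype**: logit P(case) = intercept + Σ_causal β·dosage +
  sex/smoking/PC terms (+ optional dosage×age_std interaction);
  case-control ascertainment by rejection sampling from the population
  model, under which the logistic covariate model remains valid
  (intercept aside). Unreachable case quotas abort with advice after a
  bounded number of rounds.
* **Covariates**: sex Bernoulli(0.5); age uniform on [40, 80]; smoking
  never/former/current at 0.4/0.3/0.3; two subpopulations with shifted
  allele frequencies feed PC1 when PC effects are nonzero, PCs 2–4 are
  noise.
* **Defaults** (the study conditions): 1000 cases, 1000 controls, 120
  SNPs in blocks of 5 at target D′ 0.8, MAF 0.05–0.40, 20 genes of 8 kb
  with 2 kb gaps and 500 bp flanks, Poisson(0.5) enhancers per gene
  placed in inter-genic gaps, 12 terms of 4–10 genes with 1 enriched
  term containing all 3 causal genes, per-allele causal log-OR ln(1.3),
  smoker effect 0.7 (former half), male 0.3, PC1 0.2, 30% of
  non-causal SNPs converted to noisy imputed dosages (clipped Gaussian
  noise, empirical r² recorded; Iam_HWE and hiQ drawn on [0.4, 1.0] so a
  realistic minority fails imputation QC), genotyped SNPs missing at up
  to 2%. Causal SNPs stay genotyped so the planted truth is not erased
  by imputation-quality filters at random.
* **Tests sizes.** Null-calibration suites use 1,000 replicates at
  n = 1,000–2,000; parameter recovery 200 cohorts of 4,000; oracle
  fixtures n = 200 with 100,000 permutations; enrichment power 50
  replicates at per-allele OR 1.5 with 600+600 samples. These sizes make
  Monte-Carlo error small against the tested tolerances while keeping
  the default suite fast.

What passing these tests shows: the statistics are correctly implemented
(oracle equivalence), calibrated under their own assumptions (type-I
bands), and able to recover planted effects of realistic size. What they
do not show: behaviour under cryptic relatedness, fine-scale population
structure beyond two subpopulations, genotyping batch effects,
non-logistic disease models, or the attrition profile of a real
58,836-SNP panel.

## Known limitations

* X-chromosome markers are treated as autosomal.
* The Fp and all-SNP-ADD burden forms follow the cited tools'
  published descriptions (frequency-inverse-variance weights; unweighted
  dosage burden); both weighting schemes are parameters, since the
  wrapped tools' internals admit variants.
* Deep mixture tails (p < 10⁻⁶) use moment matching rather than exact
  inversion and are flagged.
* The permutation set test with covariates permutes phenotype against
  fixed covariate rows; with strong covariate effects this is an
  approximate, not exact, null (the standard behaviour of the wrapped
  tool's design).
* The enhancer reader accepts any 4-column BED; upstream curation
  (tissue filters, gene–enhancer scores) is the user's responsibility.
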