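# Methods

## Model

Normalized expression is modeled as a low-rank tensor plus Gaussian noise:

Ω = Σ_{r=1..R} λ_r G_r ⊗ I_r ⊗ T_r + ε,  ε entries i.i.d. N(0, σ²),

with λ_r ≥ 0 and unit-norm factor vectors. Each rank-1 term is a
*module*: the eigen-gene G_r weights genes, the eigen-individual I_r
weights animals, and the eigen-tissue T_r — constrained to a single sign —
says in which tissues the module is active. The association model is the
standard animal model y = Xβ + u + e with var(u) = K σ²_a for a pedigree
(A) or genomic (G) relationship matrix and var(e) = I σ²_e.

## Decomposition

Each component solves min ‖Ω − λ G⊗I⊗T‖_F subject to unit norms by
alternating least squares: a factor update contracts the tensor against the
other two factors and renormalizes. The tissue contraction is thresholded
both to ≥ 0 and to ≤ 0 and the larger-norm variant is kept (ties →
nonnegative), which maximizes the captured singular value among the two
sign-feasible candidates; λ = ⟨Ω, G⊗I⊗T⟩ is then the norm of the kept
part, hence nonnegative. After convergence the (G, I) sign ambiguity is
fixed by making the largest-magnitude entry of I positive. A planted
tensor with T ≤ 0 equals one with (−G, I, −T), so either single-signed
representation may be returned; reconstruction is identical.

Successive components are extracted from the deflated residual
(residual ← residual − λ G⊗I⊗T). Because λ equals the inner product of the
residual with the fitted unit-norm rank-1 term, each deflation reduces the
squared Frobenius norm by exactly λ², so residual norms are non-increasing.
Deflation does not guarantee decreasing λ across components under the sign
constraint; a violation emits a warning, not an error.

Numerical choices: initialization from the leading singular vector of each
mode unfolding (deterministic; optional seeded random restarts),
convergence on relative λ change < 1e−8, max 500 sweeps, degenerate
(all-zero) contractions returned as λ = 0 components with a flag.

## Permutation null

Null tensors permute gene values independently within every
(individual, tissue) fiber, preserving each fiber's multiset and the
tensor's Frobenius norm exactly. Each null tensor is decomposed with the
same settings; for component index r the null eigen-gene loadings are
pooled across replicates and the top-gene cutoff c_r is their
(1 − α) quantile (linear interpolation between order statistics; α = 0.005
by default, i.e. the 99.5th percentile). Pooling across replicates rather
than taking per-replicate maxima was chosen as the empirical-distribution
reading; per-replicate maxima would give a family-wise-style, more
conservative cutoff.

## Module characterization and gene tests

Individual loadings are partitioned by sequential (Type I) ANOVA of
I_r ~ ADFI + contemporary group + gender, in that fixed order; proportions
are sequential sums of squares over the total. Order matters for
unbalanced designs and is documented as such. Categorical covariates use
treatment coding with the first sorted level as reference; constant
covariates are dropped with a warning (sex-segregated pens can make gender
constant).

Gene-level tests regress the T_r-projected expression
Ω(·,·,T_r) = Σ_k T_{r,k} Ω(·,·,k) on the same covariates and test the ADFI
coefficient two-sided against the exact t reference. The scan is
vectorized ordinary least squares; statsmodels serves as the independent
oracle in tests, never as the implementation. P-values are clamped to
[tiny, 1] so downstream −log₁₀ weights stay finite; no multiple-testing
correction is applied to the weights (a Benjamini–Hochberg column is
reporting-only).

## SNP weights and relationship matrices

Gene intervals are 1-based with both ends inclusive; a SNP in several
overlapping genes takes the maximum weight (strongest prior signal).
Intergenic SNP get weight 0, raised to a floor of 1e−5 only in the
all-SNP weighted variant. Selection keeps SNP with w strictly > t
(t ∈ {2, 5} by convention).

The genomic relationship matrix is VanRaden's method 1 with a diagonal
weight matrix: M holds 0/1/2 B-allele dosages centered by 2p̂ᵢ, M* = MD,
G = M*M*ᵀ / (2Σ pᵢ(1−pᵢ)). Allele frequencies come from the analyzed
genotypes; monomorphic SNP are excluded from numerator and denominator;
the denominator uses the SNP included in the variant at hand. The matrix
transpose convention is fixed by dimensional consistency with M as
animals × SNP. Pedigree relationships use Henderson's tabular method after
topological sorting, with cycle detection.

## REML, corrected heritability, back-solving

The restricted likelihood of (σ²_a, σ²_e) is profiled to one dimension on
the eigenbasis of K: with K normalized to mean diagonal 1 and
d_i = h²λ_i + (1 − h²), both β and the scale σ²_P have closed forms, and
h² is found by a 41-point grid plus bounded scalar refinement (the profile
can be multimodal near boundaries). h² is therefore a share of observed
phenotypic variance and invariant to rescaling K; σ²_a is reported on the
scale of the supplied K. Standard errors come from the expected
information of (σ²_a, σ²_e) with a delta-method SE for h²; estimates within
1e−4 of the h² ∈ {0, 1} boundary are flagged.

Weighted G changes the variance scale and structure, inflating additive
variance estimates; following the method's correction, weighted fits
report h²_w = (Var(P_u) − Var(E_w)) / Var(P_u), the unweighted reference
phenotypic variance minus the weighted residual variance over the
reference phenotypic variance. Values outside [0, 1] are returned with a
warning, never clipped, and the raw REML h² is always reported alongside.
The reported SE is the raw REML SE (the correction's sampling error is not
propagated) and is flagged as such a caveat.

Animal effects are predicted by BLUP, û = σ²_a K V⁻¹(y − Xβ̂), and SNP
effects back-solved as â = M*ᵀ[M*M*ᵀ]⁻û with a Moore–Penrose
pseudo-inverse (relative cutoff 1e−10), so M*â is the projection of û onto
the row space of M*. Z-scores standardize â by its sample mean and SD; the
significance rule |Z| ≥ 4 is configurable and recorded in output metadata,
as no canonical threshold exists for back-solved effects.

## Phenotype QC

Event bounds are strict inequalities exactly as specified (boundary values
removed); the consumption rate is recomputed from amount and duration
rather than trusting a recorded rate. Pen × day screening reports the
aberrant-event count, total dispensed feed and event count per cell with
config-driven cutoffs (the statistics are standard; their cutoffs are
facility-specific). Adjusted test intake replaces a random-regression
mixed-model projection with a deliberately simple two-step adjustment:
fixed effects (gender, group-pen) are removed as record-weighted
deviations — preserving totals under balance — and missing days are imputed
from a per-animal polynomial in day on test (degree 3 by default, capped
at n_days − 1). This reproduces the properties downstream stages rely on
(complete-data totals unchanged, constant trajectories imputed exactly,
fixed-effect contrasts removed) without modeling animal-specific
random-regression covariance.

## Synthetic data

Generators are pure functions of (config, seed). The expression generator
plants single-signed rank-1 modules in Gaussian noise per the model above;
one module's eigen-individual can be linearly tied to a generated ADFI
covariate so recovery is scoreable end to end. Genotypes are
Hardy–Weinberg Binomial(2, p) draws with p uniform on the MAF range, laid
on synthetic chromosomes with a configurable genic fraction; phenotypes
draw u with covariance K σ²_a at a chosen heritability; feeder events
contain a labeled aberrant fraction violating exactly one rule each.

Two presets: `small` (60 × 12 × 3 tensor, 80 animals, 60 SNP) for fast
tests, and `study` (2000 genes × 30 individuals × 4 tissues, 3 planted
modules, 500 animals, 2000 SNP) shaped like the motivating experiment.
The power scenario uses 500 animals × 400 SNP with 10 causal and 90 decoy
genic SNP given informative P-values (weights > 5), chosen so that
chance alone would place a causal SNP in the top 5 |Z| far less often than
the informative-weight analysis does. What the generators do *not*
emulate: linkage disequilibrium, pedigree–genotype co-inheritance,
count-level overdispersion (a Poisson count mode exists for normalization
tests only), and selection structure in the covariates — so passing tests
demonstrate correctness of the machinery and the qualitative behavior of
the weighting, not field performance on real populations.

## Problem sizes and limitations

The test suite and acceptance script run at reduced scale: REML
calibration uses n = 500 animals with 50 replicates per heritability,
module recovery uses exact low-rank tensors plus the small preset, and the
power property uses 20 replicates of the 500 × 400 scenario. The bundled
study summary tables are inputs for arithmetic checks, not recomputed from
raw sequence data. Known limitations: heritability from a founders-only
pedigree (A = I) is unidentifiable and its reference row is reported for
layout completeness only; sequential ANOVA proportions depend on covariate
order; the corrected-heritability SE is approximate; and empty SNP
selections at a high threshold yield degenerate (NaN) summary rows rather
than aborting the run.
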