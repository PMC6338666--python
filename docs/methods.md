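# Methods

## Model

All four association tests are single-random-effect linear mixed models

    Y = Z θ + g + ε,    g ~ N(0, A σ²_g),    ε ~ N(0, I σ²_e),

where Z stacks the covariates W (always including an intercept) with the
variant term(s) of the model in question.  A is the additive genetic
relatedness matrix; σ²_g captures the polygenic background that is
substantial in any pedigree-based sample, and failing to model it inflates
test statistics among relatives.

The variant encodings come from phased genotypes with known parental origin:
X_M, X_P ∈ {0, 1} are the maternal and paternal haploid counts of the effect
allele, X_PM = X_M + X_P ∈ {0, 1, 2}, and d = (X_M − X_P)/2 ∈ {−0.5, 0, +0.5}.
Only heterozygotes with assigned parental origin have d ≠ 0; homozygotes carry
no parent-of-origin information.  The differential model

    Y = Wα + d·(β_M − β_P) + X_PM·(β_M + β_P)/2 + g + ε

is an exact linear reparameterisation of the joint model with X_M and X_P as
separate predictors: the d coefficient equals β_M − β_P with identical
standard error, p-value and likelihood.  This identity is asserted to 1e-8 in
the acceptance suite.  Note the ±0.5 coding of d: it is the unique scaling
under which the reparameterisation is exact; a ±1 coding would halve the
reported coefficient without changing the p-value.

## Estimation

A is eigendecomposed once per missingness pattern, A = U·diag(s)·Uᵀ
(eigenvalues clipped at zero).  In the rotated frame the error covariance is
diagonal, σ²_e·(λsᵢ + 1) with λ = σ²_g/σ²_e, so:

* λ is estimated by maximising the profile restricted likelihood over a
  60-point log grid on [1e−5, 1e5] followed by bounded scalar refinement to
  relative tolerance 1e-6; σ²_e and θ profile out in closed form.  An optimum
  at the grid edge is flagged (`at_boundary`).  The REML criterion includes
  the +½·log|ZᵀZ| constant so it is invariant to linear reparameterisation of
  the fixed effects — without this term the differential and joint
  parameterisations would report different "restricted likelihoods" for the
  same model.
* Fixed effects are weighted least squares at λ̂; standard errors use
  σ̂²_e = RSS_w/(n − c); p-values are two-sided t on n − c degrees of
  freedom.  Weights (λsᵢ + 1) are floored at 1e-10 before inversion.

By default λ is re-estimated per variant under the alternative model; an
approximate mode (`lambda_strategy="once"`) estimates λ once per phenotype
under the covariates-only model and reuses it, trading a small loss of
accuracy for speed on very large scans.  A likelihood-ratio variant of the
differential test (`run_differential_lrt`) is provided using full-ML
likelihoods (restricted likelihoods are not comparable across fixed-effect
designs); the Wald test is the default.

Per-variant analysis is complete-case: a sample missing either parental call
is dropped for that variant in all four models, so the models see comparable
samples.  MAF and call-rate QC (defaults: MAF > 1%, call rate > 85%, both
strict) are computed once over all loaded samples, with MAF checked first
when attributing failures.  Each result row carries its own analysed n.

Relatedness can come from the pedigree (recursive tabular method, A = 2Φ;
half-founders are treated as having an unrelated unknown parent) or from
genotypes (centered cross-product GRM with per-variant mean imputation of
missing calls).  A Monte-Carlo gene-dropping IBD estimator provides an
independent cross-check of the recursion and is used in validation.

## POE classification and thresholds

A variant is called `maternal_only` when p_maternal < α, p_paternal ≥ α and
p_standard ≥ α, all at the same genome-wide α (default 5×10⁻⁸, strict
inequality); `paternal_only` symmetrically.  A `differential` call
(p of β_M − β_P below α) is reported separately and may co-occur.  No LD
clumping is attempted; a greedy 1 Mb top-hit reporter is provided for
convenience only.  Multiple phenotypes are independent runs with no
cross-phenotype adjustment.

The cis-eQTL mode selects genes whose TSS is within a closed 1 Mb window of
the query SNP (SNP-to-TSS distance, strand-agnostic) and applies the same
scans with each gene's normalised expression vector as the trait; the
Bonferroni threshold is family_alpha divided by the exact number of
(SNP, gene) pairs tested.  Expression preprocessing (detection filtering,
normalisation, technical-covariate removal) is upstream of this package,
except for a convenience CPM detection filter.

The inverse-normal transform uses Blom offsets, z = Φ⁻¹((r − 0.375)/(n + 0.25)),
with average ranks for ties and NaN passthrough; the offset is configurable
since rank-transform conventions vary across studies.  Covariates enter the
mixed model as fixed effects in the primary mode; pre-residualising the trait
on covariates and transforming the residuals reproduces the common
replication-cohort recipe and is approximate relative to joint fitting.

## Synthetic data

The generator emulates a founder-population design: `n_founders` unrelated
individuals, then non-overlapping generations formed by random
within-generation mating (parent-offspring and full-sib matings disallowed),
with `round(n_couples × mean_offspring)` children per generation —
`mean_offspring = 2` keeps generation sizes constant (sizes can fall slightly
short when sib-avoidance leaves individuals unpaired).  Genotypes are
gene-dropped: founders draw two independent Bernoulli(p) alleles with p
uniform on `maf_range` (default 0.05–0.5), and each meiosis transmits one
uniformly chosen parental allele, with the maternal/paternal labels known by
construction.  Variants are independent — there is no linkage disequilibrium,
recombination map, genotyping error, or structured missingness (the
`missing_po_rate` mask is i.i.d. per sample × variant).  Consequently the
tests exercised here validate single-SNP inference and classification, not
LD-aware locus reporting or the behaviour of real phasing pipelines whose
missingness tracks IBD coverage.

Phenotypes follow the generative model exactly: Y = Wα + Σ(X_M β_M + X_P β_P)
+ g + ε with g drawn through the Cholesky factor of A·σ²_g.  Every dataset
retains its ground truth (effects, g, ε, covariate coefficients) for recovery
assertions.  Planted causal variants default to allele frequency 0.3 — a
common variant comfortably above QC cutoffs — and the parameter-recovery
scenario uses σ²_g = 0.4, σ²_e = 0.6 (narrow-sense h² ≈ 0.4); opposite-effect
and null-calibration scenarios use σ²_g = σ²_e = 0.5.

## Validation problem sizes

The acceptance suite uses pedigrees of ~500 (4 generations × 125 founders),
~600 (3 × 200) and ~1000 (4 × 250) individuals; 200 variants for the
reparameterisation identity, 2000 null variants for calibration, 50 replicates
for opposite-effect detectability, 100 replicates for recovery/classification,
and 10⁵ gene-dropping replicates for the relatedness check.  Dense
brute-force oracles (explicit V = λA + I inversion and likelihood grids) are
evaluated on n ≤ 12 instances.

## Numerical notes and edge cases

* Degenerate designs are skipped per variant with a logged reason: fewer than
  10 analysed samples, monomorphic tested regressor, no parent-of-origin
  informative heterozygotes (d ≡ 0), or rank deficiency.  When X_PM is
  constant on the analysed subset of the differential model it is absorbed by
  the intercept and dropped.
* Relatedness matrices are validated on construction: symmetry to 1e-10,
  eigenvalues ≥ −1e-8 after symmetrisation, pedigree diagonals ≥ 1.
* Wald p-values are floored away from exact 0 only by float underflow; ties
  in rank transforms get average ranks; p = α exactly is *not* significant.
* Unphased (`/`), half-missing and missing genotypes all count as
  parental-origin-missing; phased VCF haplotype order has no community
  standard, so the maternal-first/paternal-first convention is an explicit
  argument, echoed to the log, and recorded in written VCF headers.

## Known limitations

Single random effect only (no multiple variance components, no sparse-matrix
shortcuts for n ≫ 10⁴); per-variant complete-case analysis re-eigendecomposes
A per distinct missingness pattern, which is slow when missingness is dense
and unstructured; binary traits, haplotype/multi-SNP models and X-chromosome
analyses are out of scope; multi-allelic sites are skipped.
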