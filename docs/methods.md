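# Methods

## Kinship

Kinship coefficients Φ are computed by the standard recursion over a
topological order of the parent graph (founders unrelated, Φ_ii =
½(1+Φ_father,mother), Φ_ij = ½(Φ_fi,j + Φ_mi,j)).  The *kinship* matrix
(self = ½) is stored, never the relationship matrix 2Φ: both mixed
models use `σ²·K` literally, so the simulator and the fitters share one
convention and no factor of 2 appears anywhere in model code.  Inbred
pedigrees are supported (diagonal > ½).  Kinship is computed on the full
pedigree and then restricted to the analysed individuals; for expected
kinship the order of subsetting is immaterial, but ancestors always
contribute.  Individuals referenced only as parents are an error by
default; a flag promotes them to founders with a warning, since real
pedigree files are often incomplete.

## Genotype QC

Three rules, in order: (1) any missing genotype removes the SNP (a
missingness-fraction threshold generalises this, default 0); (2)
monomorphic SNPs are removed; (3) a SNP with exactly two observed
genotype classes is removed when the rarer class frequency is below 5%.
A SNP with three observed classes is *not* removed however rare its
minor homozygote; a conventional MAF filter exists but is off by
default.  Dosages always count the minor allele as observed in the data.
Coordinates are 1-based inclusive internally; BED input is converted on
read.

## Phenotype preprocessing

* **Transform**: y = log(log(x)), natural logs (the base is
  configurable; ln∘ln is the default since nothing in the design forces
  a base).  Defined only for raw values > 1; nonpositive raw values are
  rejected at read time.
* **Imputation**: missing transformed values are filled per trait-visit
  column under the no-SNP polygenic null model with Var(y) =
  σ²(h²·2K + (1−h²)I), conditioning each missing cell on the observed
  cells of its column (Schur complement).  The heritability h² is a
  visible constant (default 0.5), not an estimate: imputation at a fixed
  assumed heritability is part of the procedure, and because the
  constant is not derivable from the data it is exposed as a parameter
  rather than buried.  2K (unit diagonal for outbred individuals) is
  used inside the imputation covariance so that h² really is the
  heritability of the column; the mixed models themselves still consume
  K unscaled.  Imputation is marginal per column, the simplest reading
  of a constant-heritability null model; joint imputation across the
  eight columns is a possible extension, not silently added.
* **Response**: Y = mean(post-treatment visits) − mean(pre-treatment
  visits) of transformed TG, so negative Y means the drug lowered TG.
  If exactly one visit of a pre (post) pair is missing it is imputed
  with the other visit of that pair; individuals missing both pre or
  both post visits are excluded and reported.

## Bivariate longitudinal model

Ordering is fixed throughout as (trait, visit) ⊗ individual with the
individual index fastest.  The covariance is Var(y) = C1⊗I + C2⊗K with
C1 the 8×8 environmental block (per-trait Markov-product temporal
correlation, common variance per trait across visits, cross-trait block
ρ_ε S₁^½S₂^½ with *symmetric* matrix square roots — a Cholesky root
would break the symmetry of the assembled block) and C2 = Σ_u⊗J₄ (the
polygenic effect of a trait is constant over visits).  Whitening the
cross-trait block shows C1 is positive definite for every |ρ_ε| < 1, and
C2 is PSD, so validity holds on the whole interior of the parameter
space; the fitter still guards each 8×8 block numerically and rejects a
proposal whose Cholesky fails.

**Fitting** maximises the full likelihood (ML, not REML): the LRT
compares models differing in fixed effects, where restricted likelihoods
are not comparable.  The 12 variance parameters are optimised by
L-BFGS-B on an unconstrained scale (log variances, atanh correlations)
with numerical gradients; fixed effects are profiled out at every
proposal by GLS.  Rotating individuals onto the eigenbasis of K (done
once per dataset and cached) decomposes every likelihood evaluation into
n independent 8×8 blocks C1 + λᵢC2; a compiled kernel (numba, with a
numpy fallback checked against it in the tests) accumulates the
log-determinants, quadratic forms and design cross-products in one pass.
Restarts are deterministic — moment-based, shrunk, inflated — so scans
are seed-free and reproducible; per-SNP alternative fits warm-start at
the null variance components.  Convergence: relative log-likelihood
change < 1e-8, cap 500 iterations.

**Testing**: LRT statistic 2(ℓ_alt − ℓ_null) against χ² with 2 df (the
SNP enters both traits).  Whether variance components should be refit
per SNP is genuinely open; both modes exist, `full_refit` (default, the
literal LRT) and `fixed_vc` (null components held fixed, labeled a fast
approximation in the output).  Covariates are *not* in the longitudinal
design by default — the design of record holds only visit means and the
SNP — but can be appended per trait by flag.

## Treatment-response model

Y = Xβ + Zu + ε with u ~ N(0, σ²_g K), ε ~ N(0, σ²_e R).  Defaults:
Z = I on individuals (the family random effect is carried entirely by
Var(u) = σ²_g K, which is what the model display fixes; an explicit
family-indicator Z can be supplied), and R = I.  A non-diagonal R is
supported (user matrix or within-family exchangeable with fixed ρ) but
identity is the default because family covariance already enters through
ZKZ′ and an unstructured non-diagonal R on top is not identifiable from
one response per individual.

**EM-REML**: the classical update
σ²_c ← σ²_c + σ⁴_c(y′P V_c P y − tr(P V_c))/m_c (m_g = r random-effect
levels, m_e = n), a genuine EM step, so the restricted likelihood is
nondecreasing — asserted in the tests at every iteration.  Whitening by
chol(R) and eigendecomposing the whitened ZKZ′ once per dataset makes
each step O(nq²), so per-SNP refits across a genome scan are cheap.
Convergence: max relative component change < 1e-6, cap 1000 iterations
(`em_reml`); the scan wrappers use a variance-scaled starting value
(s²_y/2 for each component) and a cap of 5000, since EM's geometric
convergence rate degrades on small, weakly identified samples.
Components collapsing below 1e-12 are pinned there with a warning.

**F-test**: F = (Mβ̂)′[M(X′V̂⁻¹X)⁻¹M′]⁻¹(Mβ̂)/p with V̂ the fitted
covariance of Y, referred to F(p, n−q) with q = ncol(X) — the literal
denominator df, with no Satterthwaite/Kenward-Roger adjustment; for
small n this is anti-conservative and the tests therefore check
calibration empirically at n = 300.  Var(β̂) is (X′V̂⁻¹X)⁻¹ — the
inverse, as the quadratic form itself requires.  Single-SNP scans use
p = 1 (equivalently a squared Wald ratio); region tests put all pruned
SNP dosages in X and test their coefficients jointly, dropping
collinear columns with a warning first.

## Regions and LD pruning

One genic region per annotated gene and one intergenic region per
positive gap between consecutive genes (by sorted position; overlapping
genes stay distinct unless merged by flag); regions without genotyped
SNPs are dropped, and a SNP inside overlapping regions belongs to each.
SNPs before the first or after the last gene of a chromosome fall in
terminal regions labeled `intergenic_telomeric`, emitted by default so
that every SNP belongs to at least one region.  Pruning is greedy
left-to-right by position: keep a SNP iff its squared dosage correlation
with every kept SNP is ≤ 0.5 (strictly-greater removes, so a pair at
exactly the threshold survives).  r² is computed on dosages (composite
LD), appropriate for unphased family genotypes; keep-first-by-position
is the tie-break (a MAF-priority ordering is available).  Strand is
ignored; regions are pure intervals.

## Synthetic data

The generator draws from exactly the two models above, so every fitted
quantity has a known truth.  Pedigrees are nuclear (2 founders +
k children) or three-generation (10 members, yielding first cousins);
genotypes are gene-dropped from founders in Hardy-Weinberg proportions
at per-SNP MAFs (default U(0.1, 0.5)); longitudinal phenotypes are
sampled from C1⊗I + C2⊗K and exported on the raw scale via exp(exp(y))
so the whole transform–impute–fit pipeline is exercised; the response is
sampled from the Henderson model with age ~ U{20..70}, smoking ~
Bernoulli(0.3).  One root seed feeds fixed, named substreams so each
component regenerates independently.

Default generating values: transformed-scale total variance 0.25 per
trait (σ²_u = 0.10/0.075, σ²_e = 0.15/0.175 for TG/HDL), ρ_g = −0.3,
ρ_ε = −0.2 (TG and HDL covary negatively), temporal correlations
(0.6, 0.5, 0.4) and (0.5, 0.4, 0.3); response components
(σ²_g, σ²_e) = (1.0, 0.5).  The transformed variance is kept larger than
real lipid data would show so that optimisation is exercised away from
degeneracy; consequently raw-scale exports span a wider range than real
TG/HDL panels.  The world has no LD between SNPs, no ascertainment and
no genotyping error — a green simulation test establishes correctness of
the estimators under the stated model, not robustness to those
features.

## Multiple testing and reporting

BH step-up within each analysis family (longitudinal scan, response
scan, region scan) separately; m counts successfully tested units, and
failed fits propagate as missing without entering the correction.  Top
tables rank by raw p with (chromosome, position) tie-break; the
Manhattan output is a plot-ready table (cumulative genome coordinate,
−log₁₀ p, alternating colour index), the data being the contract and any
image cosmetic.

## Known limitations

* Exactly four visits, two traits; the Markov temporal structure is
  hard-coded to that design.
* Single imputation only; imputation uncertainty is not propagated.
* No score tests, no random SNP slopes, no gene–time interactions; no
  Satterthwaite df; at most two variance components in the response
  model.
* Numerical gradients in the longitudinal fitter: fits are
  deterministic, but pathological starting values can stop at local
  optima — mitigated by the three fixed restarts and checked against a
  dense-likelihood optimiser in the tests.
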