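# famgwas

Family-based genome-wide association for longitudinal lipid traits and
lipid-lowering treatment response.

## The problem

Family studies of drug response — the motivating design measures
triglycerides (TG) and HDL cholesterol at four clinic visits, two before
and two after fenofibrate treatment — pose two linked statistical
problems:

1. **Which SNPs are associated with the lipid traits themselves?**
   Using both traits at all visits in one model exploits the temporal
   and cross-trait correlation instead of discarding it.
2. **Which SNPs or genomic regions are associated with the *response* to
   treatment** (the pre-to-post change in transformed TG)?

Both analyses must respect relatedness: phenotypes of family members are
correlated through shared polygenic background, quantified by the
pedigree kinship matrix **K** (Φ, self-kinship ½).

## The models

**Bivariate longitudinal model.** With
y = (y_TG', y_HDL')' the 8n-vector of two traits × four visits on n
individuals,

    y = X β + Z u + ε,
    Var(y) = Z (Σ_u ⊗ K) Z' + Σ_ε ⊗ I_n

where Σ_u is the 2×2 polygenic covariance of the traits (variances
σ²_u,TG, σ²_u,HDL, genetic correlation ρ_g) and Σ_ε is the 8×8
environmental block: per-trait temporal correlation is Markov-product —
corr(visit i, visit j) = ∏ adjacent-lag ρ's — and the cross-trait block
is ρ_ε Σ_TG^½ Σ_HDL^½.  Fixed effects are four visit means per trait
plus one SNP effect per trait.  Each SNP is tested by a likelihood-ratio
test with 2 df (the SNP enters both traits); fitting uses maximum
likelihood over the 12 variance parameters with fixed effects profiled
out by GLS, made fast by rotating the individual axis onto the
eigenbasis of K (n independent 8×8 blocks).

**Treatment-response model.**  With Y the per-individual change in
log(log TG) from pre- to post-treatment visit means,

    Y = X β + Z u + ε,   u ~ N(0, σ²_g K),   ε ~ N(0, σ²_e R),

X holding intercept, age, smoking and either one SNP or the LD-pruned
SNPs of a genomic region.  Variance components are estimated by EM-REML,
fixed effects and BLUPs solve Henderson's mixed-model equations, and
H₀: Mβ = 0 is tested with

    F = (Mβ̂)' [M (X'V̂⁻¹X)⁻¹ M']⁻¹ (Mβ̂) / rank(M)  ~  F(p, n − q).

Regions are the genic intervals and the intergenic gaps between
consecutive genes that contain genotyped SNPs; within a region SNPs with
dosage r² > 0.5 are greedily pruned before the joint test.  All scans
are BH-corrected.

## Worked example

```bash
famgwas simulate --n-families 60 --m-snps 40 --seed 1 --out demo/
famgwas gwas-longitudinal --pedigree demo/pedigree.fam \
    --vcf demo/genotypes.vcf --phenotypes demo/phenotypes.tsv \
    --mode full_refit --out demo/longitudinal.tsv
```

The same pipeline through the library, with a SNP effect of 0.25 planted
on both traits at `snp0003` (this is the run `scripts/acceptance.py`
performs; output abridged):

```
simulated 240 individuals in 60 families, 40 SNPs (seed 1)
QC kept 40/40 SNPs
longitudinal LRT scan: top SNPs
 snp_id       lrt            p         p_bh
snp0003 61.958456 3.514733e-14 1.405893e-12
snp0024  9.663655 7.971937e-03 1.358561e-01
snp0005  9.172852 1.018921e-02 1.358561e-01
```

The planted SNP tops the scan: its LRT statistic of 62.0 on 2 df gives
p ≈ 3.5×10⁻¹⁴, far below the others, and survives BH correction while
every null SNP does not.  The response F-test scan and the region tests
in the same script behave analogously for an effect planted on the
response phenotype.

## What `scripts/acceptance.py` does

`python scripts/acceptance.py --seed <int> --out <path>` regenerates a
seeded synthetic study and runs every stage of the package end to end —
kinship, QC, transform, imputation, response construction, both
genome-wide scans, region construction with LD pruning, and BH
correction — printing the intermediate tables, and writes its JSON
summary to `--out`.  Statistical correctness itself (oracle
equivalences, type-I calibration, parameter recovery, power
monotonicity) is asserted by the test suite, in particular
`tests/test_acceptance.py`.

See `docs/methods.md` for modelling details, defaults and limitations.
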