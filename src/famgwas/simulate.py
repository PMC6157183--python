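"""Synthetic family data drawn exactly from the package's two models.

The generator stands in for a lipid-lowering pharmacogenetics family
study: multigenerational pedigrees, Mendelian genotypes gene-dropped
from founders in Hardy-Weinberg proportions, TG/HDL measured at four
visits around a treatment, and a treatment-response phenotype.  The
longitudinal phenotypes are sampled from the exact structured normal
model (Markov temporal correlation, genetic and environmental
cross-trait correlation spread over the kinship matrix) and exported on
the raw scale via ``exp(exp(y))`` so the full transform-impute-fit
pipeline can be exercised end to end; the response phenotype is sampled
from the Henderson model ``Y = X beta + u + eps``.

Default variance components put total variance 0.25 per trait on the
transformed scale (heritability 0.4 for TG, 0.3 for HDL), negative
TG-HDL coupling, and decaying visit-to-visit correlation; the response
truth uses (sigma2_g, sigma2_e) = (1.0, 0.5).  What this world does not
emulate: linkage disequilibrium between simulated SNPs, ascertainment,
genotyping error, and tight raw-scale lipid ranges (the transformed
variance is kept larger than real lipid data would show so that fitting
behaviour is exercised well away from degeneracy; raw-scale exports are
correspondingly wide).

All samplers are reproducible: one root seed, with fixed per-component
substreams so each piece can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covstruct import BivarVarComponents, MarkovCorrParams
from .dataio import PHENO_COLUMNS, GenotypeMatrix
from .pedkin import Individual, KinshipMatrix, Pedigree, Sex, compute_kinship
from .preprocess import loglog_inverse

__all__ = [
    "SimConfig",
    "ResponseTruth",
    "DEFAULT_VC_TRUTH",
    "DEFAULT_VISIT_MEANS",
    "sim_pedigree",
    "sim_genotypes",
    "sim_longitudinal",
    "sim_response",
]

DEFAULT_VC_TRUTH = BivarVarComponents(
    sigma2_u_t1=0.10,
    sigma2_u_t2=0.075,
    rho_g=-0.3,
    sigma2_e_t1=0.15,
    sigma2_e_t2=0.175,
    markov_t1=MarkovCorrParams(0.6, 0.5, 0.4),
    markov_t2=MarkovCorrParams(0.5, 0.4, 0.3),
    rho_eps=-0.2,
)

# visit means on the transformed scale: TG around 120 mg/dL falling after
# treatment, HDL around 50 mg/dL nudged up
DEFAULT_VISIT_MEANS = {
    "tg": (1.57, 1.57, 1.50, 1.50),
    "hdl": (1.36, 1.36, 1.37, 1.37),
}


@dataclass(frozen=True)
class ResponseTruth:
    """Generating values of the response model (intercept, age, smoking)."""

    beta: tuple[float, float, float] = (-0.1, 0.001, 0.05)
    snp_effects: dict = field(default_factory=dict)  # snp_id -> beta
    sigma2_g: float = 1.0
    sigma2_e: float = 0.5


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 100
    family_design: str = "nuclear"  # nuclear | three_generation
    k_children: int = 2
    m_snps: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    vc_truth: BivarVarComponents = DEFAULT_VC_TRUTH
    response_truth: ResponseTruth = ResponseTruth()
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")
        if self.family_design not in {"nuclear", "three_generation"}:
            raise ValueError(f"unknown family design {self.family_design!r}")
        self.vc_truth.validate()


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Substream generator: stable across runs and platforms."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed) % 2**31, zlib.crc32(stream.encode())])
    )


# ---------------------------------------------------------------------------
# pedigree


def sim_pedigree(cfg: SimConfig) -> Pedigree:
    """Deterministic pedigree of the requested family design.

    ``nuclear``: two founder parents and ``k_children`` offspring per
    family.  ``three_generation``: two grandparents, two of their
    children married into founder spouses, two grandchildren per couple
    (10 members; grandchildren of different couples are first cousins).
    """
    recs: list[Individual] = []
    for f in range(cfg.n_families):
        fam = f"F{f:04d}"
        if cfg.family_design == "nuclear":
            pa, ma = f"{fam}_pa", f"{fam}_ma"
            recs.append(Individual(pa, "", "", Sex.male, fam))
            recs.append(Individual(ma, "", "", Sex.female, fam))
            for c in range(cfg.k_children):
                recs.append(
                    Individual(f"{fam}_c{c + 1}", pa, ma,
                               Sex.male if c % 2 == 0 else Sex.female, fam)
                )
        else:
            gp, gm = f"{fam}_gpa", f"{fam}_gma"
            recs.append(Individual(gp, "", "", Sex.male, fam))
            recs.append(Individual(gm, "", "", Sex.female, fam))
            for b in (1, 2):
                child = f"{fam}_p{b}"
                spouse = f"{fam}_s{b}"
                child_sex = Sex.male if b == 1 else Sex.female
                spouse_sex = Sex.female if b == 1 else Sex.male
                recs.append(Individual(child, gp, gm, child_sex, fam))
                recs.append(Individual(spouse, "", "", spouse_sex, fam))
                fa, mo = (child, spouse) if child_sex is Sex.male else (spouse, child)
                for c in (1, 2):
                    recs.append(
                        Individual(f"{fam}_g{b}{c}", fa, mo,
                                   Sex.male if c == 1 else Sex.female, fam)
                    )
    return Pedigree(recs)


# ---------------------------------------------------------------------------
# genotypes


def sim_genotypes(ped: Pedigree, cfg: SimConfig) -> GenotypeMatrix:
    """Mendelian gene-dropping at per-SNP MAFs drawn from ``maf_range``.

    Founder alleles are independent Bernoulli(MAF); each non-founder
    inherits one uniformly chosen allele from each parent.  Dosages
    count the designated minor allele (the one at frequency MAF among
    founders).
    """
    rng = _rng(cfg.seed, "genotypes")
    m = cfg.m_snps
    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    order = ped._toposort()
    pos = {iid: k for k, iid in enumerate(order)}
    n = len(order)
    alleles = np.zeros((n, m, 2), dtype=np.int8)
    for iid in order:
        k = pos[iid]
        rec = ped.record(iid)
        for slot, parent in enumerate((rec.father, rec.mother)):
            if parent == "":
                alleles[k, :, slot] = rng.random(m) < mafs
            else:
                pick = rng.integers(0, 2, size=m)
                alleles[k, :, slot] = alleles[pos[parent], np.arange(m), pick]
    dosage_by_order = alleles.sum(axis=2).astype(float)
    idx = np.array([pos[iid] for iid in ped.ids])
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j:04d}" for j in range(m)],
            "chrom": "1",
            "bp": [10_000 * (j + 1) for j in range(m)],
        }
    )
    return GenotypeMatrix(dosage_by_order[idx], list(ped.ids), snps)


# ---------------------------------------------------------------------------
# phenotypes


def _kinship_sqrt(K: KinshipMatrix) -> np.ndarray:
    lam, U = np.linalg.eigh(K.values)
    lam = np.clip(lam, 0.0, None)
    return U * np.sqrt(lam)


def sim_longitudinal(
    ped: Pedigree,
    G: GenotypeMatrix | None,
    causal: dict | None,
    vc_truth: BivarVarComponents = DEFAULT_VC_TRUTH,
    seed: int = 0,
    missing_rate: float = 0.0,
    visit_means: dict = DEFAULT_VISIT_MEANS,
    K: KinshipMatrix | None = None,
    raw_scale: bool = True,
) -> pd.DataFrame:
    """Sample TG/HDL at four visits from the structured bivariate model.

    ``causal`` maps snp_id to a (beta_tg, beta_hdl) pair of additive
    dosage effects on the transformed scale.  Returns a raw-scale
    phenotype table (``exp(exp(y))``) with MCAR missingness at
    ``missing_rate`` unless ``raw_scale=False`` (transformed values,
    useful for fitting-only studies).
    """
    vc_truth.validate()
    rng = _rng(seed, "longitudinal")
    if K is None:
        K = compute_kinship(ped)
    n = K.n
    mean = np.empty((n, 8))
    mean[:, :4] = np.asarray(visit_means["tg"])
    mean[:, 4:] = np.asarray(visit_means["hdl"])
    if causal:
        if G is None:
            raise ValueError("causal effects given but no genotypes")
        for sid, (b_tg, b_hdl) in causal.items():
            g = G.column(sid)
            mean[:, :4] += np.outer(g, np.full(4, b_tg))
            mean[:, 4:] += np.outer(g, np.full(4, b_hdl))
    Lk = _kinship_sqrt(K)
    Lu = np.linalg.cholesky(vc_truth.sigma_u() + 1e-14 * np.eye(2))
    gen = Lk @ rng.standard_normal((n, 2)) @ Lu.T  # (n, 2): per-trait polygenic
    C1, _ = vc_truth.blocks()
    eps = rng.standard_normal((n, 8)) @ np.linalg.cholesky(C1).T
    y = mean + np.repeat(gen, 4, axis=1) + eps
    out = pd.DataFrame(
        loglog_inverse(y) if raw_scale else y,
        index=pd.Index(K.ids, name="iid"),
        columns=PHENO_COLUMNS,
    )
    if missing_rate > 0:
        mask = rng.random(out.shape) < missing_rate
        out = out.mask(mask)
    return out


def sim_response(
    ped: Pedigree,
    G: GenotypeMatrix | None,
    truth: ResponseTruth = ResponseTruth(),
    seed: int = 0,
    R: np.ndarray | None = None,
    K: KinshipMatrix | None = None,
) -> tuple[pd.Series, pd.DataFrame]:
    """Sample the treatment-response model ``Y = X beta + u + eps``.

    Covariates: age ~ discrete uniform on 20..70 years, smoking ~
    Bernoulli(0.3).  ``u ~ N(0, sigma2_g K)`` over the whole pedigree;
    ``eps ~ N(0, sigma2_e R)`` with ``R = I`` by default.
    """
    rng = _rng(seed, "response")
    if K is None:
        K = compute_kinship(ped)
    n = K.n
    age = rng.integers(20, 71, size=n).astype(float)
    smoking = (rng.random(n) < 0.3).astype(float)
    b0, b_age, b_smk = truth.beta
    mu = b0 + b_age * age + b_smk * smoking
    for sid, beta in truth.snp_effects.items():
        if G is None:
            raise ValueError("snp_effects given but no genotypes")
        mu = mu + beta * G.column(sid)
    u = np.sqrt(truth.sigma2_g) * (_kinship_sqrt(K) @ rng.standard_normal(n))
    if R is None:
        eps = np.sqrt(truth.sigma2_e) * rng.standard_normal(n)
    else:
        eps = np.sqrt(truth.sigma2_e) * (
            np.linalg.cholesky(R) @ rng.standard_normal(n)
        )
    y = pd.Series(mu + u + eps, index=pd.Index(K.ids, name="iid"), name="response")
    cov = pd.DataFrame(
        {"age": age, "smoking": smoking}, index=pd.Index(K.ids, name="iid")
    )
    return y, cov
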