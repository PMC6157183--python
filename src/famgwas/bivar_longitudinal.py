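"""Bivariate longitudinal mixed model and its genome-wide LRT scan.

The model treats the two lipid traits at four visits,
``Y = (Y_TG', Y_HDL')'``, as one Gaussian vector: fixed effects are four
visit means per trait (which absorb the drug effect) plus one SNP effect
per trait, the polygenic random effect is spread over relatives by the
kinship matrix, and the residual carries Markov-product temporal and
cross-trait environmental correlation (see :mod:`famgwas.covstruct`).

A SNP is tested by the likelihood ratio between the model with and
without its two trait effects; twice the log-likelihood difference is
referred to chi-square with 2 degrees of freedom.  Both fits maximize
the *full* (ML, not REML) likelihood — the hypotheses differ in fixed
effects, where restricted likelihoods are not comparable.  Fixed
effects are profiled out by GLS at every variance-parameter proposal,
so the optimizer works on the 12 variance parameters only, on an
unconstrained scale (log variances, atanh correlations).  Fitting is
deterministic: restarts are fixed transformations of a moment-based
start, and no randomness enters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .covstruct import (
    BLOCK,
    N_VISITS,
    BivarVarComponents,
    KinshipEigen,
    MarkovCorrParams,
    profiled_loglik,
)
from .dataio import PHENO_COLUMNS, GenotypeMatrix
from .pedkin import KinshipMatrix

__all__ = [
    "BivarFixedEffects",
    "BivarFit",
    "LrtResult",
    "fit_bivar",
    "lrt_snp",
    "gwas_longitudinal",
    "moment_start",
]

_PENALTY = 1e10
LRT_DF = 2


@dataclass
class BivarFixedEffects:
    """Per-trait fixed effects: 4 visit means then the SNP effect."""

    beta_t1: np.ndarray  # (5,)
    beta_t2: np.ndarray  # (5,)

    def __post_init__(self):
        self.beta_t1 = np.asarray(self.beta_t1, dtype=float)
        self.beta_t2 = np.asarray(self.beta_t2, dtype=float)
        if self.beta_t1.shape != (5,) or self.beta_t2.shape != (5,):
            raise ValueError("fixed-effect vectors must have length 5")


@dataclass
class BivarFit:
    fixed: BivarFixedEffects
    vc: BivarVarComponents
    loglik: float
    converged: bool
    iterations: int
    n: int


@dataclass
class LrtResult:
    snp_id: str
    lrt_stat: float
    df: int
    p_value: float
    converged: bool
    reason: str = ""


def _design(n_extra: int) -> tuple[np.ndarray, np.ndarray]:
    """Column patterns of the rotated design.

    Columns 0-7 are the per-trait visit means (pattern ``e_{t,v}``,
    scalar 0 = rotated intercept); then for each extra per-individual
    scalar (SNP, covariates) one constant-over-visits column per trait.
    """
    patterns = [np.eye(BLOCK)[c] for c in range(BLOCK)]
    scalars = [0] * BLOCK
    for k in range(1, n_extra + 1):
        for t in range(2):
            p = np.zeros(BLOCK)
            p[t * N_VISITS : (t + 1) * N_VISITS] = 1.0
            patterns.append(p)
            scalars.append(k)
    return np.array(patterns), np.array(scalars, dtype=np.int64)


def moment_start(Y: np.ndarray) -> BivarVarComponents:
    """Moment-based starting values from the (n, 8) phenotype block.

    Sample column variances are split half-and-half between polygenic
    and residual components; adjacent-visit and cross-trait sample
    correlations seed the correlation parameters (shrunk, clipped away
    from the boundary).
    """
    v = Y.var(axis=0, ddof=1)
    v1 = max(float(v[:4].mean()), 1e-6)
    v2 = max(float(v[4:].mean()), 1e-6)

    def adj(cols):
        out = []
        for k in range(3):
            r = np.corrcoef(cols[:, k], cols[:, k + 1])[0, 1]
            out.append(float(np.clip(np.nan_to_num(r), -0.9, 0.9)))
        return MarkovCorrParams(*out)

    m1, m2 = adj(Y[:, :4]), adj(Y[:, 4:])
    rx = np.corrcoef(Y[:, :4].mean(axis=1), Y[:, 4:].mean(axis=1))[0, 1]
    rx = float(np.clip(np.nan_to_num(rx), -0.9, 0.9))
    return BivarVarComponents(
        sigma2_u_t1=0.5 * v1,
        sigma2_u_t2=0.5 * v2,
        rho_g=0.5 * rx,
        sigma2_e_t1=0.5 * v1,
        sigma2_e_t2=0.5 * v2,
        markov_t1=m1,
        markov_t2=m2,
        rho_eps=0.5 * rx,
    )


def _prepare(pheno: pd.DataFrame, K) -> tuple[np.ndarray, KinshipEigen]:
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns {missing}")
    Y = pheno[PHENO_COLUMNS].to_numpy(dtype=float)
    if np.isnan(Y).any():
        raise ValueError("phenotypes must be complete (impute first)")
    if isinstance(K, KinshipEigen):
        if list(pheno.index) != K.ids:
            raise ValueError("phenotype ids do not match kinship eigen ids")
        eigen = K
    else:
        eigen = KinshipEigen(K.subset(list(pheno.index)))
    return Y, eigen


def fit_bivar(
    pheno: pd.DataFrame,
    K: KinshipMatrix | KinshipEigen,
    g: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    constrain_snp_to_zero: bool = False,
    starts: list[BivarVarComponents] | None = None,
    tol: float = 1e-8,
    max_iter: int = 500,
) -> BivarFit:
    """Maximum-likelihood fit of the bivariate longitudinal model.

    ``pheno``: complete transformed phenotypes (rows = individuals,
    columns ``tg_v1..hdl_v4``), aligned with ``K``.  ``g``: minor-allele
    dosage vector, omitted or ignored under the null
    (``constrain_snp_to_zero=True``).  ``covariates``: optional numeric
    table appended per trait as constant-over-visit effects (off by
    default; the design of record holds only visit means and the SNP).

    ``starts`` overrides the three deterministic restarts (moment-based,
    shrunk, inflated); scans pass the null fit's variance components as
    a warm start.
    """
    Y, eigen = _prepare(pheno, K)
    n = eigen.n
    Yt = eigen.rotate(Y)
    cols = [eigen.rotate(np.ones(n))]
    snp_in_model = g is not None and not constrain_snp_to_zero
    if snp_in_model:
        g = np.asarray(g, dtype=float)
        if g.shape != (n,):
            raise ValueError("genotype vector length mismatch")
        if np.isnan(g).any():
            raise ValueError("genotype vector has missing values")
        if np.unique(g).size < 2:
            raise ValueError("constant genotype column (should have been QC'd)")
        cols.append(eigen.rotate(g))
    if covariates is not None:
        C = covariates.loc[pheno.index].to_numpy(dtype=float)
        for j in range(C.shape[1]):
            cols.append(eigen.rotate(C[:, j]))
    W = np.column_stack(cols)
    patterns, scalars = _design(W.shape[1] - 1)
    lam = eigen.lam

    def negloglik(theta: np.ndarray) -> float:
        try:
            vc = BivarVarComponents.from_vector(theta)
            C1, C2 = vc.blocks()
        except (ValueError, FloatingPointError):
            return _PENALTY
        ll, _, _ = profiled_loglik(C1, C2, lam, Yt, W, patterns, scalars)
        if not np.isfinite(ll):
            return _PENALTY
        return -ll

    if starts is None:
        base = moment_start(Y)
        starts = [base, base.scaled(0.5, 0.5), base.scaled(2.0, 1.0)]
    best = None
    total_iter = 0
    for s in starts:
        res = optimize.minimize(
            negloglik,
            s.to_vector(),
            method="L-BFGS-B",
            options={"maxiter": max_iter, "ftol": tol, "maxfun": 50 * max_iter},
        )
        total_iter += res.nit
        if best is None or res.fun < best.fun:
            best = res
    converged = bool(best.fun < _PENALTY and np.all(np.isfinite(best.x)))
    vc_hat = BivarVarComponents.from_vector(best.x)
    C1, C2 = vc_hat.blocks()
    ll, beta, _ = profiled_loglik(C1, C2, lam, Yt, W, patterns, scalars)
    if beta is None:
        raise RuntimeError("final likelihood evaluation failed")
    b1 = np.zeros(5)
    b2 = np.zeros(5)
    b1[:4], b2[:4] = beta[:4], beta[4:8]
    if snp_in_model:
        b1[4], b2[4] = beta[8], beta[9]
    return BivarFit(
        fixed=BivarFixedEffects(b1, b2),
        vc=vc_hat,
        loglik=float(ll),
        converged=converged,
        iterations=total_iter,
        n=n,
    )


def _gls_loglik_at(
    vc: BivarVarComponents, eigen: KinshipEigen, Yt, W
) -> tuple[float, np.ndarray | None]:
    """Profiled likelihood at fixed variance components (no refit)."""
    C1, C2 = vc.blocks()
    patterns, scalars = _design(W.shape[1] - 1)
    ll, beta, _ = profiled_loglik(C1, C2, eigen.lam, Yt, W, patterns, scalars)
    return ll, beta


def lrt_snp(
    pheno: pd.DataFrame,
    g: np.ndarray,
    K: KinshipMatrix | KinshipEigen,
    snp_id: str = "snp",
    null_fit: BivarFit | None = None,
    covariates: pd.DataFrame | None = None,
    **fit_kw,
) -> LrtResult:
    """Likelihood-ratio test of one SNP against both traits (df = 2).

    The null fit (no SNP anywhere) does not depend on the genotype and
    may be passed in to be shared across a scan; the alternative refit
    is warm-started at the null variance components.
    """
    if null_fit is None:
        null_fit = fit_bivar(
            pheno, K, constrain_snp_to_zero=True, covariates=covariates, **fit_kw
        )
    alt = fit_bivar(
        pheno,
        K,
        g=g,
        covariates=covariates,
        starts=[null_fit.vc],
        **fit_kw,
    )
    if not (null_fit.converged and alt.converged):
        return LrtResult(snp_id, np.nan, LRT_DF, np.nan, False, "fit_not_converged")
    stat = 2.0 * (alt.loglik - null_fit.loglik)
    if stat < 0.0:
        if stat < -1e-6:
            warnings.warn(
                f"{snp_id}: negative LRT statistic {stat:.3g} clipped to 0",
                stacklevel=2,
            )
        stat = 0.0
    return LrtResult(snp_id, float(stat), LRT_DF, float(stats.chi2.sf(stat, LRT_DF)), True)


def gwas_longitudinal(
    pheno: pd.DataFrame,
    G: GenotypeMatrix,
    K: KinshipMatrix | KinshipEigen,
    mode: str = "full_refit",
    covariates: pd.DataFrame | None = None,
    **fit_kw,
) -> pd.DataFrame:
    """Genome-wide bivariate LRT scan.

    ``full_refit`` re-maximizes the 12 variance parameters under the
    alternative for every SNP (warm-started at the null estimates);
    ``fixed_vc`` keeps the null variance components fixed and refits
    fixed effects only — a labeled fast approximation.  Per-SNP
    failures are recorded, never fatal.  Output columns: snp_id, chrom,
    bp, lrt, df, p, p_bh, converged, mode.
    """
    from .report import bh_adjust

    if mode not in {"full_refit", "fixed_vc"}:
        raise ValueError(f"unknown mode {mode!r}")
    cols = ["snp_id", "chrom", "bp", "lrt", "df", "p", "p_bh", "converged", "mode"]
    if G.m == 0:
        return pd.DataFrame(columns=cols)
    if list(G.iids) != list(pheno.index):
        raise ValueError("genotype iids do not match phenotype rows")
    Y, eigen = _prepare(pheno, K)
    null_fit = fit_bivar(
        pheno, eigen, constrain_snp_to_zero=True, covariates=covariates, **fit_kw
    )
    Yt = eigen.rotate(Y)
    ones_rot = eigen.rotate(np.ones(eigen.n))
    rows = []
    for j, sid in enumerate(G.snp_ids):
        g = G.dosages[:, j]
        rec = {
            "snp_id": sid,
            "chrom": G.snps["chrom"].iloc[j],
            "bp": G.snps["bp"].iloc[j],
            "df": LRT_DF,
            "mode": mode,
        }
        try:
            if mode == "full_refit":
                r = lrt_snp(
                    pheno, g, eigen, snp_id=sid, null_fit=null_fit,
                    covariates=covariates, **fit_kw,
                )
                rec.update(lrt=r.lrt_stat, p=r.p_value, converged=r.converged)
            else:
                W = np.column_stack([ones_rot, eigen.rotate(np.asarray(g, float))])
                ll_alt, _ = _gls_loglik_at(null_fit.vc, eigen, Yt, W)
                stat = max(0.0, 2.0 * (ll_alt - null_fit.loglik))
                rec.update(
                    lrt=stat,
                    p=float(stats.chi2.sf(stat, LRT_DF)),
                    converged=null_fit.converged,
                )
        except (ValueError, RuntimeError) as exc:
            rec.update(lrt=np.nan, p=np.nan, converged=False, reason=str(exc))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out[cols + [c for c in out.columns if c not in cols]]
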