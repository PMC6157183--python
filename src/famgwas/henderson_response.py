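"""Henderson mixed model for the fenofibrate-response phenotype.

The response ``Y`` (change in transformed TG from pre- to post-treatment
visits) follows ``Y = X beta + Z u + eps`` with a family-structured
polygenic effect ``u ~ N(0, sigma2_g K)`` and residual
``eps ~ N(0, sigma2_e R)``, so ``Var(Y) = sigma2_g Z K Z' + sigma2_e R``.
``X`` holds an intercept, age, smoking status and either one SNP dosage
or the dosages of a (LD-pruned) genomic region.

Variance components are estimated by REML through the classical EM
iteration (each step is a genuine EM step, so the restricted likelihood
never decreases).  Fixed effects and BLUPs solve Henderson's
mixed-model equations; association is tested with the Wald-type
F statistic

    F = (M beta_hat)' [M (X' V^-1 X)^-1 M']^-1 (M beta_hat) / rank(M)

referred to F(p, n - q) with p = rank(M) and q = ncol(X).

Computation: ``R`` is whitened by its Cholesky factor and ``Z K Z'``
eigendecomposed once per dataset (it does not involve ``X``), after
which every EM step and every per-SNP refit costs O(n q^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .dataio import GenotypeMatrix
from .pedkin import KinshipMatrix

__all__ = [
    "HendersonModel",
    "HendersonFit",
    "FtestResult",
    "solve_mme",
    "em_reml",
    "f_test",
    "gwas_response",
    "region_test",
    "gls_fit",
    "family_exchangeable_R",
    "RandomStructure",
]

_BOUNDARY = 1e-12


def _as_matrix(K) -> np.ndarray:
    return K.values if isinstance(K, KinshipMatrix) else np.asarray(K, dtype=float)


def _check_full_rank(X: np.ndarray, names=None) -> None:
    q = X.shape[1]
    if np.linalg.matrix_rank(X) < q:
        R = np.abs(np.diag(np.linalg.qr(X, mode="r")))
        bad = np.where(R < 1e-10 * max(R.max(), 1.0))[0]
        labels = [names[j] if names else str(j) for j in bad]
        raise ValueError(f"design matrix rank-deficient; collinear columns {labels}")


@dataclass
class HendersonModel:
    """Data and structure of one mixed-model fit."""

    y: np.ndarray  # (n,)
    X: np.ndarray  # (n, q), full column rank
    Z: np.ndarray  # (n, r)
    K: np.ndarray | KinshipMatrix  # (r, r) PSD
    R: np.ndarray | None = None  # (n, n) PD residual correlation; None = I
    column_names: list[str] | None = None

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        self.Kv = _as_matrix(self.K)
        n = self.y.shape[0]
        if self.X.shape[0] != n or self.Z.shape[0] != n:
            raise ValueError("X/Z row count does not match y")
        if self.Kv.shape != (self.Z.shape[1],) * 2:
            raise ValueError("K dimension does not match columns of Z")
        if self.R is None:
            self.R = np.eye(n)
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (n, n) or not np.allclose(self.R, self.R.T, atol=1e-10):
            raise ValueError("R must be a symmetric n x n matrix")
        _check_full_rank(self.X, self.column_names)

    @property
    def n(self) -> int:
        return self.y.shape[0]

    @property
    def q(self) -> int:
        return self.X.shape[1]

    @property
    def r(self) -> int:
        return self.Z.shape[1]


class RandomStructure:
    """Whitened-and-rotated representation of (Z, K, R), cached per scan.

    Whitening by ``chol(R)`` then rotating onto the eigenbasis of the
    whitened ``Z K Z'`` makes ``Var(Y)`` diagonal: ``sigma2_g d_i +
    sigma2_e``.  Independent of ``X`` and ``y``, so one instance serves
    every SNP of a genome scan.
    """

    def __init__(self, Z: np.ndarray, K, R: np.ndarray):
        Kv = _as_matrix(K)
        try:
            Lr = np.linalg.cholesky(R)
        except np.linalg.LinAlgError as exc:
            raise ValueError("R is not positive definite") from exc
        M0 = Z @ Kv @ Z.T
        Mw = linalg.solve_triangular(Lr, M0, lower=True)
        Mw = linalg.solve_triangular(Lr, Mw.T, lower=True).T
        d, Q = np.linalg.eigh(0.5 * (Mw + Mw.T))
        self.d = np.clip(d, 0.0, None)
        self._Q = Q
        self._Lr = Lr
        self.logdet_R = float(2.0 * np.log(np.diag(Lr)).sum())
        self.n = R.shape[0]
        if np.ptp(self.d) < 1e-10 * (1.0 + self.d.max()):
            raise ValueError(
                "variance components not identifiable: Z K Z' is proportional "
                "to R, so sigma2_g and sigma2_e are confounded"
            )

    def transform(self, x: np.ndarray) -> np.ndarray:
        w = linalg.solve_triangular(self._Lr, x, lower=True)
        return self._Q.T @ w


@dataclass
class HendersonFit:
    beta_hat: np.ndarray
    u_hat: np.ndarray
    sigma2_g: float
    sigma2_e: float
    loglik_reml: float
    iterations: int
    converged: bool
    boundary: bool
    n: int
    q: int
    XtViX: np.ndarray  # X' V^-1 X at the fitted components
    loglik_path: list[float] = field(default_factory=list)
    model: HendersonModel | None = None

    @property
    def Vy_hat(self) -> np.ndarray:
        m = self.model
        return self.sigma2_g * (m.Z @ _as_matrix(m.K) @ m.Z.T) + self.sigma2_e * m.R


@dataclass
class FtestResult:
    unit_id: str
    f_stat: float
    df1: int
    df2: int
    p_value: float
    converged: bool = True
    reason: str = ""


# ---------------------------------------------------------------------------
# Henderson's mixed-model equations


def solve_mme(
    m: HendersonModel, sigma2_g: float, sigma2_e: float
) -> tuple[np.ndarray, np.ndarray]:
    """Solve the mixed-model equations at fixed variance components.

    The block system uses the full residual covariance
    ``R* = sigma2_e R`` and ``D = sigma2_g K``; a singular kinship
    matrix is ridged by ``1e-8 I`` (with a warning) so that ``D^-1``
    exists.  The returned ``beta_hat`` coincides with the GLS estimator
    ``(X' V^-1 X)^-1 X' V^-1 y`` and ``u_hat`` with the BLUP
    ``D Z' V^-1 (y - X beta_hat)``.
    """
    if sigma2_g <= 0 or sigma2_e <= 0:
        raise ValueError("variance components must be positive")
    Kv = _as_matrix(m.K)
    w = np.linalg.eigvalsh(Kv)
    if w.min() < 1e-10 * max(1.0, w.max()):
        warnings.warn("kinship matrix numerically singular; ridging by 1e-8 I",
                      stacklevel=2)
        Kv = Kv + 1e-8 * np.eye(Kv.shape[0])
    Rstar_inv = np.linalg.inv(sigma2_e * m.R)
    Dinv = np.linalg.inv(sigma2_g * Kv)
    XtR = m.X.T @ Rstar_inv
    ZtR = m.Z.T @ Rstar_inv
    A = np.block(
        [
            [XtR @ m.X, XtR @ m.Z],
            [ZtR @ m.X, ZtR @ m.Z + Dinv],
        ]
    )
    rhs = np.concatenate([XtR @ m.y, ZtR @ m.y])
    sol = np.linalg.solve(A, rhs)
    return sol[: m.q], sol[m.q :]


# ---------------------------------------------------------------------------
# EM-REML


def em_reml(
    m: HendersonModel,
    init: tuple[float, float] = (1.0, 1.0),
    tol: float = 1e-6,
    max_iter: int = 1000,
    rotation: RandomStructure | None = None,
) -> HendersonFit:
    """REML variance components by the classical EM iteration.

    Update (for each component, with ``V_g = Z K Z'``, ``V_e = R`` and
    ``P`` the REML projection)::

        sigma2_new = sigma2 + sigma2^2 (y' P V_c P y - tr(P V_c)) / m_c

    with ``m_g = r`` (random-effect levels) and ``m_e = n``.  Converges
    when the largest relative component change drops below ``tol``; a
    component collapsing below 1e-12 is pinned at that boundary with a
    warning.  The restricted log-likelihood is recorded at every
    iteration (it is nondecreasing, a property the tests assert).
    """
    if m.n <= m.q:
        raise ValueError("need n > q observations for REML")
    s2g, s2e = map(float, init)
    if s2g <= 0 or s2e <= 0:
        raise ValueError("initial variance components must be positive")
    rot = rotation or RandomStructure(m.Z, m.K, m.R)
    yt = rot.transform(m.y)
    Xt = rot.transform(m.X)
    d = rot.d
    n, q, r = m.n, m.q, m.r

    def state(s2g, s2e):
        v = s2g * d + s2e
        A = Xt / v[:, None]
        XtVX = Xt.T @ A
        cf = linalg.cho_factor(XtVX)
        beta = linalg.cho_solve(cf, A.T @ yt)
        Py = yt / v - A @ beta
        ll = -0.5 * (
            (n - q) * np.log(2.0 * np.pi)
            + np.log(v).sum()
            + rot.logdet_R
            + 2.0 * np.log(np.diag(cf[0])).sum()
            + yt @ Py
        )
        return v, A, XtVX, cf, beta, Py, float(ll)

    path: list[float] = []
    boundary = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        v, A, XtVX, cf, beta, Py, ll = state(s2g, s2e)
        path.append(ll)
        AtA_g = A.T @ (d[:, None] * A)
        AtA_e = A.T @ A
        tr_g = float((d / v).sum() - np.trace(linalg.cho_solve(cf, AtA_g)))
        tr_e = float((1.0 / v).sum() - np.trace(linalg.cho_solve(cf, AtA_e)))
        yq_g = float(d @ (Py**2))
        yq_e = float(Py @ Py)
        s2g_new = s2g + s2g**2 * (yq_g - tr_g) / r
        s2e_new = s2e + s2e**2 * (yq_e - tr_e) / n
        if s2g_new < _BOUNDARY or s2e_new < _BOUNDARY:
            boundary = True
            warnings.warn("variance component pinned at lower boundary 1e-12",
                          stacklevel=2)
            s2g_new = max(s2g_new, _BOUNDARY)
            s2e_new = max(s2e_new, _BOUNDARY)
        delta = max(
            abs(s2g_new - s2g) / max(s2g, _BOUNDARY),
            abs(s2e_new - s2e) / max(s2e, _BOUNDARY),
        )
        s2g, s2e = s2g_new, s2e_new
        if delta < tol:
            converged = True
            break
    v, A, XtVX, cf, beta, Py, ll = state(s2g, s2e)
    path.append(ll)
    # BLUP in original coordinates: u_hat = sigma2_g K Z' V^-1 (y - X beta)
    Kv = _as_matrix(m.K)
    Vy = s2g * (m.Z @ Kv @ m.Z.T) + s2e * m.R
    u_hat = s2g * Kv @ m.Z.T @ np.linalg.solve(Vy, m.y - m.X @ beta)
    return HendersonFit(
        beta_hat=beta,
        u_hat=u_hat,
        sigma2_g=s2g,
        sigma2_e=s2e,
        loglik_reml=float(ll),
        iterations=it,
        converged=converged,
        boundary=boundary,
        n=n,
        q=q,
        XtViX=XtVX,
        loglik_path=path,
        model=m,
    )


# ---------------------------------------------------------------------------
# F-test


def f_test(fit: HendersonFit, M: np.ndarray, unit_id: str = "unit") -> FtestResult:
    """Wald-type F-test of H0: M beta = 0 with df (rank(M), n - q)."""
    M = np.atleast_2d(np.asarray(M, dtype=float))
    p = M.shape[0]
    if M.shape[1] != fit.q:
        raise ValueError("contrast matrix column count does not match beta")
    if np.linalg.matrix_rank(M) < p:
        raise ValueError("contrast matrix is not full row rank")
    mb = M @ fit.beta_hat
    mid = M @ np.linalg.solve(fit.XtViX, M.T)
    try:
        cf = linalg.cho_factor(mid)
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular contrast covariance (redundant contrasts)") from exc
    F = float(mb @ linalg.cho_solve(cf, mb)) / p
    df2 = fit.n - fit.q
    return FtestResult(
        unit_id=unit_id,
        f_stat=F,
        df1=p,
        df2=df2,
        p_value=float(stats.f.sf(F, p, df2)),
        converged=fit.converged,
    )


# ---------------------------------------------------------------------------
# scans


def family_exchangeable_R(families: list, rho: float) -> np.ndarray:
    """Within-family exchangeable residual correlation (diag 1, rho within)."""
    if not -1.0 < rho < 1.0:
        raise ValueError("rho must lie in (-1, 1)")
    fam = np.asarray(families)
    same = fam[:, None] == fam[None, :]
    R = np.where(same, rho, 0.0)
    np.fill_diagonal(R, 1.0)
    return R


def _base_design(
    response: pd.Series, covariates: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    cov = covariates.loc[response.index, ["age", "smoking"]].to_numpy(dtype=float)
    X0 = np.column_stack([np.ones(len(response)), cov])
    return response.to_numpy(dtype=float), X0, ["intercept", "age", "smoking"]


def gwas_response(
    response: pd.Series,
    covariates: pd.DataFrame,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    R: np.ndarray | None = None,
    refit: bool = True,
    init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> pd.DataFrame:
    """Single-SNP F-test scan for treatment response.

    For each SNP, ``X = [1, age, smoking, g]`` and the contrast selects
    the SNP coefficient (df1 = 1).  By default variance components are
    re-estimated by EM-REML per SNP (the rotated random structure is
    shared, so refits are cheap); ``refit=False`` estimates them once
    under the covariate-only model and keeps them fixed, a labeled
    approximation.  Per-SNP failures are recorded and the scan
    continues.  Output: unit_id, chrom, bp, f, df1, df2, p, p_bh,
    converged, reason.
    """
    from .report import bh_adjust

    iids = list(response.index)
    if list(G.iids) != iids:
        raise ValueError("genotype iids do not match response index")
    y, X0, names = _base_design(response, covariates)
    n = len(y)
    if init is None:
        v0 = float(np.var(y, ddof=1))
        init = (v0 / 2, v0 / 2)  # variance-scaled start speeds EM markedly
    Kv = K.subset(iids).values
    Rm = np.eye(n) if R is None else np.asarray(R, dtype=float)
    Z = np.eye(n)
    rot = RandomStructure(Z, Kv, Rm)
    shared = None
    if not refit:
        m0 = HendersonModel(y, X0, Z, Kv, Rm, column_names=names)
        shared = em_reml(m0, init=init, tol=tol, max_iter=max_iter, rotation=rot)
    rows = []
    for j, sid in enumerate(G.snp_ids):
        rec = {
            "unit_id": sid,
            "chrom": G.snps["chrom"].iloc[j],
            "bp": G.snps["bp"].iloc[j],
        }
        g = G.dosages[:, j]
        try:
            if np.isnan(g).any():
                raise ValueError("missing genotypes (QC first)")
            if np.unique(g).size < 2:
                raise ValueError("constant genotype column")
            X = np.column_stack([X0, g])
            m = HendersonModel(y, X, Z, Kv, Rm, column_names=names + [sid])
            if refit:
                fit = em_reml(m, init=init, tol=tol, max_iter=max_iter, rotation=rot)
            else:
                fit = gls_fit(m, rot, shared.sigma2_g, shared.sigma2_e)
            Mc = np.zeros((1, X.shape[1]))
            Mc[0, -1] = 1.0
            r = f_test(fit, Mc, unit_id=sid)
            rec.update(
                f=r.f_stat, df1=r.df1, df2=r.df2, p=r.p_value,
                converged=r.converged, reason="",
            )
        except (ValueError, np.linalg.LinAlgError) as exc:
            rec.update(f=np.nan, df1=1, df2=n - 4, p=np.nan,
                       converged=False, reason=str(exc))
        rows.append(rec)
    out = pd.DataFrame(rows)
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out[["unit_id", "chrom", "bp", "f", "df1", "df2", "p", "p_bh",
                "converged", "reason"]]


def gls_fit(
    m: HendersonModel, rot: RandomStructure, s2g: float, s2e: float
) -> HendersonFit:
    """Fixed-effect GLS fit at externally fixed variance components.

    Accepts ``sigma2_g = 0`` (pure fixed-effects model), in which case the
    F-test reduces exactly to the classical OLS partial F-test when R = I.
    """
    yt = rot.transform(m.y)
    Xt = rot.transform(m.X)
    v = s2g * rot.d + s2e
    A = Xt / v[:, None]
    XtVX = Xt.T @ A
    beta = np.linalg.solve(XtVX, A.T @ yt)
    Py = yt / v - A @ beta
    ll = -0.5 * (
        (m.n - m.q) * np.log(2.0 * np.pi)
        + np.log(v).sum()
        + rot.logdet_R
        + np.linalg.slogdet(XtVX)[1]
        + yt @ Py
    )
    Kv = _as_matrix(m.K)
    Vy = s2g * (m.Z @ Kv @ m.Z.T) + s2e * m.R
    u_hat = s2g * Kv @ m.Z.T @ np.linalg.solve(Vy, m.y - m.X @ beta)
    return HendersonFit(
        beta_hat=beta, u_hat=u_hat, sigma2_g=s2g, sigma2_e=s2e,
        loglik_reml=float(ll), iterations=0, converged=True, boundary=False,
        n=m.n, q=m.q, XtViX=XtVX, model=m,
    )


def region_test(
    response: pd.Series,
    covariates: pd.DataFrame,
    region,
    G: GenotypeMatrix,
    K: KinshipMatrix,
    R: np.ndarray | None = None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 5000,
) -> FtestResult:
    """Joint F-test of all pruned SNPs in one genomic region.

    ``X = [1, age, smoking, g_1..g_p]``; the contrast selects the p SNP
    coefficients jointly, giving df (p, n - q).  Collinear SNP columns
    surviving pruning are dropped with a warning before testing; a
    saturated design (p >= n - 3) raises.
    """
    snp_ids = list(region.pruned_snp_ids or region.snp_ids)
    if not snp_ids:
        raise ValueError(f"region {region.region_id} has no SNPs")
    iids = list(response.index)
    if list(G.iids) != iids:
        raise ValueError("genotype iids do not match response index")
    y, X0, names = _base_design(response, covariates)
    n = len(y)
    if len(snp_ids) >= n - 3:
        raise ValueError(
            f"region {region.region_id}: {len(snp_ids)} SNPs saturate the "
            f"design (n = {n})"
        )
    Gs = G.select(snp_ids)
    cols = Gs.dosages
    # drop columns collinear with the covariates or each other
    keep: list[int] = []
    base = X0
    for j in range(cols.shape[1]):
        trial = np.column_stack([base, cols[:, keep + [j]]])
        if np.linalg.matrix_rank(trial) == trial.shape[1]:
            keep.append(j)
    if len(keep) < cols.shape[1]:
        dropped = [snp_ids[j] for j in range(cols.shape[1]) if j not in keep]
        warnings.warn(
            f"region {region.region_id}: dropped collinear SNP columns {dropped}",
            stacklevel=2,
        )
    if not keep:
        raise ValueError(f"region {region.region_id}: no testable SNP columns")
    X = np.column_stack([X0, cols[:, keep]])
    if init is None:
        v0 = float(np.var(y, ddof=1))
        init = (v0 / 2, v0 / 2)
    Kv = K.subset(iids).values
    Rm = np.eye(n) if R is None else np.asarray(R, dtype=float)
    m = HendersonModel(
        y, X, np.eye(n), Kv, Rm,
        column_names=names + [snp_ids[j] for j in keep],
    )
    fit = em_reml(m, init=init, tol=tol, max_iter=max_iter)
    p = len(keep)
    Mc = np.zeros((p, X.shape[1]))
    Mc[:, 3:] = np.eye(p)
    return f_test(fit, Mc, unit_id=region.region_id)
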