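"""Kronecker-structured covariance for the bivariate longitudinal model.

Two traits (TG, HDL) observed at four visits on *n* related individuals
give an ``8n``-dimensional response whose covariance splits into a
per-individual environmental block repeated over individuals and a
genetic block spread by the kinship matrix::

    Var(Y) = C1 (x) I_n  +  C2 (x) K

under trait-major (trait, visit) x individual ordering, where

* ``C1`` is the 8x8 bivariate environmental covariance: trait-diagonal
  blocks ``sigma2_e,t * M(rho_t)`` with ``M`` a Markov-product temporal
  correlation (corr(visit i, visit j) = product of the adjacent-lag
  correlations between them), and off-diagonal blocks
  ``rho_eps * S_1^{1/2} S_2^{1/2}`` built from symmetric matrix square
  roots;
* ``C2 = Sigma_u (x) J_4`` with ``Sigma_u`` the 2x2 polygenic
  (co)variance of the two traits and ``J_4`` the all-ones matrix — the
  polygenic effect of a trait is constant across visits.

Rotating the individual axis onto the eigenbasis of ``K`` turns the
``8n x 8n`` Gaussian into *n* independent 8-dimensional blocks
``C1 + lambda_i * C2``, which is what makes genome-wide likelihood work
feasible; the rotation is computed once per kinship matrix and reused.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pedkin import KinshipMatrix
from . import _kernels

__all__ = [
    "MarkovCorrParams",
    "BivarVarComponents",
    "StructuredCov",
    "markov_corr",
    "sym_sqrt",
    "build_structured_cov",
    "gaussian_loglik",
    "KinshipEigen",
]

N_VISITS = 4
N_TRAITS = 2
BLOCK = N_VISITS * N_TRAITS  # 8


@dataclass(frozen=True)
class MarkovCorrParams:
    """Adjacent-visit correlations (rho1, rho2, rho3), each in (-1, 1)."""

    rho1: float
    rho2: float
    rho3: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.rho1, self.rho2, self.rho3)

    def validate(self) -> None:
        for r in self.as_tuple():
            if not abs(r) < 1.0:
                raise ValueError(f"Markov correlation |rho| >= 1: {r}")


def markov_corr(params: MarkovCorrParams | tuple[float, float, float]) -> np.ndarray:
    """4x4 correlation matrix with corr(i, j) = prod of adjacent rhos.

    The product rule gives the Markov identity
    ``corr(i, k) = corr(i, j) * corr(j, k)`` for i < j < k exactly.
    """
    if not isinstance(params, MarkovCorrParams):
        params = MarkovCorrParams(*params)
    params.validate()
    rho = params.as_tuple()
    M = np.eye(N_VISITS)
    for i in range(N_VISITS):
        for j in range(i + 1, N_VISITS):
            M[i, j] = M[j, i] = float(np.prod(rho[i:j]))
    return M


def sym_sqrt(S: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Unique symmetric PSD square root via eigendecomposition.

    Eigenvalues in ``[-tol, 0)`` are clipped to zero; materially negative
    ones raise.  The symmetric (not Cholesky) root is required so that
    cross-trait blocks ``rho_eps * S1^{1/2} S2^{1/2}`` assemble into a
    symmetric overall covariance.
    """
    S = np.asarray(S, dtype=float)
    if not np.allclose(S, S.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")
    w, V = np.linalg.eigh(S)
    if w.min() < -tol * max(1.0, abs(w.max())):
        raise ValueError(f"matrix is not PSD (min eigenvalue {w.min():g})")
    w = np.clip(w, 0.0, None)
    return (V * np.sqrt(w)) @ V.T


@dataclass(frozen=True)
class BivarVarComponents:
    """The 12 variance parameters of the bivariate longitudinal model.

    ``sigma2_u_*``: polygenic variances of the two traits; ``rho_g``:
    genetic correlation; ``sigma2_e_*``: residual variances (common over
    visits within a trait); ``markov_*``: temporal correlations per
    trait; ``rho_eps``: environmental cross-trait correlation.  All on
    the transformed (log-log) phenotype scale, unitless.
    """

    sigma2_u_t1: float
    sigma2_u_t2: float
    rho_g: float
    sigma2_e_t1: float
    sigma2_e_t2: float
    markov_t1: MarkovCorrParams
    markov_t2: MarkovCorrParams
    rho_eps: float

    def validate(self) -> None:
        for v in (self.sigma2_u_t1, self.sigma2_u_t2, self.sigma2_e_t1, self.sigma2_e_t2):
            if not v > 0:
                raise ValueError(f"variance must be positive, got {v}")
        for r in (self.rho_g, self.rho_eps):
            if not abs(r) < 1.0:
                raise ValueError(f"correlation |rho| >= 1: {r}")
        self.markov_t1.validate()
        self.markov_t2.validate()

    # -- unconstrained parameterization for optimizers ------------------
    def to_vector(self) -> np.ndarray:
        """Map to R^12: log variances, atanh correlations."""
        return np.array(
            [
                np.log(self.sigma2_u_t1),
                np.log(self.sigma2_u_t2),
                np.arctanh(self.rho_g),
                np.log(self.sigma2_e_t1),
                np.log(self.sigma2_e_t2),
                *np.arctanh(self.markov_t1.as_tuple()),
                *np.arctanh(self.markov_t2.as_tuple()),
                np.arctanh(self.rho_eps),
            ]
        )

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "BivarVarComponents":
        v = np.asarray(v, dtype=float)
        if v.shape != (12,):
            raise ValueError("parameter vector must have length 12")
        return cls(
            sigma2_u_t1=float(np.exp(v[0])),
            sigma2_u_t2=float(np.exp(v[1])),
            rho_g=float(np.tanh(v[2])),
            sigma2_e_t1=float(np.exp(v[3])),
            sigma2_e_t2=float(np.exp(v[4])),
            markov_t1=MarkovCorrParams(*np.tanh(v[5:8])),
            markov_t2=MarkovCorrParams(*np.tanh(v[8:11])),
            rho_eps=float(np.tanh(v[11])),
        )

    def scaled(self, var_factor: float = 1.0, corr_factor: float = 1.0):
        """Scaled copy (used for deterministic optimizer restarts)."""
        sc = lambda m: MarkovCorrParams(*(r * corr_factor for r in m.as_tuple()))
        return replace(
            self,
            sigma2_u_t1=self.sigma2_u_t1 * var_factor,
            sigma2_u_t2=self.sigma2_u_t2 * var_factor,
            sigma2_e_t1=self.sigma2_e_t1 * var_factor,
            sigma2_e_t2=self.sigma2_e_t2 * var_factor,
            rho_g=self.rho_g * corr_factor,
            rho_eps=self.rho_eps * corr_factor,
            markov_t1=sc(self.markov_t1),
            markov_t2=sc(self.markov_t2),
        )

    # -- block assembly --------------------------------------------------
    def sigma_u(self) -> np.ndarray:
        """2x2 polygenic covariance matrix of the two traits."""
        c = self.rho_g * np.sqrt(self.sigma2_u_t1 * self.sigma2_u_t2)
        return np.array([[self.sigma2_u_t1, c], [c, self.sigma2_u_t2]])

    def blocks(self) -> tuple[np.ndarray, np.ndarray]:
        """(C1, C2): 8x8 environmental and genetic per-individual blocks."""
        S1 = self.sigma2_e_t1 * markov_corr(self.markov_t1)
        S2 = self.sigma2_e_t2 * markov_corr(self.markov_t2)
        off = self.rho_eps * sym_sqrt(S1) @ sym_sqrt(S2)
        C1 = np.block([[S1, off], [off.T, S2]])
        C2 = np.kron(self.sigma_u(), np.ones((N_VISITS, N_VISITS)))
        return C1, C2


class KinshipEigen:
    """Cached eigendecomposition of a kinship matrix.

    Computed once per dataset (O(n^3)); every per-SNP likelihood reuses
    it.  ``lam`` are the eigenvalues (ascending), ``U`` the rotation.
    """

    def __init__(self, K: KinshipMatrix):
        lam, U = np.linalg.eigh(K.values)
        if lam.min() < -1e-8 * max(1.0, lam.max()):
            raise ValueError(f"kinship matrix not PSD (min eig {lam.min():g})")
        self.lam = np.clip(lam, 0.0, None)
        self.U = U
        self.ids = list(K.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def rotate(self, x: np.ndarray) -> np.ndarray:
        """Apply U' along the individual (first) axis."""
        return self.U.T @ x


@dataclass
class StructuredCov:
    """Var(Y) = C1 (x) I_n + C2 (x) K in eigen-rotated representation."""

    C1: np.ndarray
    C2: np.ndarray
    eigen: KinshipEigen

    @property
    def n(self) -> int:
        return self.eigen.n

    def dense(self) -> np.ndarray:
        """Literal 8n x 8n matrix (tests and tiny-n work only)."""
        K = (self.eigen.U * self.eigen.lam) @ self.eigen.U.T
        return np.kron(self.C1, np.eye(self.n)) + np.kron(self.C2, K)

    def min_block_eigenvalue(self) -> float:
        lam0 = self.eigen.lam.min()
        return float(np.linalg.eigvalsh(self.C1 + lam0 * self.C2).min())


def build_structured_cov(
    vc: BivarVarComponents, K: KinshipMatrix | KinshipEigen
) -> StructuredCov:
    """Assemble the structured covariance and verify positive definiteness.

    Because ``C2`` is PSD and the kinship eigenvalues are nonnegative,
    ``C1 + lam * C2`` is PD for every eigenvalue as soon as it is PD at
    the smallest one; only that block is checked.
    """
    vc.validate()
    C1, C2 = vc.blocks()
    eig = K if isinstance(K, KinshipEigen) else KinshipEigen(K)
    sc = StructuredCov(C1, C2, eig)
    if sc.min_block_eigenvalue() <= 0.0:
        raise ValueError(
            "Var(Y) not positive definite for these variance components "
            f"(rho_g={vc.rho_g:g}, rho_eps={vc.rho_eps:g}); "
            "the bivariate block fails at the smallest kinship eigenvalue"
        )
    return sc


def _as_blocks(y: np.ndarray, n: int) -> np.ndarray:
    """Accept (n, 8) or flat 8n (trait-major, individual-fastest)."""
    y = np.asarray(y, dtype=float)
    if y.shape == (n, BLOCK):
        return y
    if y.shape == (BLOCK * n,):
        return y.reshape(BLOCK, n).T
    raise ValueError(f"expected shape ({n},{BLOCK}) or ({BLOCK * n},), got {y.shape}")


def gaussian_loglik(y: np.ndarray, mean: np.ndarray, sc: StructuredCov) -> float:
    """Exact log-density of N(mean, C1 (x) I + C2 (x) K).

    ``y`` and ``mean`` may be (n, 8) arrays (rows are individuals,
    columns trait-major visits) or flat 8n vectors ordered
    (trait, visit) x individual with the individual index fastest.
    """
    n = sc.n
    resid = _as_blocks(y, n) - _as_blocks(mean, n)
    if not np.all(np.isfinite(resid)):
        raise ValueError("non-finite residual")
    rt = sc.eigen.rotate(resid)  # (n, 8)
    B = sc.C1[None, :, :] + sc.eigen.lam[:, None, None] * sc.C2[None, :, :]
    try:
        L = np.linalg.cholesky(B)
    except np.linalg.LinAlgError as exc:
        raise ValueError("non-PD covariance block") from exc
    logdet = 2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum()
    sol = np.linalg.solve(B, rt[:, :, None])[:, :, 0]
    quad = float(np.einsum("ij,ij->", rt, sol))
    return -0.5 * (BLOCK * n * np.log(2.0 * np.pi) + logdet + quad)


# ---------------------------------------------------------------------------
# profiled GLS likelihood used by the fitter


def profiled_loglik(
    C1: np.ndarray,
    C2: np.ndarray,
    lam: np.ndarray,
    Yt: np.ndarray,
    W: np.ndarray,
    patterns: np.ndarray,
    pattern_scalar: np.ndarray,
):
    """Gaussian log-likelihood with fixed effects profiled out by GLS.

    The rotated design of individual *i* has columns ``W[i, k] * p_c``
    where ``p_c = patterns[c]`` is an 8-vector and
    ``k = pattern_scalar[c]`` indexes the per-individual scalar (rotated
    ones for visit means, rotated genotype/covariate for constant-over-
    visits effects).  Returns ``(loglik, beta, normal_matrix)`` or
    ``(-inf, None, None)`` when some block is not PD.
    """
    ok, ld, T0, V, M = _kernels.accumulate(C1, C2, lam, Yt, W)
    if not ok:
        return -np.inf, None, None
    ncol = len(patterns)
    N = np.empty((ncol, ncol))
    b = np.empty(ncol)
    for c in range(ncol):
        kc = pattern_scalar[c]
        b[c] = patterns[c] @ V[kc]
        for d in range(c, ncol):
            N[c, d] = N[d, c] = patterns[c] @ M[kc, pattern_scalar[d]] @ patterns[d]
    try:
        beta = np.linalg.solve(N, b)
    except np.linalg.LinAlgError:
        return -np.inf, None, None
    n = lam.shape[0]
    quad = T0 - b @ beta
    ll = -0.5 * (BLOCK * n * np.log(2.0 * np.pi) + ld + quad)
    return ll, beta, N
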