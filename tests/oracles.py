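"""Independent oracles used across the test suite.

Each function here recomputes a quantity by a route deliberately
different from the package implementation it checks: Wright's
path-counting formula for kinship, literal dense assembly of the
structured covariance, textbook step-up FDR, and closed-form
GLS/BLUP/ANOVA estimators.
"""

from __future__ import annotations

import numpy as np

from famgwas.covstruct import markov_corr, sym_sqrt
from famgwas.pedkin import Individual, Pedigree, Sex

# ---------------------------------------------------------------------------
# kinship by Wright's path counting


def _ancestral_paths(ped: Pedigree, iid: str):
    """All chains iid -> ... -> ancestor (including the trivial chain)."""
    rec = ped.record(iid)
    paths = [(iid,)]
    for parent in (rec.father, rec.mother):
        if parent:
            for tail in _ancestral_paths(ped, parent):
                paths.append((iid,) + tail)
    return paths


def kinship_path_counting(ped: Pedigree, a: str, b: str, _memo=None) -> float:
    """Wright's formula: sum over pairs of ancestor-disjoint paths.

    phi(a, b) = sum over common ancestors A and over pairs of ascending
    paths (a -> A, b -> A) sharing no individual except A of
    (1/2)^(la + lb + 1) * (1 + f_A), with f_A the kinship of A's parents
    computed by the same rule.  phi(a, a) = 0.5 * (1 + f_a).
    """
    if _memo is None:
        _memo = {}
    key = (a, b) if a <= b else (b, a)
    if key in _memo:
        return _memo[key]
    if a == b:
        rec = ped.record(a)
        f = (
            kinship_path_counting(ped, rec.father, rec.mother, _memo)
            if rec.father and rec.mother
            else 0.0
        )
        val = 0.5 * (1.0 + f)
        _memo[key] = val
        return val
    total = 0.0
    paths_b = _ancestral_paths(ped, b)
    for pa in _ancestral_paths(ped, a):
        interior_a = set(pa[:-1])
        for pb in paths_b:
            if pa[-1] != pb[-1]:
                continue
            if interior_a & set(pb[:-1]):
                continue
            anc = ped.record(pa[-1])
            f_anc = (
                kinship_path_counting(ped, anc.father, anc.mother, _memo)
                if anc.father and anc.mother
                else 0.0
            )
            total += 0.5 ** (len(pa) + len(pb) - 1) * (1.0 + f_anc)
    _memo[key] = total
    return total


def kinship_matrix_path_counting(ped: Pedigree) -> np.ndarray:
    memo: dict = {}
    ids = ped.ids
    n = len(ids)
    phi = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            phi[i, j] = phi[j, i] = kinship_path_counting(ped, ids[i], ids[j], memo)
    return phi


def random_pedigree(rng: np.random.Generator, max_members: int = 40) -> Pedigree:
    """Random single-family pedigree; matings may join relatives."""
    n_founders = int(min(rng.integers(4, 9), max_members - 2))
    recs = [
        Individual(
            f"I{k}", "", "", Sex.male if k % 2 == 0 else Sex.female, "FAM"
        )
        for k in range(n_founders)
    ]
    males = [r.iid for r in recs if r.sex is Sex.male]
    females = [r.iid for r in recs if r.sex is Sex.female]
    k = n_founders
    target = int(rng.integers(n_founders + 1, max_members + 1))
    while k < target and males and females:
        fa = males[int(rng.integers(len(males)))]
        mo = females[int(rng.integers(len(females)))]
        sex = Sex.male if rng.random() < 0.5 else Sex.female
        iid = f"I{k}"
        recs.append(Individual(iid, fa, mo, sex, "FAM"))
        (males if sex is Sex.male else females).append(iid)
        k += 1
    return Pedigree(recs)


# ---------------------------------------------------------------------------
# dense structured-covariance assembly straight from the model display


def dense_bivar_cov(vc, K: np.ndarray) -> np.ndarray:
    """Literal Z (Sigma_u (x) K) Z' + Sigma_eps (x) I assembly.

    Ordering: (trait, visit) blocks with the individual index fastest,
    matching the package's flat-vector convention.
    """
    n = K.shape[0]
    Zt = np.kron(np.ones((4, 1)), np.eye(n))
    Z = np.block(
        [[Zt, np.zeros_like(Zt)], [np.zeros_like(Zt), Zt]]
    )
    S1 = vc.sigma2_e_t1 * markov_corr(vc.markov_t1)
    S2 = vc.sigma2_e_t2 * markov_corr(vc.markov_t2)
    off = vc.rho_eps * sym_sqrt(S1) @ sym_sqrt(S2)
    Se = np.block([[S1, off], [off.T, S2]])
    return Z @ np.kron(vc.sigma_u(), K) @ Z.T + np.kron(Se, np.eye(n))


def flatten_blocks(y: np.ndarray) -> np.ndarray:
    """(n, 8) -> flat 8n, (trait, visit) major, individual fastest."""
    return y.T.reshape(-1)


# ---------------------------------------------------------------------------
# textbook BH step-up


def bh_step_up(p: np.ndarray) -> np.ndarray:
    """adj_(i) = min_{j >= i} m p_(j) / j, capped at 1, input order kept."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    prev = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        prev = min(prev, m * p[idx] / rank)
        adj[idx] = prev
    return adj


# ---------------------------------------------------------------------------
# GLS / BLUP closed forms


def gls_blup(y, X, Z, K, R, s2g, s2e):
    """Direct closed forms: GLS beta and BLUP u from the full V."""
    V = s2g * Z @ K @ Z.T + s2e * R
    Vi = np.linalg.inv(V)
    beta = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    u = s2g * K @ Z.T @ Vi @ (y - X @ beta)
    return beta, u
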