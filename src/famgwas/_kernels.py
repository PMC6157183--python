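"""Inner numerical kernels for the eigen-rotated bivariate likelihood.

The genome-wide scan evaluates, thousands of times, sums over *n*
independent 8x8 Gaussian blocks ``B_i = C1 + lam_i * C2``:
log-determinants, quadratic forms, and the cross-products needed to
profile fixed effects by GLS.  A numba-compiled loop with a hand-written
8x8 Cholesky does this in microseconds; a vectorized numpy fallback is
used when numba is unavailable and serves as a cross-check in tests.
"""

from __future__ import annotations

import numpy as np

BLOCK = 8

__all__ = ["accumulate", "accumulate_numpy", "HAVE_NUMBA"]


def accumulate_numpy(C1, C2, lam, Yt, W):
    """Batched-numpy reference implementation (see :func:`accumulate`)."""
    n = lam.shape[0]
    K = W.shape[1]
    B = C1[None, :, :] + lam[:, None, None] * C2[None, :, :]
    try:
        L = np.linalg.cholesky(B)
    except np.linalg.LinAlgError:
        return False, 0.0, 0.0, np.zeros((K, BLOCK)), np.zeros((K, K, BLOCK, BLOCK))
    ld = float(2.0 * np.log(np.diagonal(L, axis1=1, axis2=2)).sum())
    Binv = np.linalg.inv(B)  # (n, 8, 8)
    s = np.einsum("iab,ib->ia", Binv, Yt)
    T0 = float(np.einsum("ia,ia->", Yt, s))
    V = W.T @ s  # (K, 8)
    M = np.einsum("ik,il,iab->klab", W, W, Binv)
    return True, ld, T0, V, M


try:  # pragma: no cover - exercised indirectly
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _accumulate_nb(C1, C2, lam, Yt, W):  # pragma: no cover - compiled
        n = lam.shape[0]
        K = W.shape[1]
        ld = 0.0
        T0 = 0.0
        V = np.zeros((K, BLOCK))
        M = np.zeros((K, K, BLOCK, BLOCK))
        B = np.empty((BLOCK, BLOCK))
        L = np.empty((BLOCK, BLOCK))
        Li = np.zeros((BLOCK, BLOCK))
        Binv = np.empty((BLOCK, BLOCK))
        s = np.empty(BLOCK)
        for i in range(n):
            li = lam[i]
            for a in range(BLOCK):
                for b in range(BLOCK):
                    B[a, b] = C1[a, b] + li * C2[a, b]
            # Cholesky B = L L'
            for a in range(BLOCK):
                for b in range(a + 1):
                    acc = B[a, b]
                    for c in range(b):
                        acc -= L[a, c] * L[b, c]
                    if a == b:
                        if acc <= 0.0:
                            return False, 0.0, 0.0, V, M
                        L[a, a] = np.sqrt(acc)
                        ld += 2.0 * np.log(L[a, a])
                    else:
                        L[a, b] = acc / L[b, b]
            # invert lower-triangular L
            for a in range(BLOCK):
                Li[a, a] = 1.0 / L[a, a]
                for b in range(a):
                    acc = 0.0
                    for c in range(b, a):
                        acc -= L[a, c] * Li[c, b]
                    Li[a, b] = acc / L[a, a]
            # Binv = Li' Li
            for a in range(BLOCK):
                for b in range(a + 1):
                    acc = 0.0
                    for c in range(a, BLOCK):
                        acc += Li[c, a] * Li[c, b]
                    Binv[a, b] = acc
                    Binv[b, a] = acc
            for a in range(BLOCK):
                acc = 0.0
                for b in range(BLOCK):
                    acc += Binv[a, b] * Yt[i, b]
                s[a] = acc
            for a in range(BLOCK):
                T0 += Yt[i, a] * s[a]
            for k in range(K):
                wk = W[i, k]
                for a in range(BLOCK):
                    V[k, a] += wk * s[a]
                for l in range(k, K):
                    wkl = wk * W[i, l]
                    for a in range(BLOCK):
                        for b in range(BLOCK):
                            M[k, l, a, b] += wkl * Binv[a, b]
        for k in range(K):
            for l in range(k + 1, K):
                for a in range(BLOCK):
                    for b in range(BLOCK):
                        M[l, k, a, b] = M[k, l, a, b]
        return True, ld, T0, V, M

    def accumulate(C1, C2, lam, Yt, W):
        return _accumulate_nb(
            np.ascontiguousarray(C1),
            np.ascontiguousarray(C2),
            np.ascontiguousarray(lam),
            np.ascontiguousarray(Yt),
            np.ascontiguousarray(W),
        )

    HAVE_NUMBA = True
except Exception:  # numba missing or incompatible
    accumulate = accumulate_numpy
    HAVE_NUMBA = False

accumulate.__doc__ = """Per-block accumulations for the rotated likelihood.

Parameters: C1, C2 (8, 8); lam (n,) kinship eigenvalues; Yt (n, 8)
rotated responses; W (n, K) rotated per-individual design scalars.
Returns ``(ok, logdet_sum, y'Vinv y, V, M)`` with
``V[k] = sum_i W[i,k] Binv_i y_i`` and
``M[k,l] = sum_i W[i,k] W[i,l] Binv_i``; ``ok`` is False when some
block is not positive definite.
"""
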