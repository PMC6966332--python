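"""Compiled Newton-Raphson kernel for the Efron/Breslow partial likelihood.

One plain-loop implementation of the same algorithm as the vectorized
engine in ``survival.py`` (their agreement is asserted in the tests).
Rows must already be sorted by time with event rows at the head of each
tie group; ``gstart`` holds the G+1 tie-group row boundaries and
``devents`` the number of events per group.

The linear step solves the p x p system with an explicit Cholesky
factorization so that a singular observed information is reported as a
failure flag instead of an exception.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def _cholesky_solve(A, b, x):
    """Solve A x = b for symmetric positive-definite A.

    Returns False (without touching x) when a pivot collapses, i.e. A is
    (numerically) singular.
    """
    p = A.shape[0]
    L = np.zeros((p, p))
    scale = 0.0
    for i in range(p):
        if A[i, i] > scale:
            scale = A[i, i]
    if scale <= 0.0 or not np.isfinite(scale):
        return False
    for j in range(p):
        s = A[j, j]
        for k in range(j):
            s -= L[j, k] * L[j, k]
        if s <= 1e-12 * scale:
            return False
        L[j, j] = np.sqrt(s)
        for i in range(j + 1, p):
            s = A[i, j]
            for k in range(j):
                s -= L[i, k] * L[j, k]
            L[i, j] = s / L[j, j]
    # forward then backward substitution
    y = np.zeros(p)
    for i in range(p):
        s = b[i]
        for k in range(i):
            s -= L[i, k] * y[k]
        y[i] = s / L[i, i]
    for i in range(p - 1, -1, -1):
        s = y[i]
        for k in range(i + 1, p):
            s -= L[k, i] * x[k]
        x[i] = s / L[i, i]
    return True


@njit(cache=True)
def _derivs_one(X, beta, eta, wrow, gstart, devents, grad, info, efron):
    """Log-likelihood, score and observed information for one model."""
    n, p = X.shape
    G = devents.shape[0]
    for i in range(n):
        s = 0.0
        for a in range(p):
            s += X[i, a] * beta[a]
        eta[i] = s
    shift = eta[0]
    for i in range(1, n):
        if eta[i] > shift:
            shift = eta[i]
    for i in range(n):
        wrow[i] = np.exp(eta[i] - shift)

    for a in range(p):
        grad[a] = 0.0
        for b in range(p):
            info[a, b] = 0.0
    ll = 0.0
    S0 = 0.0
    S1 = np.zeros(p)
    S2 = np.zeros((p, p))
    s1d = np.zeros(p)
    s2d = np.zeros((p, p))
    z = np.zeros(p)
    for g in range(G - 1, -1, -1):
        for i in range(gstart[g], gstart[g + 1]):
            w = wrow[i]
            S0 += w
            for a in range(p):
                xa = X[i, a]
                S1[a] += w * xa
                for b in range(a, p):
                    S2[a, b] += w * xa * X[i, b]
        dg = devents[g]
        if dg > 0:
            s0d = 0.0
            for a in range(p):
                s1d[a] = 0.0
                for b in range(p):
                    s2d[a, b] = 0.0
            for i in range(gstart[g], gstart[g] + dg):
                w = wrow[i]
                s0d += w
                ll += eta[i]
                for a in range(p):
                    xa = X[i, a]
                    grad[a] += xa
                    s1d[a] += w * xa
                    for b in range(a, p):
                        s2d[a, b] += w * xa * X[i, b]
            for l in range(dg):
                f = l / dg if efron else 0.0
                den = S0 - f * s0d
                ll -= np.log(den) + shift
                for a in range(p):
                    z[a] = (S1[a] - f * s1d[a]) / den
                    grad[a] -= z[a]
                for a in range(p):
                    for b in range(a, p):
                        info[a, b] += (S2[a, b] - f * s2d[a, b]) / den - z[a] * z[b]
    for a in range(p):
        for b in range(a + 1, p):
            info[b, a] = info[a, b]
    return ll


@njit(cache=True)
def newton_kernel_batch(Xs, d, gstart, devents, beta0, tol, max_iter, bound, efron):
    """Newton-Raphson with step-halving for K models sharing one cohort.

    Returns (beta, loglik, info, converged, failed, n_iter, max_score).
    """
    K, n, p = Xs.shape
    beta = beta0.copy()
    loglik = np.full(K, -np.inf)
    info = np.zeros((K, p, p))
    converged = np.zeros(K, dtype=np.uint8)
    failed = np.zeros(K, dtype=np.uint8)
    n_iter = np.zeros(K, dtype=np.int64)
    max_score = np.full(K, np.inf)

    eta = np.zeros(n)
    wrow = np.zeros(n)
    grad = np.zeros(p)
    delta = np.zeros(p)
    btry = np.zeros(p)

    for k in range(K):
        X = Xs[k]
        b = beta[k]
        inf_k = info[k]
        ll = _derivs_one(X, b, eta, wrow, gstart, devents, grad, inf_k, efron)
        for it in range(1, max_iter + 1):
            n_iter[k] = it
            loglik[k] = ll
            gmax = 0.0
            bad = not np.isfinite(ll)
            for a in range(p):
                ga = abs(grad[a])
                if not np.isfinite(ga):
                    bad = True
                elif ga > gmax:
                    gmax = ga
                if abs(b[a]) > bound:
                    bad = True
            max_score[k] = gmax if not bad else np.inf
            if bad:
                failed[k] = 1
                break
            if gmax < tol:
                converged[k] = 1
                break
            if not _cholesky_solve(inf_k, grad, delta):
                failed[k] = 1
                break
            # propose the Newton step; halve it while the likelihood worsens
            # (derivatives at the accepted point double as the next iterate's)
            step = 1.0
            ll_new = -np.inf
            for _ in range(40):
                for a in range(p):
                    btry[a] = b[a] + step * delta[a]
                ll_new = _derivs_one(X, btry, eta, wrow, gstart, devents, grad, inf_k, efron)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                    break
                step *= 0.5
            for a in range(p):
                b[a] = btry[a]
            ll = ll_new
    return beta, loglik, info, converged, failed, n_iter, max_score
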