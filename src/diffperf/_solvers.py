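"""Compiled coordinate-descent kernels.

Two solvers live here: a covariance-update lasso for the feature
selection stage (operates on the Gram matrix of a standardized design,
so a whole regularization path amortizes one ``X.T @ X``), and an
IRLS + weighted-coordinate-descent solver for L1-penalized logistic
regression. Both use cyclic coordinate descent with an active-set
strategy: sweep the active set to convergence, then one full pass to
admit violators, repeating until no coordinate moves.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NB = dict(cache=True, fastmath=False)


@njit(**NB)
def _soft(x: float, t: float) -> float:
    if x > t:
        return x - t
    if x < -t:
        return x + t
    return 0.0


@njit(**NB)
def _active_solve(G, c, lam, beta, active, grad):
    """Equality-constrained Newton step on the active set.

    Solves G_AA b = c_A - lam*s with s the current coefficient sign
    (gradient sign for coordinates sitting at zero); a tiny ridge keeps
    the system nonsingular. Coordinates whose solution flips against
    the guessed sign are left at zero but stay active. Pure
    acceleration: correctness is enforced by the cyclic sweeps and the
    KKT pass around it.
    """
    idx = np.flatnonzero(active)
    m = idx.shape[0]
    if m == 0 or m > 500:
        return
    sign = np.empty(m)
    keep = np.ones(m, dtype=np.bool_)
    for a in range(m):
        ja = idx[a]
        ref = beta[ja] if beta[ja] != 0.0 else grad[ja]
        sign[a] = 1.0 if ref > 0.0 else -1.0
    # drop sign-infeasible coordinates and re-solve until clean
    for _ in range(m):
        kidx = np.flatnonzero(keep)
        mk = kidx.shape[0]
        if mk == 0:
            break
        A = np.empty((mk, mk))
        b = np.empty(mk)
        for a in range(mk):
            ja = idx[kidx[a]]
            for bcol in range(mk):
                A[a, bcol] = G[ja, idx[kidx[bcol]]]
            A[a, a] += 1e-12
            b[a] = c[ja] - lam * sign[kidx[a]]
        sol = np.linalg.solve(A, b)
        flipped = False
        for a in range(mk):
            if sol[a] * sign[kidx[a]] <= 0.0:
                keep[kidx[a]] = False
                flipped = True
        if not flipped:
            for a in range(m):
                beta[idx[a]] = 0.0
            for a in range(mk):
                beta[idx[kidx[a]]] = sol[a]
            break


@njit(**NB)
def lasso_cd_gram(G, c, lam, beta, tol, max_iter):
    """Minimize (1/2n)||y - Xb||^2 + lam*||b||_1 on standardized data.

    G = X'X/n (diagonal 1 for standardized columns), c = X'y/n.
    ``beta`` is modified in place (warm start). Cyclic coordinate
    descent over the active set with an exact active-set solve as
    accelerator and a full KKT pass to admit violators. Returns the
    sweep count used, or -1 on non-convergence.
    """
    p = c.shape[0]
    active = np.zeros(p, dtype=np.bool_)
    for j in range(p):
        active[j] = beta[j] != 0.0
    grad = c - G @ beta  # residual correlations: X'r/n
    it = 0
    converged = False
    while it < max_iter:
        # admit KKT violators on the exact gradient
        changed = False
        for j in range(p):
            if not active[j] and G[j, j] > 0.0:
                if abs(grad[j]) > lam + 1e-12 or beta[j] != 0.0:
                    active[j] = True
                    changed = True
        if converged and not changed:
            return it
        # Newton step on the active set with backtracking: accept the
        # longest step along the solve direction that lowers the
        # objective (beta-dependent part: -c.b + 0.5 b'Gb + lam|b|_1)
        f_cur = (
            -np.dot(c, beta)
            + 0.5 * np.dot(beta, c - grad)
            + lam * np.abs(beta).sum()
        )
        beta_save = beta.copy()
        _active_solve(G, c, lam, beta, active, grad)
        d = beta - beta_save
        if np.any(d != 0.0):
            Gd = G @ d
            dGd = np.dot(d, Gd)
            g_d = np.dot(grad, d)  # grad is at beta_save here
            t = 1.0
            accepted = False
            for _ in range(12):
                f_t = (
                    f_cur
                    - t * g_d
                    + 0.5 * t * t * dGd
                    + lam * np.abs(beta_save + t * d).sum()
                    - lam * np.abs(beta_save).sum()
                )
                if f_t < f_cur:
                    beta[:] = beta_save + t * d
                    grad = grad - t * Gd
                    accepted = True
                    break
                t *= 0.5
            if not accepted:
                beta[:] = beta_save
        # cyclic sweeps over the active set (grad maintained on actives)
        idx = np.flatnonzero(active)
        delta = tol
        sweeps = 0
        while delta >= tol and sweeps < 5 and it < max_iter:
            delta = 0.0
            for a in range(idx.shape[0]):
                j = idx[a]
                gjj = G[j, j]
                if gjj <= 0.0:
                    continue
                old = beta[j]
                new = _soft(grad[j] + gjj * old, lam) / gjj
                if new != old:
                    d = new - old
                    beta[j] = new
                    for b in range(idx.shape[0]):
                        k = idx[b]
                        grad[k] -= G[k, j] * d
                    ad = abs(d)
                    if ad > delta:
                        delta = ad
            sweeps += 1
            it += 1
        converged = delta < tol
        grad = c - G @ beta  # exact gradient for the next violator pass
        it += 1
    return -1


@njit(**NB)
def lasso_path_gram(G, c, lambdas, tol, max_iter, ymss, dev_stop, max_support):
    """Warm-started path over a descending lambda grid.

    Returns (betas, status): betas has one row per lambda; status[i] is
    the iteration count or -1 for non-convergence at lambdas[i].

    ``ymss`` is mean(y_c^2). Once the training deviance ratio exceeds
    ``dev_stop`` or the support reaches ``max_support`` the fit is
    saturated and the remaining (smaller) lambdas inherit the current
    solution: past that point the path only interpolates noise and a
    CV criterion can never prefer it.
    """
    n_lam = lambdas.shape[0]
    p = c.shape[0]
    betas = np.zeros((n_lam, p))
    status = np.zeros(n_lam, dtype=np.int64)
    beta = np.zeros(p)
    for i in range(n_lam):
        status[i] = lasso_cd_gram(G, c, lambdas[i], beta, tol, max_iter)
        betas[i] = beta
        if ymss > 0.0:
            rss_n = ymss - 2.0 * np.dot(c, beta) + np.dot(beta, G @ beta)
            nnz = 0
            for j in range(p):
                if beta[j] != 0.0:
                    nnz += 1
            if 1.0 - rss_n / ymss >= dev_stop or nnz >= max_support:
                for k in range(i + 1, n_lam):
                    betas[k] = beta
                    status[k] = 0
                break
    return betas, status


@njit(**NB)
def wls_lasso_cd(X, z, w, lam, beta, b0, tol, max_iter):
    """Weighted lasso with unpenalized intercept.

    Minimizes (1/2n) sum_i w_i (z_i - b0 - x_i'b)^2 + lam*||b||_1.
    beta is warm-started in place; returns (b0, iters) with iters=-1 on
    non-convergence.
    """
    n, p = X.shape
    wsum = w.sum()
    eta = X @ beta
    r = z - b0 - eta  # working residual
    it = 0
    while it < max_iter:
        delta = 0.0
        # intercept (unpenalized)
        num = 0.0
        for i in range(n):
            num += w[i] * r[i]
        d0 = num / wsum
        b0 += d0
        r -= d0
        if abs(d0) > delta:
            delta = abs(d0)
        for j in range(p):
            wxx = 0.0
            wxr = 0.0
            for i in range(n):
                wxx += w[i] * X[i, j] * X[i, j]
                wxr += w[i] * X[i, j] * r[i]
            if wxx <= 0.0:
                continue
            old = beta[j]
            new = _soft(wxr / n + (wxx / n) * old, lam) / (wxx / n)
            if new != old:
                d = new - old
                beta[j] = new
                for i in range(n):
                    r[i] -= X[i, j] * d
                if abs(d) > delta:
                    delta = abs(d)
        it += 1
        if delta < tol:
            return b0, it
    return b0, -1


@njit(**NB)
def logistic_l1_irls(X, y, lam, tol, max_iter):
    """L1-penalized logistic regression by IRLS over weighted lasso.

    Minimizes -(1/n) loglik + lam*||b||_1 (intercept unpenalized).
    Returns (b0, beta, converged flag). Weights are clipped below at
    1e-5 to keep the working response finite.
    """
    n, p = X.shape
    beta = np.zeros(p)
    ybar = y.mean()
    if ybar <= 0.0 or ybar >= 1.0:
        return 0.0, beta, False
    b0 = np.log(ybar / (1.0 - ybar))
    for _ in range(max_iter):
        eta = b0 + X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        w = mu * (1.0 - mu)
        z = np.empty(n)
        for i in range(n):
            wi = w[i]
            if wi < 1e-5:
                wi = 1e-5
                w[i] = wi
            z[i] = eta[i] + (y[i] - mu[i]) / wi
        b0_old = b0
        beta_old = beta.copy()
        b0, ok = wls_lasso_cd(X, z, w, lam, beta, b0, tol * 0.1, 1000)
        delta = abs(b0 - b0_old)
        for j in range(p):
            d = abs(beta[j] - beta_old[j])
            if d > delta:
                delta = d
        if delta < tol:
            # reject runs that are diverging toward separation
            if np.abs(b0 + X @ beta).max() > 100.0:
                return b0, beta, False
            return b0, beta, True
    return b0, beta, False
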