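"""Numba-compiled inner loops: Gibbs sampling and the lasso-logistic path.

Both routines sit in hot paths — bootstrap stability and permutation
comparisons re-estimate the network tens of thousands of times, and the
intervention simulation draws one Gibbs chain per simulated respondent —
so they are JIT-compiled.  The path solver is a glmnet-style coordinate
descent (IRLS outer loop, soft-threshold inner loop, warm starts along a
decreasing λ grid); its solutions are cross-checked against
scikit-learn's saga solver in the test suite.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["gibbs_states", "lasso_logistic_path", "refit_mle"]


@njit(cache=False)
def _sigmoid(x):
    if x >= 0.0:
        return 1.0 / (1.0 + np.exp(-x))
    e = np.exp(x)
    return e / (1.0 + e)


@njit(cache=False)
def gibbs_states(W, tau, n_chains, burn_in, seed):
    """Draw one {0,1}^p state per independent chain.

    Each chain starts from fair-coin initial states and runs ``burn_in``
    fixed-order sweeps of the single-site conditional

        P(x_i = 1 | x_-i) = logistic(tau_i + sum_j W_ij x_j);

    the state after the last sweep is retained.  Chains are independent,
    so rows model exchangeable respondents.
    """
    p = tau.shape[0]
    np.random.seed(seed)
    out = np.empty((n_chains, p), dtype=np.int8)
    for c in range(n_chains):
        x = np.empty(p, dtype=np.int8)
        for i in range(p):
            x[i] = 1 if np.random.random() < 0.5 else 0
        for _ in range(burn_in):
            for i in range(p):
                field = tau[i]
                for j in range(p):
                    if x[j] == 1:
                        field += W[i, j]
                x[i] = 1 if np.random.random() < _sigmoid(field) else 0
        out[c] = x
    return out


@njit(cache=False)
def _loglik(eta, y, counts):
    """Bernoulli log-likelihood Σ c_i [y η − log(1+e^η)], numerically stable."""
    ll = 0.0
    for i in range(eta.shape[0]):
        e = eta[i]
        if e > 0.0:
            ll += counts[i] * (y[i] * e - (e + np.log1p(np.exp(-e))))
        else:
            ll += counts[i] * (y[i] * e - np.log1p(np.exp(e)))
    return ll


@njit(cache=False)
def _sweep(beta, b0_box, s, w, wsum, a, col_ptr, col_rows, lam, n, active_only):
    """One coordinate-descent pass; returns the largest update magnitude.

    ``active_only`` restricts the pass to currently-nonzero coefficients
    (glmnet-style active-set cycling); a full pass re-screens all
    coordinates.  Binary predictors let each coordinate touch only the
    rows where x_ij = 1 (indexed by col_ptr/col_rows).
    """
    p = beta.shape[0]
    step = 0.0
    # unpenalized intercept
    num = 0.0
    for i in range(s.shape[0]):
        num += w[i] * s[i]
    d = num / wsum
    if abs(d) > step:
        step = abs(d)
    b0_box[0] += d
    for i in range(s.shape[0]):
        s[i] -= d
    for j in range(p):
        if active_only and beta[j] == 0.0:
            continue
        aj = a[j]
        if aj <= 0.0:
            continue
        gj = 0.0
        for k in range(col_ptr[j], col_ptr[j + 1]):
            gj += w[col_rows[k]] * s[col_rows[k]]
        u = (gj + aj * beta[j]) / n
        if u > lam:
            bnew = (u - lam) * n / aj
        elif u < -lam:
            bnew = (u + lam) * n / aj
        else:
            bnew = 0.0
        d = bnew - beta[j]
        if d != 0.0:
            if abs(d) > step:
                step = abs(d)
            beta[j] = bnew
            for k in range(col_ptr[j], col_ptr[j + 1]):
                s[col_rows[k]] -= d
    return step


@njit(cache=False)
def lasso_logistic_path(X, y, counts, n_total, lambdas, max_outer, max_inner,
                        tol, coef_bound):
    """ℓ1-penalized logistic regression along a decreasing λ path.

    Minimizes (1/n) Σ [log(1+exp(η)) − y η] + λ ||β||₁ with an
    unpenalized intercept, by iteratively reweighted least squares with
    coordinate-wise soft-thresholding, warm-starting each λ at the
    previous solution.  Predictors are assumed binary {0,1}.

    Rows may be collapsed to unique (y, x) patterns with multiplicities
    ``counts`` (Σ counts = ``n_total``), which is exact for binary data
    and is how the callers keep small-p bootstrap and permutation loops
    cheap.

    Returns ``(coefs [L×p], intercepts [L], logliks [L], n_valid)``.
    ``n_valid < L`` flags early termination of the path because a
    coefficient magnitude exceeded ``coef_bound`` (quasi-separation
    guard); path entries at and beyond ``n_valid`` stay NaN.
    """
    n_rows, p = X.shape
    n = n_total
    L = lambdas.shape[0]
    coefs = np.full((L, p), np.nan)
    intercepts = np.full(L, np.nan)
    logliks = np.full(L, np.nan)

    # column-wise indices of the rows with x_ij = 1
    nnz = 0
    col_ptr = np.empty(p + 1, dtype=np.int64)
    col_ptr[0] = 0
    for j in range(p):
        cnt = 0
        for i in range(n_rows):
            if X[i, j] != 0.0:
                cnt += 1
        nnz += cnt
        col_ptr[j + 1] = nnz
    col_rows = np.empty(nnz, dtype=np.int64)
    for j in range(p):
        k = col_ptr[j]
        for i in range(n_rows):
            if X[i, j] != 0.0:
                col_rows[k] = i
                k += 1

    beta = np.zeros(p)
    ysum = 0.0
    for i in range(n_rows):
        ysum += counts[i] * y[i]
    ybar = ysum / n
    b0_box = np.empty(1)
    b0_box[0] = np.log(ybar / (1.0 - ybar))
    eta = np.full(n_rows, b0_box[0])
    n_valid = L

    w = np.empty(n_rows)
    s = np.empty(n_rows)
    a = np.empty(p)
    for l in range(L):
        lam = lambdas[l]
        for _outer in range(max_outer):
            # IRLS linearization at current eta; s tracks z − b0 − Xβ,
            # which equals (y − p)/w̃ at the start of the inner solve;
            # w folds the pattern multiplicities into the IRLS weights
            for i in range(n_rows):
                pr = _sigmoid(eta[i])
                wi = pr * (1.0 - pr)
                if wi < 1e-6:
                    wi = 1e-6
                w[i] = counts[i] * wi
                s[i] = (y[i] - pr) / wi
            wsum = w.sum()
            for j in range(p):
                aj = 0.0
                for k in range(col_ptr[j], col_ptr[j + 1]):
                    aj += w[col_rows[k]]
                a[j] = aj
            first_step = -1.0
            inner = 0
            while inner < max_inner:
                step = _sweep(beta, b0_box, s, w, wsum, a, col_ptr, col_rows,
                              lam, n, False)
                inner += 1
                if first_step < 0.0:
                    first_step = step
                if step < tol:
                    break
                while inner < max_inner:
                    astep = _sweep(beta, b0_box, s, w, wsum, a, col_ptr,
                                   col_rows, lam, n, True)
                    inner += 1
                    if astep < tol:
                        break
            # eta = z − s with z fixed during the inner solve
            for i in range(n_rows):
                eta[i] = eta[i] + counts[i] * (y[i] - _sigmoid(eta[i])) / w[i] - s[i]
            if first_step < tol:
                break
        bmax = 0.0
        for j in range(p):
            if abs(beta[j]) > bmax:
                bmax = abs(beta[j])
        if bmax > coef_bound or abs(b0_box[0]) > coef_bound:
            n_valid = l
            break
        coefs[l] = beta
        intercepts[l] = b0_box[0]
        logliks[l] = _loglik(eta, y, counts)
    return coefs, intercepts, logliks, n_valid


@njit(cache=False)
def refit_mle(X, y, counts, n_total, support, max_iter, tol, coef_bound):
    """Unpenalized logistic MLE restricted to ``support`` (Newton–Raphson).

    Operates on collapsed unique rows with multiplicities, like
    :func:`lasso_logistic_path`.  Returns ``(beta_support, intercept,
    loglik, converged)``; on quasi-separation (a coefficient passing
    ``coef_bound``) iteration stops early and the current iterate is
    returned with ``converged = False``.
    """
    m = X.shape[0]
    k = support.shape[0]
    d = k + 1
    theta = np.zeros(d)  # [intercept, beta_support...]
    ysum = 0.0
    for i in range(m):
        ysum += counts[i] * y[i]
    ybar = ysum / n_total
    theta[0] = np.log(ybar / (1.0 - ybar))
    eta = np.empty(m)
    converged = False
    for _it in range(max_iter):
        for i in range(m):
            e = theta[0]
            for j in range(k):
                if X[i, support[j]] != 0.0:
                    e += theta[j + 1]  # binary predictors: x ∈ {0,1}
            eta[i] = e
        grad = np.zeros(d)
        H = np.zeros((d, d))
        for i in range(m):
            pr = _sigmoid(eta[i])
            w = counts[i] * pr * (1.0 - pr)
            r = counts[i] * (y[i] - pr)
            grad[0] += r
            H[0, 0] += w
            for j in range(k):
                if X[i, support[j]] != 0.0:
                    grad[j + 1] += r
                    H[0, j + 1] += w
                    H[j + 1, 0] += w
                    for j2 in range(k):
                        if X[i, support[j2]] != 0.0:
                            H[j + 1, j2 + 1] += w
        # ridge jitter keeps the solve well-posed near separation
        for j in range(d):
            H[j, j] += 1e-10
        step = np.linalg.solve(H, grad)
        theta += step
        bmax = 0.0
        for j in range(d):
            if abs(theta[j]) > bmax:
                bmax = abs(theta[j])
        if bmax > coef_bound:
            break
        smax = 0.0
        for j in range(d):
            if abs(step[j]) > smax:
                smax = abs(step[j])
        if smax < tol:
            converged = True
            break
    for i in range(m):
        e = theta[0]
        for j in range(k):
            if X[i, support[j]] != 0.0:
                e += theta[j + 1]
        eta[i] = e
    ll = _loglik(eta, y, counts)
    return theta[1:], theta[0], ll, converged
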