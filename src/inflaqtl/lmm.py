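"""Linear mixed models with one genetic random effect, fit by spectral decomposition.

The model for one response vector (one gene, one design) is

    y = X beta + u + e,   u ~ N(0, sg2 * K),   e ~ N(0, se2 * I)

with K a sample-by-sample genetic similarity (kinship) matrix.  Writing
lambda = sg2/se2 and K = U D U', the rotated data U'y, U'X have diagonal
covariance se2 * (lambda*D + I), so for each candidate lambda the fit is a
weighted least squares and the restricted likelihood can be profiled over
lambda alone.  lambda is maximized on a log-spaced grid refined by bounded
Brent search; fixed effects are then tested with Wald t statistics on
n - rank(X) degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["LMMFit", "SpectralKinship", "fit_lmm", "fit_lmm_rotated", "gls_oracle", "bh_fdr"]

# lambda = sg2/se2 search grid (log10 bounds) and Brent relative tolerance
_LOG10_LO, _LOG10_HI = -5.0, 5.0
_N_GRID = 21
_BRENT_RTOL = 1e-6


@dataclass
class LMMFit:
    """Result of one mixed-model fit.

    beta/se/wald_t/p are aligned with the columns of the design matrix;
    variance_ratio is the REML estimate of sg2/se2.
    """

    beta: np.ndarray
    se: np.ndarray
    wald_t: np.ndarray
    p: np.ndarray
    variance_ratio: float
    sigma_e2: float
    log_restricted_likelihood: float
    df_residual: int
    columns: list = field(default_factory=list)


class SpectralKinship:
    """Eigendecomposition of a kinship matrix, reusable across many fits.

    Decomposing K once and rotating every response/design into the eigenbasis
    is what makes genome-wide scans affordable: each gene-SNP fit then costs
    one weighted least squares per candidate variance ratio.
    """

    def __init__(self, K: np.ndarray, sample_ids=None):
        K = np.asarray(K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kinship matrix must be square")
        if not np.allclose(K, K.T, atol=1e-8):
            raise ValueError("kinship matrix must be symmetric")
        d, U = np.linalg.eigh(K)
        if d.min() < -1e-6:
            raise ValueError(
                f"kinship matrix is not positive semidefinite (min eigenvalue {d.min():.3g}); "
                "apply a ridge before fitting"
            )
        self.d = np.clip(d, 0.0, None)
        self.U = U
        self.n = K.shape[0]
        self.sample_ids = list(sample_ids) if sample_ids is not None else None

    def rotate(self, A: np.ndarray) -> np.ndarray:
        """Return U' A (rows of A must follow the kinship sample order)."""
        return self.U.T @ np.asarray(A, dtype=float)


def _check_full_rank(X: np.ndarray) -> None:
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns for the error message
        bad = []
        _, R, piv = _qr_pivot(X)
        thresh = np.abs(R[0, 0]) * max(X.shape) * np.finfo(float).eps
        for k in range(p):
            if k >= R.shape[0] or abs(R[k, k]) <= thresh:
                bad.append(int(piv[k]))
        raise ValueError(f"design matrix is rank deficient (collinear columns: {sorted(bad)})")


def _qr_pivot(X):
    from scipy.linalg import qr

    Q, R, piv = qr(X, mode="economic", pivoting=True)
    return Q, R, piv


def _profile(lam: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray):
    """Profiled REML pieces at a given variance ratio lambda.

    Returns (restricted log-likelihood, beta, sigma_e2, X'W^-1 X cholesky).
    """
    n, p = Xt.shape
    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    XtWX = Xt.T @ Xw
    XtWy = Xw.T @ yt
    c = cho_factor(XtWX, lower=True)
    beta = cho_solve(c, XtWy)
    resid = yt - Xt @ beta
    rss = float(np.sum(resid * resid / w))
    nu = n - p
    var_floor = 1e-10 * max(float(np.var(yt)), np.finfo(float).tiny)
    sigma_e2 = max(rss / nu, var_floor)
    logdet_w = float(np.sum(np.log(w)))
    logdet_XtWX = 2.0 * float(np.sum(np.log(np.diag(c[0]))))
    ll = -0.5 * (nu * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + logdet_w + logdet_XtWX)
    return ll, beta, sigma_e2, c


def _profile_grid(grid: np.ndarray, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> np.ndarray:
    """Restricted log-likelihood at every grid lambda, batched over the grid."""
    n, p = Xt.shape
    nu = n - p
    w = grid[:, None] * d[None, :] + 1.0  # (L, n)
    Xw = Xt[None, :, :] / w[:, :, None]  # (L, n, p)
    XtWX = np.matmul(Xt.T[None, :, :], Xw)  # (L, p, p)
    XtWy = np.matmul(Xw.transpose(0, 2, 1), yt)  # (L, p)
    chol = np.linalg.cholesky(XtWX)
    beta = np.linalg.solve(XtWX, XtWy[:, :, None])
    resid = yt[None, :] - np.matmul(Xt[None, :, :], beta)[:, :, 0]
    rss = np.sum(resid * resid / w, axis=1)
    var_floor = 1e-10 * max(float(np.var(yt)), np.finfo(float).tiny)
    sigma_e2 = np.maximum(rss / nu, var_floor)
    logdet_w = np.sum(np.log(w), axis=1)
    logdet_XtWX = 2.0 * np.sum(np.log(np.diagonal(chol, axis1=1, axis2=2)), axis=1)
    return -0.5 * (nu * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + logdet_w + logdet_XtWX)


def fit_lmm_rotated(yt: np.ndarray, Xt: np.ndarray, d: np.ndarray, columns=None) -> LMMFit:
    """Fit the LMM given already-rotated response/design and kinship eigenvalues.

    This is the inner engine used by the scan modules, which rotate whole
    matrices once per dataset instead of once per fit.
    """
    yt = np.asarray(yt, dtype=float)
    Xt = np.asarray(Xt, dtype=float)
    n, p = Xt.shape
    if n <= p:
        raise ValueError(f"need more samples ({n}) than covariates ({p})")
    _check_full_rank(Xt)

    grid = np.concatenate([[0.0], np.logspace(_LOG10_LO, _LOG10_HI, _N_GRID)])
    lls = _profile_grid(grid, d, yt, Xt)
    best = int(np.argmax(lls))
    lam_hat = grid[best]
    ll_hat = lls[best]

    # refine interior optima between the neighbouring grid points (log scale)
    if 0 < best < grid.size - 1:
        lo = np.log10(grid[best - 1]) if grid[best - 1] > 0 else _LOG10_LO - 1.0
        hi = np.log10(grid[best + 1])
        res = optimize.minimize_scalar(
            lambda t: -_profile(10.0**t, d, yt, Xt)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": _BRENT_RTOL},
        )
        if -res.fun >= ll_hat:
            lam_hat = 10.0 ** float(res.x)
            ll_hat = float(-res.fun)

    ll, beta, sigma_e2, c = _profile(lam_hat, d, yt, Xt)
    cov = sigma_e2 * cho_solve(c, np.eye(p))
    se = np.sqrt(np.diag(cov))
    t = beta / se
    nu = n - p
    pvals = 2.0 * stats.t.sf(np.abs(t), df=nu)
    return LMMFit(
        beta=beta,
        se=se,
        wald_t=t,
        p=pvals,
        variance_ratio=float(lam_hat),
        sigma_e2=float(sigma_e2),
        log_restricted_likelihood=float(ll),
        df_residual=int(nu),
        columns=list(columns) if columns is not None else [f"x{i}" for i in range(p)],
    )


def fit_lmm(y, X, K, columns=None) -> LMMFit:
    """REML fit of y = X beta + u + e with u ~ N(0, sg2 K), e ~ N(0, se2 I).

    Parameters
    ----------
    y : (n,) response (one gene's expression across samples).
    X : (n, p) fixed-effect design including the intercept.
    K : kinship as an (n, n) array or a precomputed :class:`SpectralKinship`.
    columns : optional design column names carried into the fit object.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if y.shape[0] != X.shape[0]:
        raise ValueError("y and X have different numbers of samples")
    sk = K if isinstance(K, SpectralKinship) else SpectralKinship(K)
    if sk.n != y.shape[0]:
        raise ValueError("kinship dimension does not match y")
    return fit_lmm_rotated(sk.rotate(y), sk.rotate(X), sk.d, columns=columns)


def gls_oracle(y, X, V):
    """Closed-form generalized least squares with known covariance V.

    beta = (X' V^-1 X)^-1 X' V^-1 y; standard errors from the inverse
    information.  Used as an independent correctness oracle in tests.
    """
    y = np.asarray(y, dtype=float).ravel()
    X = np.asarray(X, dtype=float)
    V = np.asarray(V, dtype=float)
    if not np.allclose(V, V.T, atol=1e-8):
        raise ValueError("V must be symmetric")
    try:
        cV = cho_factor(V, lower=True)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - scipy raises LinAlgError
        raise ValueError("V is singular or not positive definite") from exc
    Vinv_X = cho_solve(cV, X)
    Vinv_y = cho_solve(cV, y)
    info = X.T @ Vinv_X
    cI = cho_factor(info, lower=True)
    beta = cho_solve(cI, X.T @ Vinv_y)
    cov = cho_solve(cI, np.eye(X.shape[1]))
    return beta, np.sqrt(np.diag(cov))


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    NaN entries are passed through untouched and do not count toward the
    number of tests.
    """
    p = np.asarray(p, dtype=float)
    shape = p.shape
    p = p.ravel()
    q = np.full(p.size, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    if pv.size and (pv.min() < 0 or pv.max() > 1):
        raise ValueError("p-values must lie in [0, 1]")
    m = pv.size
    if m:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * m / np.arange(1, m + 1)
        # enforce monotonicity from the largest p down, cap at 1
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(m)
        out[order] = np.minimum(adj, 1.0)
        q[ok] = out
    return q.reshape(shape)
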