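"""Vectorized fitting and testing across many phenotypes at once.

Massively univariate analysis (one model per voxel) and Monte-Carlo
simulation (one model per replicate) share the same computational shape:
the design ``X*`` and eigenvalues ``lambda_g`` are fixed while thousands of
phenotype columns vary.  The functions here operate on an (N, V) phenotype
matrix and reproduce the univariate pipeline in :mod:`kinherit.model` /
:mod:`kinherit.stats` column by column (asserted to 1e-10 by the test
suite), using BLAS-level matrix products instead of Python loops.

The permutation engine exploits a common structure of schemes P1-P4: for
every scheme the surrogate statistic depends on the data only through a
"base" residual vector that is row-permuted and then re-analyzed, because
the add-back of fixed effects is annihilated by the refit.  One (N, V)
gather plus one projection per permutation therefore covers all columns.
"""

from __future__ import annotations

import numpy as np
from scipy import stats as sps

from .model import SIGMA_E_FLOOR, IdentifiabilityError

__all__ = [
    "batch_ols",
    "batch_theta",
    "batch_h2",
    "batch_ml",
    "batch_statistic",
    "batch_parametric_p",
    "batch_permutation",
]


def _as_matrix(Y: np.ndarray) -> np.ndarray:
    Y = np.asarray(Y, float)
    return Y[:, None] if Y.ndim == 1 else Y


def batch_ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS coefficients (p, V) and residuals (N, V) for every column."""
    Y = _as_matrix(Y)
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    return beta, Y - X @ beta


def _floor(theta: np.ndarray, y_var: np.ndarray) -> np.ndarray:
    floor = SIGMA_E_FLOOR * np.maximum(y_var, 1.0)
    theta[1] = np.maximum(theta[1], floor)
    return theta


def batch_theta(
    f: np.ndarray, lam: np.ndarray, weights: np.ndarray | None = None
) -> np.ndarray:
    """Projected regression of squared residuals on [1, lambda], per column.

    Returns theta = (sigma_A^2, sigma_E^2) as a (2, V) array.  ``weights``
    is an (N, V) per-observation weight matrix (Sigma*^-2 for Newton
    steps) or None for the unweighted OLS start.
    """
    f = _as_matrix(f)
    if np.ptp(lam) < 1e-12:
        raise IdentifiabilityError("all eigenvalues equal")
    if weights is None:
        n = lam.shape[0]
        lc = lam - lam.mean()
        slope = (lc @ f) / (lc @ lc)
        intercept = f.mean(axis=0) - slope * lam.mean()
    else:
        a00 = weights.sum(axis=0)
        a01 = lam @ weights
        a11 = (lam**2) @ weights
        r0 = (weights * f).sum(axis=0)
        r1 = lam @ (weights * f)
        det = a00 * a11 - a01**2
        slope = (a00 * r1 - a01 * r0) / det
        intercept = (a11 * r0 - a01 * r1) / det
    theta = np.vstack([np.maximum(0.0, slope), np.maximum(0.0, intercept)])
    return theta


def batch_h2(theta: np.ndarray) -> np.ndarray:
    total = theta.sum(axis=0)
    out = np.zeros(theta.shape[1])
    pos = total > 0
    out[pos] = theta[0, pos] / total[pos]
    return out


def _batch_wls(
    Y: np.ndarray, X: np.ndarray, lam: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Newton step from OLS: returns (theta_wls, theta_ols, f_ols)."""
    _, resid = batch_ols(Y, X)
    f = resid**2
    y_var = Y.var(axis=0)
    theta0 = _floor(batch_theta(f, lam), y_var)
    s2 = np.outer(lam, theta0[0]) + theta0[1]
    theta1 = _floor(batch_theta(f, lam, weights=1.0 / s2**2), y_var)
    return theta1, theta0, f


def _beta_solve(X: np.ndarray, Y: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Per-column weighted LS solve; beta returned as (V, p)."""
    A = np.einsum("np,nv,nq->vpq", X, w, X, optimize=True)
    b = np.einsum("np,nv->vp", X, w * Y, optimize=True)
    return np.linalg.solve(A, b[..., None])[..., 0]


def _batch_loglik(f: np.ndarray, s2: np.ndarray) -> np.ndarray:
    n = f.shape[0]
    return -0.5 * (n * np.log(2 * np.pi) + np.log(s2).sum(axis=0) + (f / s2).sum(axis=0))


def batch_ml(
    Y: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> dict:
    """Iterated Newton (ML) fit for every column.

    Returns a dict with ``theta`` (2, V), ``beta`` (V, p), ``loglik`` (V,),
    ``converged`` (V,) and ``n_iter``.  All columns are iterated together;
    a column's convergence is judged on its own log-likelihood change.
    """
    Y = _as_matrix(Y)
    V = Y.shape[1]
    y_var = Y.var(axis=0)
    beta_v, resid = batch_ols(Y, X)
    theta = _floor(batch_theta(resid**2, lam), y_var)
    s2 = np.outer(lam, theta[0]) + theta[1]
    ll = _batch_loglik(resid**2, s2)
    beta = beta_v.T
    converged = np.zeros(V, dtype=bool)
    active = np.ones(V, dtype=bool)
    it = 0
    # converged columns are frozen so each column reproduces exactly the
    # univariate iteration path (same stopping iterate)
    for it in range(1, max_iter + 1):
        idx = np.flatnonzero(active)
        Ya = Y[:, idx]
        s2a = s2[:, idx]
        w = 1.0 / s2a
        beta_a = _beta_solve(X, Ya, w)
        resid_a = Ya - X @ beta_a.T
        f = resid_a**2
        theta_a = batch_theta(f, lam, weights=w**2)
        # KKT face re-solve when a component clips to zero (see model.fit)
        on_A = theta_a[0] == 0.0
        if on_A.any():
            theta_a[1, on_A] = f[:, on_A].mean(axis=0)
        on_E = (~on_A) & (theta_a[1] == 0.0)
        if on_E.any():
            wl = w[:, on_E] ** 2 * lam[:, None]
            theta_a[0, on_E] = (wl * f[:, on_E]).sum(axis=0) / (wl * lam[:, None]).sum(axis=0)
        theta_a = _floor(theta_a, y_var[idx])
        s2a = np.outer(lam, theta_a[0]) + theta_a[1]
        ll_a = _batch_loglik(f, s2a)
        done = np.abs(ll_a - ll[idx]) < tol
        beta[idx] = beta_a
        resid[:, idx] = resid_a
        theta[:, idx] = theta_a
        s2[:, idx] = s2a
        ll[idx] = ll_a
        converged[idx[done]] = True
        active[idx[done]] = False
        if not active.any():
            break
    return {
        "theta": theta,
        "beta": beta,
        "loglik": ll,
        "converged": converged,
        "n_iter": it,
        "resid": resid,
    }


def _gq_projectors(X: np.ndarray, lam: np.ndarray) -> dict:
    idx_A = np.flatnonzero(lam > 1.0)
    idx_B = np.flatnonzero(lam <= 1.0)
    p = X.shape[1]
    if len(idx_A) <= p or len(idx_B) <= p:
        raise ValueError("GQ groups too small")
    proj = {}
    for name, idx in (("A", idx_A), ("B", idx_B)):
        Xg = X[idx]
        M = np.eye(len(idx)) - Xg @ np.linalg.pinv(Xg)
        proj[name] = (idx, M, len(idx) - p)
    return proj


def batch_statistic(
    Y: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    kind: str,
    ddof: str = "p",
    tol: float = 1e-8,
    max_iter: int = 200,
) -> np.ndarray:
    """The chosen test statistic for every phenotype column."""
    Y = _as_matrix(Y)
    kind = kind.lower().replace("-", "_")
    n = Y.shape[0]

    if kind == "score":
        _, resid = batch_ols(Y, X)
        f = resid**2
        sig2 = f.mean(axis=0)
        lc = lam - lam.mean()
        s_ll = float(lc @ lc)
        sA2 = np.maximum(0.0, (lc @ f) / s_ll)
        T = np.zeros(Y.shape[1])
        ok = sig2 > 0
        T[ok] = 0.5 * (sA2[ok] / sig2[ok]) ** 2 * s_ll
        return T

    if kind == "gq":
        proj = _gq_projectors(X, lam)
        idx_A, M_A, df_A = proj["A"]
        idx_B, M_B, df_B = proj["B"]
        rss_A = ((M_A @ Y[idx_A]) ** 2).sum(axis=0)
        rss_B = ((M_B @ Y[idx_B]) ** 2).sum(axis=0)
        if ddof == "p":
            return (rss_A / df_A) / (rss_B / df_B)
        return (rss_A / (len(idx_A) - 1)) / (rss_B / (len(idx_B) - 1))

    if kind == "wald_wls":
        theta1, theta0, _ = _batch_wls(Y, X, lam)
        s2 = np.outer(lam, theta0[0]) + theta0[1]
        w = 1.0 / s2**2
        a00 = w.sum(axis=0)
        a01 = lam @ w
        a11 = (lam**2) @ w
        contrast = a11 - a01**2 / a00
        return 0.5 * theta1[0] ** 2 * contrast

    if kind == "wald_ml":
        res = batch_ml(Y, X, lam, tol=tol, max_iter=max_iter)
        theta = res["theta"]
        s2 = np.outer(lam, theta[0]) + theta[1]
        w = 1.0 / s2**2
        contrast = (lam**2) @ w - (lam @ w) ** 2 / w.sum(axis=0)
        return 0.5 * theta[0] ** 2 * contrast

    if kind in ("lrt_ml", "lrt_wls"):
        _, resid0 = batch_ols(Y, X)
        f0 = resid0**2
        sig2 = np.maximum(f0.mean(axis=0), SIGMA_E_FLOOR)
        ll_null = -0.5 * (n * np.log(2 * np.pi) + n * np.log(sig2) + n)
        if kind == "lrt_ml":
            res = batch_ml(Y, X, lam, tol=tol, max_iter=max_iter)
            ll_alt = res["loglik"]
        else:
            theta1, theta0, _ = _batch_wls(Y, X, lam)
            y_var = Y.var(axis=0)
            theta1 = _floor(theta1, y_var)
            s2_0 = np.outer(lam, theta0[0]) + theta0[1]
            beta1 = _beta_solve(X, Y, 1.0 / s2_0)
            resid1 = Y - X @ beta1.T
            s2_1 = np.outer(lam, theta1[0]) + theta1[1]
            ll_alt = _batch_loglik(resid1**2, s2_1)
        return np.maximum(0.0, 2.0 * (ll_alt - ll_null))

    raise ValueError(f"unknown test kind {kind!r}")


def batch_parametric_p(
    T: np.ndarray, kind: str, X: np.ndarray | None = None, lam: np.ndarray | None = None
) -> np.ndarray:
    """Parametric p-values for a vector of statistics of one kind."""
    kind = kind.lower().replace("-", "_")
    if kind == "gq":
        if X is None or lam is None:
            raise ValueError("GQ p-values need X and lam for the df")
        p_cov = X.shape[1]
        n_A = int(np.count_nonzero(lam > 1.0))
        n_B = lam.shape[0] - n_A
        return sps.f.sf(T, n_A - p_cov, n_B - p_cov)
    p = np.ones_like(np.asarray(T, float))
    pos = T > 0
    p[pos] = 0.5 * sps.chi2.sf(T[pos], df=1)
    return p


def _base_residuals(Y, X, lam, scheme, estimator, tol, max_iter):
    """Residual matrix whose row permutations generate the null surrogates."""
    scheme = scheme.upper()
    if scheme in ("P1", "P2"):
        _, resid = batch_ols(Y, X)
        return resid
    if estimator == "ml":
        res = batch_ml(Y, X, lam, tol=tol, max_iter=max_iter)
        theta, resid = res["theta"], res["resid"]
    else:
        theta1, theta0, _ = _batch_wls(Y, X, lam)
        s2_0 = np.outer(lam, theta0[0]) + theta0[1]
        beta1 = _beta_solve(X, Y, 1.0 / s2_0)
        resid = Y - X @ beta1.T
        theta = theta1
    if scheme == "P3":
        return resid
    if scheme == "P4":
        s2 = np.outer(lam, theta[0]) + np.maximum(theta[1], SIGMA_E_FLOOR)
        return resid / np.sqrt(s2)
    raise ValueError(f"unknown scheme {scheme!r}")


def batch_permutation(
    Y: np.ndarray,
    X: np.ndarray,
    lam: np.ndarray,
    kind: str = "score",
    scheme: str = "P2",
    m: int = 500,
    seed: int | np.random.Generator = 0,
    per_column_perms: bool = False,
    estimator: str = "wls",
    ddof: str = "p",
    include_identity: bool = True,
    return_perm_stats: bool = False,
    tol: float = 1e-8,
    max_iter: int = 200,
) -> dict:
    """Permutation inference for every phenotype column at once.

    With ``per_column_perms=False`` a single permutation sequence is shared
    by all columns -- required when the columns are voxels of one image and
    the maximum statistic over columns feeds FWE correction.  With
    ``per_column_perms=True`` each column draws its own sequence, the right
    choice when columns are independent simulation replicates.

    Returns a dict with ``observed`` (V,), ``p_perm`` (V,), ``max_stats``
    (m,) and optionally ``perm_stats`` (m, V).
    """
    Y = _as_matrix(Y)
    n, V = Y.shape
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scheme = scheme.upper()

    observed = batch_statistic(Y, X, lam, kind, ddof=ddof, tol=tol, max_iter=max_iter)
    R = _base_residuals(Y, X, lam, scheme, estimator, tol, max_iter)

    count = np.zeros(V)
    max_stats = np.empty(m)
    perm_stats = np.empty((m, V)) if return_perm_stats else None
    arange_cols = np.arange(V)
    base_idx = np.broadcast_to(np.arange(n)[:, None], (n, V))

    for b in range(m):
        identity = include_identity and b == 0
        if identity and scheme != "P4":
            # the identity surrogate is the data itself; reuse the observed
            # statistic exactly so ties are counted without rounding noise
            stats_b = observed
        elif scheme == "P1":
            lam_b = lam[rng.permutation(n)]
            stats_b = batch_statistic(
                Y, X, lam_b, kind, ddof=ddof, tol=tol, max_iter=max_iter
            )
        else:
            if identity:
                E = R
            elif per_column_perms:
                idx = rng.permuted(base_idx, axis=0)
                E = R[idx, arange_cols]
            else:
                E = R[rng.permutation(n)]
            stats_b = batch_statistic(
                E, X, lam, kind, ddof=ddof, tol=tol, max_iter=max_iter
            )
        count += stats_b >= observed
        max_stats[b] = stats_b.max()
        if return_perm_stats:
            perm_stats[b] = stats_b
    p_perm = count / m
    if include_identity:
        p_perm = np.clip(p_perm, 1.0 / m, 1.0)
    out = {"observed": observed, "p_perm": p_perm, "max_stats": max_stats}
    if return_perm_stats:
        out["perm_stats"] = perm_stats
    return out
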