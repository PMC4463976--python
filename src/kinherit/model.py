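"""The eigensimplified polygenic model and its OLS / one-step WLS / ML fits.

The polygenic model for a phenotype on N family members is

    Y = X beta + g + e,     Var(Y) = sigma_A^2 * 2*Phi + sigma_E^2 * I,

with ``g`` the latent additive genetic effect.  Rotating data and design by
the eigenvectors ``S`` of the kinship matrix gives ``Y* = X* beta + e*``
whose covariance is diagonal, ``Sigma* = sigma_A^2 D_g + sigma_E^2 I`` with
``D_g = diag(lambda_g)``.  In this basis the Gaussian likelihood needs no
matrix inversion, and one Newton step for the variance parameters
``theta = (sigma_A^2, sigma_E^2)`` is a weighted regression of the squared
residuals ``f* = e*^2`` on ``U = [1, lambda_g]``.  Three estimators are
provided:

OLS
    beta by ordinary least squares; theta from the unweighted regression of
    f* on U (starting values, not recommended as a final estimate).
WLS
    one Newton step from the OLS point: beta and theta re-estimated with
    weights from the OLS Sigma*.  Non-iterative, asymptotically equivalent
    to ML.
ML
    the Newton updates iterated to convergence of the log-likelihood, with
    non-negativity projection of theta after every step.

Narrow-sense heritability is ``h2 = sigma_A^2 / (sigma_A^2 + sigma_E^2)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pedigree import EigenKinship

__all__ = [
    "TransformedModel",
    "VarianceComponents",
    "VarianceFit",
    "transform_model",
    "loglik",
    "score_and_information",
    "fit",
    "heritability",
]

#: relative floor applied to sigma_E^2 when the projected update hits zero
SIGMA_E_FLOOR = 1e-12
ML_TOL = 1e-8
ML_MAX_ITER = 200


class IdentifiabilityError(ValueError):
    """Variance parameters not identifiable (e.g. all eigenvalues equal)."""


@dataclass
class TransformedModel:
    """Phenotype and design rotated into the kinship eigenbasis."""

    Y_star: np.ndarray
    X_star: np.ndarray
    lambda_g: np.ndarray

    def __post_init__(self) -> None:
        self.Y_star = np.asarray(self.Y_star, float).ravel()
        self.X_star = np.atleast_2d(np.asarray(self.X_star, float))
        self.lambda_g = np.asarray(self.lambda_g, float).ravel()
        n = self.Y_star.shape[0]
        if self.X_star.shape[0] != n or self.lambda_g.shape[0] != n:
            raise ValueError("Y_star, X_star and lambda_g row counts differ")

    @property
    def n(self) -> int:
        return self.Y_star.shape[0]

    @property
    def p(self) -> int:
        return self.X_star.shape[1]

    @property
    def U(self) -> np.ndarray:
        """N x 2 design of the variance model: a ones column and lambda_g."""
        return np.column_stack([np.ones(self.n), self.lambda_g])


@dataclass
class VarianceComponents:
    sigma_A2: float
    sigma_E2: float

    def __post_init__(self) -> None:
        if self.sigma_A2 < 0 or self.sigma_E2 < 0:
            raise ValueError("variance components must be non-negative")

    @property
    def h2(self) -> float:
        return heritability(self)


@dataclass
class VarianceFit:
    """A fitted polygenic model (one phenotype)."""

    beta: np.ndarray
    vc: VarianceComponents
    residuals: np.ndarray
    loglik: float
    method: str
    iterations: int = 0
    converged: bool = True
    floored: bool = False
    degenerate: bool = False
    f_star: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.f_star is None:
            self.f_star = self.residuals**2

    @property
    def h2(self) -> float:
        if self.degenerate:
            return 0.0
        return self.vc.h2


def transform_model(Y: np.ndarray, X: np.ndarray, eig: EigenKinship) -> TransformedModel:
    """Rotate phenotype and design by ``S'`` into the eigenbasis of 2*Phi."""
    Y = np.asarray(Y, float).ravel()
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] != eig.n_subjects or Y.shape[0] != eig.n_subjects:
        raise ValueError(
            f"expected {eig.n_subjects} rows, got Y:{Y.shape[0]} X:{X.shape[0]}"
        )
    St = eig.S.T
    return TransformedModel(Y_star=St @ Y, X_star=St @ X, lambda_g=eig.lambda_g)


def _variances(model: TransformedModel, vc: VarianceComponents) -> np.ndarray:
    s2 = vc.sigma_A2 * model.lambda_g + vc.sigma_E2
    if np.any(s2 <= 0):
        raise ValueError("per-observation variance is not positive")
    return s2


def loglik(model: TransformedModel, beta: np.ndarray, vc: VarianceComponents) -> float:
    """Diagonal-Gaussian log-likelihood of the transformed model.

    Equals the dense multivariate-normal log-likelihood of the original
    model at the same parameters (the rotation is a reparametrization).
    """
    s2 = _variances(model, vc)
    resid = model.Y_star - model.X_star @ np.asarray(beta, float).ravel()
    return float(
        -0.5 * model.n * np.log(2 * np.pi)
        - 0.5 * np.sum(np.log(s2))
        - 0.5 * np.sum(resid**2 / s2)
    )


def score_and_information(
    model: TransformedModel, beta: np.ndarray, vc: VarianceComponents
) -> tuple[np.ndarray, np.ndarray]:
    """Score vector and expected information of (beta, theta).

    The score stacks the mean block ``X*' Sigma*^-1 e*`` and the variance
    block ``-1/2 U' Sigma*^-1 1 + 1/2 U' Sigma*^-2 e*^2``.  The expected
    information is block-diagonal between beta and theta:
    ``diag(X*' Sigma*^-1 X*, 1/2 U' Sigma*^-2 U)``.
    """
    s2 = _variances(model, vc)
    X, U = model.X_star, model.U
    resid = model.Y_star - X @ np.asarray(beta, float).ravel()
    score_beta = X.T @ (resid / s2)
    # theta block ordered (sigma_A^2, sigma_E^2): columns [lambda_g, 1]
    Ut = U[:, ::-1]
    score_theta = -0.5 * Ut.T @ (1.0 / s2) + 0.5 * Ut.T @ (resid**2 / s2**2)
    p = model.p
    info = np.zeros((p + 2, p + 2))
    info[:p, :p] = X.T @ (X / s2[:, None])
    info[p:, p:] = 0.5 * Ut.T @ (Ut / (s2**2)[:, None])
    return np.concatenate([score_beta, score_theta]), info


def _theta_update(
    U: np.ndarray, f: np.ndarray, weights: np.ndarray | None
) -> np.ndarray:
    """max(0, .) projected (weighted) regression of f* on U.

    ``weights`` are per-observation weights (Sigma*^-2 for Newton steps,
    None for the OLS start).  Raises if U is rank-deficient (all
    eigenvalues equal: the two variance components are confounded).
    """
    if np.ptp(U[:, 1]) < 1e-12:
        raise IdentifiabilityError(
            "all kinship eigenvalues are equal; variance components are "
            "not identifiable"
        )
    if weights is None:
        theta, *_ = np.linalg.lstsq(U, f, rcond=None)
    else:
        A = U.T @ (U * weights[:, None])
        b = U.T @ (f * weights)
        theta = np.linalg.solve(A, b)
    return np.maximum(0.0, theta[::-1])  # (sigma_A2, sigma_E2): U = [1, lambda]


def _beta_wls(X: np.ndarray, Y: np.ndarray, s2: np.ndarray) -> np.ndarray:
    w = 1.0 / s2
    A = X.T @ (X * w[:, None])
    return np.linalg.solve(A, X.T @ (Y * w))


def _floor_sigma_e(theta: np.ndarray, y_var: float) -> tuple[np.ndarray, bool]:
    floor = SIGMA_E_FLOOR * max(y_var, 1.0)
    if theta[1] < floor:
        return np.array([theta[0], floor]), True
    return theta, False


def fit(
    model: TransformedModel,
    method: str = "ml",
    tol: float = ML_TOL,
    max_iter: int = ML_MAX_ITER,
) -> VarianceFit:
    """Fit the polygenic model by OLS, one-step WLS, or iterated ML.

    Parameters
    ----------
    model : TransformedModel
    method : {"ols", "wls", "ml", "null"}
        "null" fits the no-heritability model (sigma_A^2 = 0), whose ML
        solution is the OLS mean fit with sigma_E^2 = RSS/N.
    tol, max_iter : ML stopping rule on |change in log-likelihood|.
        Non-convergence is reported via ``converged``, never raised.
    """
    method = method.lower()
    X, Y, U = model.X_star, model.Y_star, model.U
    n = model.n
    if np.linalg.matrix_rank(X) < model.p:
        raise ValueError("design matrix X_star is rank-deficient")
    y_var = float(np.var(Y)) if n > 1 else 1.0

    beta_ols, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid_ols = Y - X @ beta_ols
    f_ols = resid_ols**2

    if method == "null":
        sig2 = float(np.mean(f_ols))
        sig2 = max(sig2, SIGMA_E_FLOOR * max(y_var, 1.0))
        vc = VarianceComponents(0.0, sig2)
        return VarianceFit(
            beta=beta_ols,
            vc=vc,
            residuals=resid_ols,
            loglik=loglik(model, beta_ols, vc),
            method="null",
        )

    theta_ols = _theta_update(U, f_ols, None)
    theta_ols, floored = _floor_sigma_e(theta_ols, y_var)
    degenerate = theta_ols[0] == 0.0 and float(np.mean(f_ols)) < SIGMA_E_FLOOR

    if method == "ols":
        vc = VarianceComponents(*theta_ols)
        return VarianceFit(
            beta=beta_ols,
            vc=vc,
            residuals=resid_ols,
            loglik=loglik(model, beta_ols, vc),
            method="ols",
            floored=floored,
            degenerate=degenerate,
        )

    if method == "wls":
        s2 = theta_ols[0] * model.lambda_g + theta_ols[1]
        beta = _beta_wls(X, Y, s2)
        theta = _theta_update(U, f_ols, 1.0 / s2**2)
        theta, floored = _floor_sigma_e(theta, y_var)
        resid = Y - X @ beta
        vc = VarianceComponents(*theta)
        return VarianceFit(
            beta=beta,
            vc=vc,
            residuals=resid,
            loglik=loglik(model, beta, vc),
            method="wls",
            iterations=1,
            floored=floored,
            degenerate=degenerate,
        )

    if method != "ml":
        raise ValueError(f"unknown method {method!r}")

    beta, theta = beta_ols, theta_ols
    ll_prev = loglik(model, beta, VarianceComponents(*theta))
    converged = False
    it = 0
    floored = False
    lam = model.lambda_g
    for it in range(1, max_iter + 1):
        s2 = theta[0] * lam + theta[1]
        beta = _beta_wls(X, Y, s2)
        resid = Y - X @ beta
        f = resid**2
        theta = _theta_update(U, f, 1.0 / s2**2)
        # KKT face re-solve: the clipped joint update is a fixed point that
        # is not the constrained optimum; refit the free component alone
        if theta[0] == 0.0:
            theta = np.array([0.0, float(np.mean(f))])
        elif theta[1] == 0.0:
            w = 1.0 / s2**2
            theta = np.array([float((w * lam) @ f / ((w * lam) @ lam)), 0.0])
        theta, fl = _floor_sigma_e(theta, y_var)
        floored = floored or fl
        ll = loglik(model, beta, VarianceComponents(*theta))
        if abs(ll - ll_prev) < tol:
            converged = True
            ll_prev = ll
            break
        ll_prev = ll
    resid = Y - X @ beta
    vc = VarianceComponents(*theta)
    return VarianceFit(
        beta=beta,
        vc=vc,
        residuals=resid,
        loglik=ll_prev,
        method="ml",
        iterations=it,
        converged=converged,
        floored=floored,
        degenerate=degenerate,
    )


def heritability(vc: VarianceComponents) -> float:
    """Narrow-sense heritability ``sigma_A^2 / (sigma_A^2 + sigma_E^2)``."""
    total = vc.sigma_A2 + vc.sigma_E2
    if total <= 0:
        raise ValueError("both variance components are zero; h2 undefined")
    return float(vc.sigma_A2 / total)
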