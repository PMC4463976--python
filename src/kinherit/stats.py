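"""Test statistics for the null hypothesis of zero heritability.

All tests address H0: sigma_A^2 = 0 against H1: sigma_A^2 > 0 on the
transformed (eigenbasis) model.  Five statistics are provided:

``lrt_ml`` / ``lrt_wls``
    Twice the log-likelihood difference, alternative minus null.  The null
    model is trivial (iid errors, OLS mean fit); the alternative is either
    the fully iterated ML fit or the one-step WLS point.
``wald_ml`` / ``wald_wls``
    Quadratic form of sigma_A^2-hat against the theta-block of the expected
    information.  The WLS variant equals half the *generalized* explained
    sum of squares of the auxiliary weighted regression of squared OLS
    residuals on the eigenvalues (weights from the OLS Sigma*).
``score``
    Evaluated at the null fit only; equals half the explained sum of
    squares of the unweighted regression of f*/sigma2-hat on lambda_g.
``gq``
    Goldfeld-Quandt heteroscedasticity ratio: under H1 the transformed
    observations with eigenvalue > 1 have inflated variance, so the ratio
    of per-group OLS residual mean squares follows an exact F distribution
    under H0 (Gaussian errors) -- no boundary-mixture approximation.

The likelihood-based statistics sit on the boundary of the parameter space
under H0, so their reference distribution is the 50:50 mixture of a point
mass at zero and chi-square with 1 df; a zero statistic therefore has
p-value 1.  Negative score values are suppressed by the non-negativity
projection of the variance estimates, so Wald and score statistics are
exactly 0 whenever the corresponding constrained sigma_A^2 estimate is 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .model import (
    IdentifiabilityError,
    TransformedModel,
    VarianceFit,
    fit,
)

__all__ = [
    "TestResult",
    "GQPartition",
    "MIXTURE_KINDS",
    "TEST_KINDS",
    "lrt",
    "wald",
    "score_test",
    "gq_test",
    "parametric_pvalue",
    "compute_test",
]

MIXTURE_KINDS = ("lrt_ml", "lrt_wls", "wald_ml", "wald_wls", "score")
TEST_KINDS = MIXTURE_KINDS + ("gq",)


@dataclass
class TestResult:
    kind: str
    statistic: float
    parametric_p: float
    df_info: tuple[int, int] | None = None
    converged: bool = True


@dataclass
class GQPartition:
    """Subject split for the Goldfeld-Quandt test.

    Group A holds the high-variance observations (eigenvalue > 1), group B
    the rest (eigenvalue <= 1, ties to B).  ``nu1 = n_A - p`` is the
    numerator df and ``nu2 = n_B - p`` the denominator df of the exact
    null F distribution.
    """

    idx_A: np.ndarray
    idx_B: np.ndarray
    nu1: int
    nu2: int

    @property
    def n_A(self) -> int:
        return len(self.idx_A)

    @property
    def n_B(self) -> int:
        return len(self.idx_B)

    @classmethod
    def from_model(cls, model: TransformedModel) -> "GQPartition":
        lam = model.lambda_g
        idx_A = np.flatnonzero(lam > 1.0)
        idx_B = np.flatnonzero(lam <= 1.0)
        p = model.p
        if len(idx_A) <= p or len(idx_B) <= p:
            raise ValueError(
                f"GQ groups too small: n_A={len(idx_A)}, n_B={len(idx_B)}, p={p}"
            )
        return cls(idx_A=idx_A, idx_B=idx_B, nu1=len(idx_A) - p, nu2=len(idx_B) - p)


def _theta_block_contrast(lam: np.ndarray, s2: np.ndarray) -> float:
    """[C (U' Sigma^-2 U)^-1 C']^-1 for C = [0, 1], via the 2x2 inverse."""
    w = 1.0 / s2**2
    a00 = float(np.sum(w))
    a01 = float(np.sum(w * lam))
    a11 = float(np.sum(w * lam**2))
    return a11 - a01**2 / a00


def lrt(
    model: TransformedModel,
    estimator: str = "ml",
    alt_fit: VarianceFit | None = None,
    null_fit: VarianceFit | None = None,
) -> TestResult:
    """Likelihood-ratio statistic, clipped at zero.

    For ``estimator="wls"`` the alternative log-likelihood is evaluated at
    the one-step WLS point rather than the ML optimum, so the difference
    can be negative; it is clipped to 0 (boundary value).
    """
    estimator = estimator.lower()
    if estimator not in ("ml", "wls"):
        raise ValueError("estimator must be 'ml' or 'wls'")
    if alt_fit is None:
        alt_fit = fit(model, method=estimator)
    if null_fit is None:
        null_fit = fit(model, method="null")
    T = max(0.0, 2.0 * (alt_fit.loglik - null_fit.loglik))
    kind = f"lrt_{estimator}"
    return TestResult(
        kind=kind,
        statistic=T,
        parametric_p=parametric_pvalue(kind, T),
        converged=alt_fit.converged,
    )


def wald(
    model: TransformedModel,
    estimator: str = "ml",
    alt_fit: VarianceFit | None = None,
) -> TestResult:
    """Wald statistic for sigma_A^2 under the ML or one-step WLS fit.

    T = sigma_A^4 / (2 * C I_theta^-1 C') with the information evaluated at
    the ML Sigma* (ML variant) or at the OLS Sigma* whose weights define
    the one-step estimator (WLS variant, the auxiliary-regression form).
    """
    estimator = estimator.lower()
    if estimator not in ("ml", "wls"):
        raise ValueError("estimator must be 'ml' or 'wls'")
    kind = f"wald_{estimator}"
    if alt_fit is None:
        alt_fit = fit(model, method=estimator)
    sA2 = alt_fit.vc.sigma_A2
    if sA2 == 0.0:
        return TestResult(kind, 0.0, 1.0, converged=alt_fit.converged)
    if estimator == "ml":
        s2 = alt_fit.vc.sigma_A2 * model.lambda_g + alt_fit.vc.sigma_E2
    else:
        ols = fit(model, method="ols")
        s2 = ols.vc.sigma_A2 * model.lambda_g + ols.vc.sigma_E2
    T = 0.5 * sA2**2 * _theta_block_contrast(model.lambda_g, s2)
    return TestResult(
        kind=kind,
        statistic=T,
        parametric_p=parametric_pvalue(kind, T),
        converged=alt_fit.converged,
    )


def score_test(model: TransformedModel) -> TestResult:
    """Score (Lagrange-multiplier) statistic, needing only the null fit.

    T = (sigma_A,OLS^2 / sigma_OLS^2)^2 * lambda'(I - 11'/N)lambda / 2 with
    the naive residual-variance estimate sigma_OLS^2 = e'e/N, set to 0 when
    the constrained sigma_A,OLS^2 estimate is 0.
    """
    lam = model.lambda_g
    if np.ptp(lam) < 1e-12:
        raise IdentifiabilityError("all eigenvalues equal; score test undefined")
    ols = fit(model, method="ols")
    sig2 = float(np.mean(ols.f_star))
    sA2 = ols.vc.sigma_A2
    if sA2 == 0.0 or sig2 <= 0.0:
        return TestResult("score", 0.0, 1.0)
    lc = lam - lam.mean()
    T = 0.5 * (sA2 / sig2) ** 2 * float(lc @ lc)
    return TestResult("score", T, parametric_pvalue("score", T))


def gq_test(model: TransformedModel, ddof: str = "p") -> TestResult:
    """Goldfeld-Quandt variance-ratio test of zero heritability.

    Separate OLS fits of the group-A and group-B rows of (Y*, X*); the
    statistic is the ratio of residual mean squares, high-variance group in
    the numerator.  ``ddof="p"`` (default) divides each sum of squares by
    n - p, making the null distribution exactly F(n_A - p, n_B - p);
    ``ddof="1"`` reproduces the n - 1 denominators sometimes printed, which
    only rescales the statistic by a known constant (the p-value is always
    computed on the n - p scale).
    """
    part = GQPartition.from_model(model)
    rms = {}
    for name, idx in (("A", part.idx_A), ("B", part.idx_B)):
        Xg = model.X_star[idx]
        Yg = model.Y_star[idx]
        if np.linalg.matrix_rank(Xg) < model.p:
            raise ValueError(f"rank-deficient design in GQ group {name}")
        bg, *_ = np.linalg.lstsq(Xg, Yg, rcond=None)
        resid = Yg - Xg @ bg
        denom = len(idx) - model.p if ddof == "p" else len(idx) - 1
        rms[name] = float(resid @ resid) / denom
    T = rms["A"] / rms["B"]
    # exact-F p-value uses the n - p scaling regardless of the ddof display
    if ddof != "p":
        T_f = T * ((part.n_A - 1) / part.nu1) / ((part.n_B - 1) / part.nu2)
    else:
        T_f = T
    p = float(sps.f.sf(T_f, part.nu1, part.nu2))
    return TestResult("gq", T, max(p, np.finfo(float).tiny), df_info=(part.nu1, part.nu2))


def parametric_pvalue(
    kind: str, statistic: float, df_info: tuple[int, int] | None = None
) -> float:
    """P-value from the parametric reference distribution of a test kind.

    Mixture kinds use the 50:50 chi2(1)/point-mass law: p = 1 for T = 0 and
    p = P(chi2_1 >= T)/2 otherwise.  The GQ kind uses the upper tail of
    F(nu1, nu2).
    """
    if kind in MIXTURE_KINDS:
        if statistic < 0:
            raise ValueError("mixture-kind statistic must be >= 0")
        if statistic == 0.0:
            return 1.0
        return float(0.5 * sps.chi2.sf(statistic, df=1))
    if kind == "gq":
        if df_info is None:
            raise ValueError("GQ p-value needs df_info=(nu1, nu2)")
        return float(sps.f.sf(statistic, *df_info))
    raise ValueError(f"unknown test kind {kind!r}")


def compute_test(
    model: TransformedModel,
    kind: str,
    ddof: str = "p",
    **fit_kwargs,
) -> TestResult:
    """Dispatch a test by kind name (see ``TEST_KINDS``)."""
    kind = kind.lower().replace("-", "_")
    if kind == "score":
        return score_test(model)
    if kind == "gq":
        return gq_test(model, ddof=ddof)
    if kind.startswith("lrt_"):
        return lrt(model, estimator=kind.split("_", 1)[1], **fit_kwargs)
    if kind.startswith("wald_"):
        return wald(model, estimator=kind.split("_", 1)[1], **fit_kwargs)
    raise ValueError(f"unknown test kind {kind!r}")
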