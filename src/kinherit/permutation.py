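"""Permutation schemes for semi-parametric heritability inference.

Under H0 (no heritability) the transformed data are iid after removing
covariate effects, so subjects are freely exchangeable.  Four resampling
strategies build surrogate null datasets:

P1
    Permute the tested part of the model only: the eigenvalue vector
    lambda_g (equivalently P D_g P').  Data and design are untouched.
P2
    Permute null-model (OLS) residuals and add the fixed effects back:
    Y~* = X* beta_OLS + P e_OLS.  The recommended scheme.
P3
    As P2 but with full-model (WLS or ML) residuals and coefficients:
    Y~* = X* beta_full + P e_full.
P4
    Whiten full-model residuals before permuting, with no mean add-back:
    Y~* = P Sigma*^(-1/2) e_full (as printed; ``add_mean=True`` restores
    the fixed effects for users who want the P3-like variant).

Each surrogate is re-analyzed with the statistic under study; the p-value
is the proportion of the m draws (identity included by default) whose
statistic reaches the observed one, so the smallest attainable p is 1/m
(0.002 at m = 500).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .model import TransformedModel, VarianceFit, fit
from .stats import TestResult, compute_test

__all__ = ["PermutationPlan", "PermResult", "null_realization", "permutation_test"]

SCHEMES = ("P1", "P2", "P3", "P4")


@dataclass
class PermutationPlan:
    scheme: str = "P2"
    m: int = 500
    seed: int = 0
    include_identity: bool = True
    add_mean_p4: bool = False

    def __post_init__(self) -> None:
        self.scheme = self.scheme.upper()
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")
        if self.m < 1:
            raise ValueError("m must be >= 1")

    def draw(self, n: int) -> np.ndarray:
        """The (m, n) array of permutations this plan denotes."""
        rng = np.random.default_rng(self.seed)
        perms = np.empty((self.m, n), dtype=np.intp)
        start = 0
        if self.include_identity:
            perms[0] = np.arange(n)
            start = 1
        for b in range(start, self.m):
            perms[b] = rng.permutation(n)
        return perms


@dataclass
class PermResult:
    observed: TestResult
    perm_stats: np.ndarray
    p_perm: float
    n_failed: int = 0
    plan: PermutationPlan | None = field(default=None, repr=False)


def null_realization(
    scheme: str,
    model: TransformedModel,
    perm: np.ndarray,
    ols_fit: VarianceFit | None = None,
    full_fit: VarianceFit | None = None,
    add_mean_p4: bool = False,
) -> TransformedModel:
    """Build the surrogate transformed model for one permutation."""
    scheme = scheme.upper()
    if scheme == "P1":
        return TransformedModel(
            Y_star=model.Y_star, X_star=model.X_star, lambda_g=model.lambda_g[perm]
        )
    if scheme == "P2":
        if ols_fit is None:
            raise ValueError("P2 requires the OLS (null-model) fit")
        y = model.X_star @ ols_fit.beta + ols_fit.residuals[perm]
    elif scheme == "P3":
        if full_fit is None:
            raise ValueError("P3 requires a full-model (WLS/ML) fit")
        y = model.X_star @ full_fit.beta + full_fit.residuals[perm]
    elif scheme == "P4":
        if full_fit is None:
            raise ValueError("P4 requires a full-model (WLS/ML) fit")
        s2 = full_fit.vc.sigma_A2 * model.lambda_g + full_fit.vc.sigma_E2
        white = full_fit.residuals / np.sqrt(s2)
        y = white[perm]
        if add_mean_p4:
            y = y + model.X_star @ full_fit.beta
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    return TransformedModel(Y_star=y, X_star=model.X_star, lambda_g=model.lambda_g)


def permutation_test(
    model: TransformedModel,
    test_kind: str,
    plan: PermutationPlan,
    estimator: str = "wls",
    ddof: str = "p",
) -> PermResult:
    """Permutation p-value for any test statistic under any scheme.

    ``estimator`` selects the full-model fit (WLS or ML) used by P3/P4 and
    by the likelihood-based statistics.  A surrogate whose fit fails is
    recorded as statistic 0 (conservative) and counted in ``n_failed``.

    Ties between permuted and observed statistics count toward rejection;
    with the identity draw included the p-value floor is exactly 1/m.
    """
    observed = compute_test(model, test_kind, ddof=ddof)
    n = model.n
    needs_ols = plan.scheme == "P2"
    needs_full = plan.scheme in ("P3", "P4")
    ols_fit = fit(model, method="ols") if needs_ols else None
    full_fit = fit(model, method=estimator) if needs_full else None

    # P1 + score: OLS residuals do not depend on lambda, so the squared
    # residuals are computed once and only the eigenvalue vector moves.
    fast_score_p1 = plan.scheme == "P1" and test_kind == "score"
    if fast_score_p1:
        ols_fit = fit(model, method="ols")
        f = ols_fit.f_star
        sig2 = float(np.mean(f))
        lam = model.lambda_g
        lc0 = lam - lam.mean()
        s_ll = float(lc0 @ lc0)

    perms = plan.draw(n)
    stats = np.zeros(plan.m)
    n_failed = 0
    for b, perm in enumerate(perms):
        try:
            if plan.include_identity and b == 0 and plan.scheme != "P4":
                # identity surrogate is the data itself: exact tie by design
                stats[b] = observed.statistic
            elif fast_score_p1:
                lam_b = lam[perm]
                slope = float((lam_b - lam_b.mean()) @ f) / s_ll
                sA2 = max(0.0, slope)
                stats[b] = 0.5 * (sA2 / sig2) ** 2 * s_ll if sig2 > 0 else 0.0
            else:
                surrogate = null_realization(
                    plan.scheme,
                    model,
                    perm,
                    ols_fit=ols_fit,
                    full_fit=full_fit,
                    add_mean_p4=plan.add_mean_p4,
                )
                stats[b] = compute_test(surrogate, test_kind, ddof=ddof).statistic
        except Exception:
            stats[b] = 0.0
            n_failed += 1
    p = float(np.count_nonzero(stats >= observed.statistic)) / plan.m
    p = min(max(p, 1.0 / plan.m if plan.include_identity else 0.0), 1.0)
    return PermResult(
        observed=observed, perm_stats=stats, p_perm=p, n_failed=n_failed, plan=plan
    )
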