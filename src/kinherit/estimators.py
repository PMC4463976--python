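"""scikit-learn style estimators wrapping the functional core.

``HeritabilityRegressor`` fits the polygenic mixed model (fixed effects +
additive genetic and environmental variance components) and exposes the
heritability estimate as a fitted attribute; ``HeritabilityTester`` wraps
the test statistics and optional permutation inference.  Both follow the
sklearn contract (``get_params``/``set_params``, ``fit`` returning self,
trailing-underscore fitted attributes) so they compose with pipelines and
model selection, with the kinship eigendecomposition supplied as a
constructor parameter (it is a property of the cohort, not of the
phenotype being fit).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import model as _model
from .pedigree import EigenKinship
from .permutation import PermutationPlan, permutation_test
from .stats import compute_test

__all__ = ["HeritabilityRegressor", "HeritabilityTester"]


def _validate(X, y, eigen: EigenKinship):
    X = check_array(X, ensure_2d=True, dtype=float)
    y = check_array(y, ensure_2d=False, dtype=float)
    if eigen is None:
        raise ValueError("an EigenKinship must be supplied via `eigen`")
    if X.shape[0] != eigen.n_subjects or y.shape[0] != eigen.n_subjects:
        raise ValueError("X/y rows must match the kinship subject count")
    return X, y


class HeritabilityRegressor(RegressorMixin, BaseEstimator):
    """Polygenic variance-components regression with heritability estimate.

    Parameters
    ----------
    eigen : EigenKinship
        Eigendecomposition of 2*Phi for the cohort, in subject order.
    method : {"ml", "wls", "ols"}
        Fully iterated ML, the non-iterative one-step estimator, or the
        raw OLS start.
    tol, max_iter : ML stopping rule.

    Attributes
    ----------
    coef_ : fixed-effect coefficients (X is used as given; include your
        own intercept column).
    h2_, sigma_a2_, sigma_e2_, loglik_, n_iter_, converged_
    """

    def __init__(self, eigen: EigenKinship | None = None, method: str = "ml",
                 tol: float = 1e-8, max_iter: int = 200):
        self.eigen = eigen
        self.method = method
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        X, y = _validate(X, y, self.eigen)
        tm = _model.transform_model(y, X, self.eigen)
        res = _model.fit(tm, method=self.method, tol=self.tol, max_iter=self.max_iter)
        self.coef_ = res.beta
        self.sigma_a2_ = res.vc.sigma_A2
        self.sigma_e2_ = res.vc.sigma_E2
        self.h2_ = res.h2
        self.loglik_ = res.loglik
        self.n_iter_ = res.iterations
        self.converged_ = res.converged
        self.fit_result_ = res
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        """Fixed-effects prediction X @ coef_ (genetic BLUPs not included)."""
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return X @ self.coef_


class HeritabilityTester(BaseEstimator):
    """Significance test for H0: h2 = 0 with parametric and permutation p.

    Parameters
    ----------
    eigen : EigenKinship
    kind : {"score", "wald_wls", "wald_ml", "lrt_wls", "lrt_ml", "gq"}
    scheme : permutation scheme "P1".."P4", used when n_permutations > 0
    n_permutations : 0 disables permutation inference
    random_state : permutation seed

    Attributes
    ----------
    statistic_, parametric_p_, perm_p_ (None without permutations)
    """

    def __init__(self, eigen: EigenKinship | None = None, kind: str = "score",
                 scheme: str = "P2", n_permutations: int = 0,
                 estimator: str = "wls", random_state: int = 0):
        self.eigen = eigen
        self.kind = kind
        self.scheme = scheme
        self.n_permutations = n_permutations
        self.estimator = estimator
        self.random_state = random_state

    def fit(self, X, y):
        X, y = _validate(X, y, self.eigen)
        tm = _model.transform_model(y, X, self.eigen)
        if self.n_permutations > 0:
            plan = PermutationPlan(
                scheme=self.scheme, m=self.n_permutations, seed=self.random_state
            )
            res = permutation_test(tm, self.kind, plan, estimator=self.estimator)
            self.statistic_ = res.observed.statistic
            self.parametric_p_ = res.observed.parametric_p
            self.perm_p_ = res.p_perm
            self.perm_result_ = res
        else:
            tr = compute_test(tm, self.kind)
            self.statistic_ = tr.statistic
            self.parametric_p_ = tr.parametric_p
            self.perm_p_ = None
        self.n_features_in_ = X.shape[1]
        return self
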