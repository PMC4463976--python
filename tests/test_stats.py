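"""The five heritability tests against independent oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats as sps

import kinherit as kh
from kinherit.batch import batch_statistic
from kinherit.stats import GQPartition, parametric_pvalue


@pytest.fixture(scope="module")
def fitted(model138):
    return {
        "ols": kh.fit(model138, method="ols"),
        "wls": kh.fit(model138, method="wls"),
        "ml": kh.fit(model138, method="ml"),
    }


class TestWald:
    def test_ml_quadratic_form_closed_identity(self, rng):
        """The theta-block quadratic form equals (N - a^2/b)/2 with
        a = 1'Sigma^-1 1, b = 1'Sigma^-2 1 -- an exact algebraic identity
        for any Sigma = sigma_A^2 D + sigma_E^2 I."""
        from kinherit.stats import _theta_block_contrast

        for _ in range(10):
            n = 30
            lam = rng.gamma(2.0, 1.0, n)
            sA2, sE2 = rng.uniform(0.05, 2.0, size=2)
            s2 = sA2 * lam + sE2
            quad = 0.5 * sA2**2 * _theta_block_contrast(lam, s2)
            a, b = np.sum(1 / s2), np.sum(1 / s2**2)
            assert quad == pytest.approx(0.5 * (n - a**2 / b), abs=1e-10)

    def test_wls_equals_half_generalized_ess(self, model138, fitted):
        """T_W,WLS is half the generalized explained SS of the auxiliary
        weighted regression of squared OLS residuals on lambda (weights
        from the OLS Sigma*), computed via statsmodels WLS."""
        ols = fitted["ols"]
        lam = model138.lambda_g
        f = ols.f_star
        s2 = ols.vc.sigma_A2 * lam + ols.vc.sigma_E2
        w = 1.0 / s2**2
        full = sm.WLS(f, sm.add_constant(lam), weights=w).fit()
        reduced = sm.WLS(f, np.ones_like(lam), weights=w).fit()
        gen_ess = reduced.ssr - full.ssr  # weighted RSS difference
        T = kh.wald(model138, estimator="wls").statistic
        assert full.params[1] > 0  # interior case: no clipping
        assert T == pytest.approx(0.5 * gen_ess, rel=1e-10)

    def test_zero_sigma_a_gives_zero(self, eig138, design138):
        X, _ = design138
        lam = eig138.lambda_g
        y = np.sqrt(np.maximum(0.05, 2.0 - lam)) * np.sin(np.arange(138))
        tm = kh.TransformedModel(y, eig138.S.T @ X, lam)
        for est in ("ml", "wls"):
            r = kh.wald(tm, estimator=est)
            assert r.statistic == 0.0 and r.parametric_p == 1.0


class TestScore:
    def test_equals_half_aux_ess(self, model138, fitted):
        """T_S is half the explained SS of the unweighted regression of
        f*/sigma2-hat on lambda (independent statsmodels route)."""
        ols = fitted["ols"]
        sig2 = np.mean(ols.f_star)
        aux = sm.OLS(ols.f_star / sig2, sm.add_constant(model138.lambda_g)).fit()
        T = kh.score_test(model138).statistic
        assert aux.params[1] > 0
        assert T == pytest.approx(0.5 * aux.ess, rel=1e-10)

    def test_constant_f_gives_zero(self, eig138, design138):
        X, _ = design138
        # residuals with constant magnitude: no association with lambda
        y = np.sin(np.arange(138))
        y = np.sign(y) * 1.0
        tm = kh.TransformedModel(y, np.ones((138, 1)), eig138.lambda_g)
        assert kh.score_test(tm).statistic == 0.0

    def test_null_zero_excess_and_p_one(self, eig138, design138):
        """Under H0 at least half the score statistics are exactly 0 (the
        zero rate exceeds 50% for dependent family data, which is what makes
        the 50:50 mixture p-values conservative), and each zero maps to a
        p-value of exactly 1."""
        X, beta = design138
        Y = kh.simulate_phenotypes(0.0, eig138, X, beta, 2000, seed=31)
        T = batch_statistic(Y, eig138.S.T @ X, eig138.lambda_g, "score")
        frac0 = np.mean(T == 0.0)
        assert 0.5 <= frac0 < 0.95
        p = kh.batch.batch_parametric_p(T, "score")
        assert np.mean(p == 1.0) == frac0


class TestLRT:
    def test_nonnegative_and_boundary(self, model138, eig138, design138):
        assert kh.lrt(model138, "ml").statistic >= 0.0
        X, _ = design138
        lam = eig138.lambda_g
        y = np.sqrt(np.maximum(0.05, 2.0 - lam)) * np.sin(np.arange(138))
        tm = kh.TransformedModel(y, eig138.S.T @ X, lam)
        r = kh.lrt(tm, "ml")
        assert r.statistic == pytest.approx(0.0, abs=1e-9)

    def test_ml_matches_dense_two_optimization_oracle(self, rng):
        """T_L,ML on a toy N=8 dataset equals a brute-force LRT that
        optimizes the dense untransformed likelihood directly."""
        from scipy.optimize import minimize

        ped = kh.generate_pedigree(1, 8, seed=21)
        kin = kh.kinship_from_pedigree(ped)
        eig = kh.eigen_kinship(kin)
        X = np.column_stack([np.ones(8), np.linspace(-1, 1, 8)])
        Y = kh.simulate_phenotype(0.6, eig, X, [0.5, 1.0], seed=rng)
        tm = kh.transform_model(Y, X, eig)
        T = kh.lrt(tm, "ml").statistic

        Phi2 = 2 * kin.Phi

        def nll(t):
            sA2, sE2 = np.exp(t[2]), np.exp(t[3])
            Sigma = sA2 * Phi2 + sE2 * np.eye(8)
            r = Y - X @ t[:2]
            sign, logdet = np.linalg.slogdet(Sigma)
            return 0.5 * (8 * np.log(2 * np.pi) + logdet + r @ np.linalg.solve(Sigma, r))

        best_alt = min(
            (
                minimize(nll, [0, 0, np.log(a), np.log(b)], method="Nelder-Mead",
                         options={"xatol": 1e-12, "fatol": 1e-13, "maxiter": 20000})
                for a, b in [(0.5, 0.5), (1.0, 0.1), (0.05, 1.0)]
            ),
            key=lambda r: r.fun,
        )
        # null: sigma_A2 = 0 -> OLS closed form
        bh, *_ = np.linalg.lstsq(X, Y, rcond=None)
        rss = np.sum((Y - X @ bh) ** 2)
        ll_null = -0.5 * (8 * np.log(2 * np.pi) + 8 * np.log(rss / 8) + 8)
        T_oracle = max(0.0, 2 * (-best_alt.fun - ll_null))
        assert T == pytest.approx(T_oracle, abs=1e-5)


class TestGQ:
    def test_partition_by_lambda(self, model138):
        part = GQPartition.from_model(model138)
        lam = model138.lambda_g
        assert np.all(lam[part.idx_A] > 1.0) and np.all(lam[part.idx_B] <= 1.0)
        assert part.n_A + part.n_B == 138
        assert part.nu1 == part.n_A - 3 and part.nu2 == part.n_B - 3

    def test_equal_rms_gives_one(self, eig138):
        """Construct Y* whose two group regressions leave identical residual
        mean squares; the ratio is then exactly 1."""
        lam = eig138.lambda_g
        X = np.ones((138, 1))
        y = np.zeros(138)
        for idx in (np.flatnonzero(lam > 1), np.flatnonzero(lam <= 1)):
            k = len(idx)
            pattern = np.resize([1.0, -1.0], k)
            pattern -= pattern.mean()
            y[idx] = pattern / np.sqrt(np.sum(pattern**2) / (k - 1))
        tm = kh.TransformedModel(y, X, lam)
        assert kh.gq_test(tm).statistic == pytest.approx(1.0)

    def test_null_distribution_is_exact_F(self, eig138, design138):
        """Under H0 the statistic follows F(n_A - p, n_B - p) exactly:
        Kolmogorov-Smirnov on 4000 null replicates."""
        X, beta = design138
        Xs = eig138.S.T @ X
        lam = eig138.lambda_g
        Y = kh.simulate_phenotypes(0.0, eig138, X, beta, 4000, seed=77)
        T = batch_statistic(Y, Xs, lam, "gq")
        n_A = int(np.sum(lam > 1))
        ks = sps.kstest(T, sps.f(n_A - 3, 138 - n_A - 3).cdf)
        assert ks.pvalue > 0.01

    def test_ddof_switch_rescales(self, model138):
        a = kh.gq_test(model138, ddof="p")
        b = kh.gq_test(model138, ddof="1")
        part = GQPartition.from_model(model138)
        scale = ((part.n_A - 3) / (part.n_A - 1)) / ((part.n_B - 3) / (part.n_B - 1))
        assert b.statistic == pytest.approx(a.statistic * scale)
        assert b.parametric_p == pytest.approx(a.parametric_p)  # same exact-F p

    def test_small_group_raises(self, rng):
        lam = np.array([0.5, 0.6, 1.5, 1.6, 1.7, 1.8])
        tm = kh.TransformedModel(rng.standard_normal(6), np.ones((6, 2)), lam)
        with pytest.raises(ValueError, match="small"):
            kh.gq_test(tm)


class TestParametricP:
    def test_point_mass_and_tail(self):
        assert parametric_pvalue("score", 0.0) == 1.0
        q95 = sps.chi2.isf(0.05, df=1)
        assert parametric_pvalue("lrt_ml", q95) == pytest.approx(0.025)

    def test_gq_symmetry_equal_df(self):
        assert parametric_pvalue("gq", 1.0, df_info=(40, 40)) == pytest.approx(0.5)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            parametric_pvalue("banana", 1.0)

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            parametric_pvalue("score", -0.5)


class TestInvariances:
    def test_mean_shift_invariance(self, model138):
        """Adding any linear combination of X columns to Y leaves every
        statistic unchanged."""
        shift = model138.X_star @ np.array([3.0, -2.0, 0.5])
        shifted = kh.TransformedModel(
            model138.Y_star + shift, model138.X_star, model138.lambda_g
        )
        for kind in ("score", "wald_wls", "wald_ml", "lrt_ml", "lrt_wls", "gq"):
            a = kh.compute_test(model138, kind).statistic
            b = kh.compute_test(shifted, kind).statistic
            assert b == pytest.approx(a, rel=1e-8, abs=1e-10)

    def test_asymptotic_rank_agreement(self):
        """Under local alternatives on a large pedigree the score, Wald and
        LRT statistics co-rank strongly (asymptotic equivalence)."""
        from itertools import combinations

        ped = kh.generate_pedigree(9, 626, seed=9626)
        eig = kh.eigen_kinship(kh.kinship_from_pedigree(ped))
        X, beta = kh.make_design(626)
        Y = kh.simulate_phenotypes(0.1, eig, X, beta, 400, seed=11)
        Xs = eig.S.T @ X
        Ts = {
            k: batch_statistic(Y, Xs, eig.lambda_g, k)
            for k in ("score", "wald_wls", "wald_ml", "lrt_ml")
        }
        for a, b in combinations(Ts, 2):
            assert sps.spearmanr(Ts[a], Ts[b]).statistic > 0.9
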