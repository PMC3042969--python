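"""Linear-model engine: Henderson III, partial F, REML, GLS/AUP, Gibbs."""

import numpy as np
import pytest
from scipy import stats

from silkqtl.linmod import (
    DegenerateDesignError,
    DesignMatrices,
    NestedFTester,
    aup_random,
    gibbs_estimate,
    gls_fixed,
    henderson3_extra_ss,
    partial_f,
    reml_components,
)

rng = np.random.default_rng(42)


def _random_nested(n=30, p_red=3, p_extra=2, seed=None):
    r = np.random.default_rng(seed)
    Xr = r.standard_normal((n, p_red))
    Xe = r.standard_normal((n, p_extra))
    y = r.standard_normal(n)
    return y, np.hstack([Xr, Xe]), Xr


class TestHendersonIII:
    @pytest.mark.parametrize("seed", range(10))
    def test_equals_two_fit_difference(self, seed):
        y, Xf, Xr = _random_nested(seed=seed)
        ssr, sse, *_ = henderson3_extra_ss(y, Xf, Xr)
        r_red = y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]
        r_full = y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
        assert ssr == pytest.approx(r_red @ r_red - r_full @ r_full, abs=1e-8)
        assert sse == pytest.approx(r_full @ r_full, abs=1e-8)

    def test_no_extra_columns(self):
        y, Xf, Xr = _random_nested(seed=0)
        ssr, *_ = henderson3_extra_ss(y, Xr, Xr)
        assert ssr == pytest.approx(0.0, abs=1e-10)

    def test_orthogonal_extra_column(self):
        n = 40
        Xr = np.ones((n, 1))
        extra = np.zeros((n, 1))
        extra[: n // 2, 0], extra[n // 2:, 0] = 1.0, -1.0
        y = np.ones(n)  # orthogonal to the balanced contrast
        ssr, *_ = henderson3_extra_ss(y, np.hstack([Xr, extra]), Xr)
        assert ssr == pytest.approx(0.0, abs=1e-10)

    def test_invariant_to_reparameterization(self):
        y, Xf, Xr = _random_nested(seed=3)
        T = np.random.default_rng(1).standard_normal((3, 3))
        while abs(np.linalg.det(T)) < 0.1:
            T = np.random.default_rng(2).standard_normal((3, 3))
        Xf2 = np.hstack([Xr @ T, Xf[:, 3:]])
        a = henderson3_extra_ss(y, Xf, Xr)[0]
        b = henderson3_extra_ss(y, Xf2, Xr @ T)[0]
        assert a == pytest.approx(b, abs=1e-8)

    def test_degenerate_design_error(self):
        y = np.zeros(3)
        X = np.eye(3)
        with pytest.raises(DegenerateDesignError):
            henderson3_extra_ss(y, X, X[:, :1])


class TestPartialF:
    @pytest.mark.parametrize("seed", range(100))
    def test_matches_textbook_nested_f(self, seed):
        y, Xf, Xr = _random_nested(n=25, seed=seed)
        res = partial_f(y, Xf, Xr)
        r_red = y - Xr @ np.linalg.lstsq(Xr, y, rcond=None)[0]
        r_full = y - Xf @ np.linalg.lstsq(Xf, y, rcond=None)[0]
        sse = r_full @ r_full
        f_ref = ((r_red @ r_red - sse) / 2) / (sse / (25 - 3))
        assert res.F == pytest.approx(f_ref, abs=1e-8)
        assert res.df_num == 2 and res.df_den == 22

    def test_scale_invariance(self):
        y, Xf, Xr = _random_nested(seed=1)
        assert partial_f(10 * y, Xf, Xr).F == pytest.approx(
            partial_f(y, Xf, Xr).F, abs=1e-9)

    def test_perfect_fit_guarded(self):
        n = 20
        Xr = np.ones((n, 1))
        extra = np.arange(n, dtype=float).reshape(-1, 1)
        y = 2.0 + 3.0 * extra[:, 0]  # exactly in span of full design
        res = partial_f(y, np.hstack([Xr, extra]), Xr)
        assert np.isfinite(res.F) and res.F > 1e6

    def test_null_calibration(self):
        """Under a Gaussian null the statistic follows a scaled central F:
        the denominator pairs the full-model SSE with the reduced-model
        degrees of freedom, so F = F(q, n-p_full) * (n-p_red)/(n-p_full).
        The empirical exceedance of that law's 0.95 quantile is ~5%."""
        n, reps = 40, 2000
        r = np.random.default_rng(7)
        Xr = np.hstack([np.ones((n, 1)), r.standard_normal((n, 2))])
        Xe = r.standard_normal((n, 3))
        Xf = np.hstack([Xr, Xe])
        crit = stats.f.ppf(0.95, 3, n - 6) * (n - 3) / (n - 6)
        hits = sum(partial_f(r.standard_normal(n), Xf, Xr).F > crit
                   for _ in range(reps))
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_vectorized_tester_agrees(self):
        y, Xf, Xr = _random_nested(n=35, seed=9)
        tester = NestedFTester(Xr)
        Y = np.column_stack([y, 2 * y, y + 1])
        F, df = tester.f_stats(Xf[:, 3:], tester.prepare(Y))
        ref = partial_f(y, Xf, Xr).F
        assert df == 2
        np.testing.assert_allclose(F[:2], ref, atol=1e-9)


class TestREML:
    def test_balanced_one_way_closed_form(self):
        k, m = 25, 8
        g = np.repeat(np.arange(k), m)
        r = np.random.default_rng(3)
        y = 3.0 + np.sqrt(2.0) * r.standard_normal(k)[g] \
            + r.standard_normal(k * m)
        U = np.zeros((k * m, k))
        U[np.arange(k * m), g] = 1.0
        dm = DesignMatrices(X=np.ones((k * m, 1)), x_labels=["mu"],
                            U_list=[U], u_terms=["group"])
        est = reml_components(y, dm)
        means = np.array([y[g == j].mean() for j in range(k)])
        msb = m * np.sum((means - y.mean()) ** 2) / (k - 1)
        msw = sum(((y[g == j] - means[j]) ** 2).sum()
                  for j in range(k)) / (k * m - k)
        assert est["converged"]
        assert est["components"]["group"] == pytest.approx((msb - msw) / m,
                                                           rel=1e-4)
        assert est["var_e"] == pytest.approx(msw, rel=1e-4)

    def test_zero_variance_boundary(self):
        n = 400
        r = np.random.default_rng(4)
        y = 1.0 + r.standard_normal(n)
        U = np.zeros((n, 2))
        U[: n // 2, 0], U[n // 2:, 1] = 1.0, 1.0
        dm = DesignMatrices(X=np.ones((n, 1)), x_labels=["mu"],
                            U_list=[U], u_terms=["grp"])
        est = reml_components(y, dm)
        assert est["components"]["grp"] < 0.05
        assert est["var_e"] == pytest.approx(1.0, abs=0.2)

    def test_no_random_terms_degenerates_to_ols_variance(self):
        r = np.random.default_rng(5)
        X = np.hstack([np.ones((50, 1)), r.standard_normal((50, 2))])
        y = X @ np.array([1.0, 2.0, -1.0]) + r.standard_normal(50)
        dm = DesignMatrices(X=X, x_labels=list("abc"))
        est = reml_components(y, dm)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        assert est["var_e"] == pytest.approx(resid @ resid / 47, rel=1e-10)


class TestGLSandAUP:
    def test_gls_equals_ols_under_identity(self):
        r = np.random.default_rng(6)
        X = r.standard_normal((60, 4))
        y = r.standard_normal(60)
        dm = DesignMatrices(X=X, x_labels=list("abcd"))
        fit = gls_fixed(y, dm, {}, 1.0)
        np.testing.assert_allclose(
            fit["estimates"], np.linalg.lstsq(X, y, rcond=None)[0], atol=1e-9)

    def test_aup_two_level_sum_to_zero_and_scaling(self):
        n = 300
        r = np.random.default_rng(8)
        sex = np.repeat([0, 1], n // 2)
        U = np.zeros((n, 2))
        U[np.arange(n), sex] = 1.0
        y = 2.0 + np.array([1.5, -1.5])[sex] + r.standard_normal(n)
        dm = DesignMatrices(X=np.ones((n, 1)), x_labels=["mu"],
                            U_list=[U], u_terms=["sex"])
        est = reml_components(y, dm)
        pred = aup_random(y, dm, est["components"], est["var_e"])["sex"]
        assert pred.sum() == pytest.approx(0.0, abs=1e-8)
        # AUP scaling: empirical second moment of levels = component
        assert np.mean(pred ** 2) == pytest.approx(
            est["components"]["sex"], rel=1e-6)
        assert pred[0] > 0 > pred[1]


class TestGibbs:
    def test_conjugate_posterior_oracle(self):
        """Known-variance normal mean model: the Gibbs posterior for the
        mean matches the analytic flat-prior posterior N(ybar, sigma2/n)."""
        n = 200
        r = np.random.default_rng(9)
        y = 3.0 + r.standard_normal(n)
        dm = DesignMatrices(X=np.ones((n, 1)), x_labels=["mu"])
        rep = gibbs_estimate(y, dm, n_iter=4000, burn_in=1000, seed=1)
        mu, sd = rep.fixed["estimate"][0], rep.fixed["sd"][0]
        se = y.std(ddof=1) / np.sqrt(n)
        assert mu == pytest.approx(y.mean(), abs=3 * se / np.sqrt(10))
        assert sd == pytest.approx(se, rel=0.15)

    def test_chain_reproducibility(self):
        r = np.random.default_rng(10)
        y = r.standard_normal(80)
        X = np.hstack([np.ones((80, 1)), r.standard_normal((80, 2))])
        dm = DesignMatrices(X=X, x_labels=list("abc"))
        a = gibbs_estimate(y, dm, n_iter=500, burn_in=100, seed=3)
        b = gibbs_estimate(y, dm, n_iter=500, burn_in=100, seed=3)
        np.testing.assert_array_equal(a.fixed["estimate"], b.fixed["estimate"])

    def test_posterior_matches_gls_when_residual_dominates(self):
        n = 600
        r = np.random.default_rng(11)
        X = np.hstack([np.ones((n, 1)), r.standard_normal((n, 2))])
        beta = np.array([1.0, 0.5, -0.8])
        y = X @ beta + 0.3 * r.standard_normal(n)
        dm = DesignMatrices(X=X, x_labels=list("abc"))
        rep = gibbs_estimate(y, dm, n_iter=3000, burn_in=500, seed=4)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        np.testing.assert_allclose(rep.fixed["estimate"], ols, atol=0.05)
        assert rep.fixed["significant"].all()

    def test_invalid_iteration_counts(self):
        dm = DesignMatrices(X=np.ones((10, 1)), x_labels=["mu"])
        with pytest.raises(ValueError):
            gibbs_estimate(np.zeros(10), dm, n_iter=100, burn_in=100)
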