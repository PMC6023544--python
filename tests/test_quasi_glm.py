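"""Engine tests: IRLS estimates, Pearson dispersion, quasi-F tests."""
import numpy as np
import pytest
import scipy.optimize
import scipy.special
import scipy.stats

from neozy.quasi_glm import (
    BINOMIAL,
    POISSON,
    DesignMatrix,
    RankDeficientError,
    f_test,
    fit,
    predict,
)


def intercept_design(n, trials=None):
    return DesignMatrix(np.ones((n, 1)), ("intercept",), trials=trials)


class TestClosedForms:
    def test_intercept_only_poisson_mean_and_dispersion(self):
        res = fit(np.array([1.0, 2.0, 3.0]), intercept_design(3), POISSON)
        assert res.coef[0] == pytest.approx(np.log(2.0), abs=1e-8)
        # Pearson X² = (1/2 + 0 + 1/2) = 1 on 2 df
        assert res.pearson_x2 == pytest.approx(1.0, abs=1e-8)
        assert res.dispersion == pytest.approx(0.5, abs=1e-8)
        assert res.df_resid == 2

    def test_intercept_only_poisson_exact_fit_is_saturated(self):
        res = fit(np.array([2.0, 2.0, 2.0]), intercept_design(3), POISSON)
        assert res.deviance == pytest.approx(0.0, abs=1e-10)
        assert res.pearson_x2 == pytest.approx(0.0, abs=1e-10)
        assert res.dispersion == pytest.approx(0.0, abs=1e-10)

    def test_intercept_only_binomial_pooled_proportion(self):
        y = np.full(4, 3.0)
        trials = np.full(4, 10.0)
        res = fit(y, intercept_design(4, trials), BINOMIAL)
        assert res.coef[0] == pytest.approx(scipy.special.logit(0.3), abs=1e-8)


def _poisson_negll(beta, X, y):
    eta = np.clip(X @ beta, -500, 500)
    mu = np.exp(eta)
    return float(np.sum(mu - y * eta))


def _binomial_negll(beta, X, y, trials):
    eta = np.clip(X @ beta, -500, 500)
    return float(np.sum(trials * np.logaddexp(0.0, eta) - y * eta))


class TestOracleEquivalence:
    """IRLS coefficients equal a generic numerical likelihood maximizer."""

    @pytest.mark.parametrize("seed", range(6))
    def test_poisson_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n, p = rng.integers(20, 50), rng.integers(2, 6)
        X = np.column_stack([np.ones(n), rng.normal(0, 0.5, (n, p - 1))])
        beta_true = rng.normal(0, 0.4, p)
        y = rng.poisson(np.exp(X @ beta_true)).astype(float)
        names = tuple(f"x{j}" for j in range(p))
        res = fit(y, DesignMatrix(X, names), POISSON)
        opt = scipy.optimize.minimize(
            _poisson_negll, np.zeros(p), args=(X, y), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        assert np.max(np.abs(res.coef - opt.x)) < 1e-6

    @pytest.mark.parametrize("seed", range(3))
    def test_binomial_random_instances(self, seed):
        rng = np.random.default_rng(100 + seed)
        n, p = 40, 3
        X = np.column_stack([np.ones(n), rng.normal(0, 0.7, (n, p - 1))])
        trials = rng.integers(5, 20, n).astype(float)
        prob = scipy.special.expit(X @ rng.normal(0, 0.5, p))
        y = rng.binomial(trials.astype(int), prob).astype(float)
        res = fit(y, DesignMatrix(X, ("a", "b", "c"), trials=trials), BINOMIAL)
        opt = scipy.optimize.minimize(
            _binomial_negll, np.zeros(p), args=(X, y, trials), method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        assert np.max(np.abs(res.coef - opt.x)) < 1e-6


class TestInvariants:
    def test_covariate_rescaling_rescales_coefficient_inversely(self, rng):
        n = 40
        x = rng.normal(0, 1, n)
        y = rng.poisson(np.exp(0.5 + 0.3 * x)).astype(float)
        d1 = DesignMatrix(np.column_stack([np.ones(n), x]), ("i", "x"))
        d2 = DesignMatrix(np.column_stack([np.ones(n), 10 * x]), ("i", "x"))
        f1, f2 = fit(y, d1, POISSON), fit(y, d2, POISSON)
        assert f2.coef[1] == pytest.approx(f1.coef[1] / 10, rel=1e-8)
        np.testing.assert_allclose(f1.fitted, f2.fitted, atol=1e-10)

    def test_dispersion_calibrated_under_pure_poisson(self):
        rng = np.random.default_rng(5)
        n = 40
        X = DesignMatrix(
            np.column_stack([np.ones(n), rng.normal(0, 1, n)]), ("i", "x")
        )
        phis = [
            fit(rng.poisson(5.0, n).astype(float), X, POISSON).dispersion
            for _ in range(1000)
        ]
        assert 0.95 < np.mean(phis) < 1.05

    def test_rank_deficient_design_names_aliased_terms(self):
        n = 10
        x = np.arange(n, dtype=float)
        X = np.column_stack([np.ones(n), x, 2 * x])
        with pytest.raises(RankDeficientError, match=r"aliased terms: .*x[12]"):
            fit(np.ones(n), DesignMatrix(X, ("i", "x1", "x2")), POISSON)

    def test_response_validation(self):
        with pytest.raises(ValueError, match="non-negative"):
            fit(np.array([-1.0, 2.0]), intercept_design(2), POISSON)
        with pytest.raises(ValueError, match="trials"):
            fit(
                np.array([5.0, 2.0]),
                intercept_design(2, trials=np.array([3.0, 3.0])),
                BINOMIAL,
            )


class TestFTest:
    def _two_group(self, rng, means=(2.0, 10.0), n=8):
        g = np.repeat([0.0, 1.0], n // 2)
        y = np.concatenate(
            [rng.poisson(means[0], n // 2), rng.poisson(means[1], n // 2)]
        ).astype(float)
        full = DesignMatrix(np.column_stack([np.ones(n), g]), ("i", "g"))
        red = DesignMatrix(np.ones((n, 1)), ("i",))
        return y, red, full

    def test_matches_direct_likelihood_oracle(self, rng):
        y, red, full = self._two_group(rng)
        rf, ff = fit(y, red, POISSON), fit(y, full, POISSON)
        res = f_test(rf, ff)
        # recompute both deviances from a generic optimizer
        def dev(X):
            p = X.shape[1]
            opt = scipy.optimize.minimize(
                _poisson_negll, np.zeros(p), args=(X, y), method="BFGS",
                options={"gtol": 1e-12},
            )
            mu = np.exp(X @ opt.x)
            with np.errstate(divide="ignore", invalid="ignore"):
                term = np.where(y > 0, y * np.log(y / mu), 0.0)
            return 2 * np.sum(term - (y - mu))

        d_red, d_full = dev(red.X), dev(full.X)
        f_expected = ((d_red - d_full) / 1) / ff.dispersion
        assert res.f_stat == pytest.approx(f_expected, abs=1e-6)
        assert (res.df_num, res.df_den) == (1, len(y) - 2)

    def test_saturated_reference_rejected(self):
        y = np.array([2.0, 2.0, 2.0, 2.0])
        g = np.array([0.0, 0.0, 1.0, 1.0])
        full = fit(y, DesignMatrix(np.column_stack([np.ones(4), g]), ("i", "g")), POISSON)
        red = fit(y, DesignMatrix(np.ones((4, 1)), ("i",)), POISSON)
        with pytest.raises(ValueError, match="saturated"):
            f_test(red, full)

    def test_non_nested_designs_rejected(self, rng):
        n = 12
        y = rng.poisson(3.0, n).astype(float)
        a = rng.normal(0, 1, n)
        b = rng.normal(0, 1, n)
        f_a = fit(y, DesignMatrix(a[:, None], ("a",)), POISSON)
        f_b = fit(
            y, DesignMatrix(np.column_stack([b, b**2]), ("b", "b2")), POISSON
        )
        with pytest.raises(ValueError, match="nested"):
            f_test(f_a, f_b)


class TestPredict:
    def test_intercept_only_poisson_prediction(self):
        res = fit(np.array([1.0, 2.0, 3.0]), intercept_design(3), POISSON)
        out = predict(res, DesignMatrix(np.ones((5, 1)), ("intercept",)))
        np.testing.assert_allclose(out, 2.0, atol=1e-10)

    def test_matches_direct_link_evaluation(self, rng):
        n = 30
        X = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        y = rng.poisson(np.exp(0.2 + 0.4 * X[:, 1])).astype(float)
        res = fit(y, DesignMatrix(X, ("i", "x")), POISSON)
        Xn = np.column_stack([np.ones(5), rng.normal(0, 1, 5)])
        out = predict(res, DesignMatrix(Xn, ("i", "x")))
        np.testing.assert_allclose(out, np.exp(Xn @ res.coef), atol=1e-12)

    def test_term_mismatch_is_reported(self):
        res = fit(np.array([1.0, 2.0]), intercept_design(2), POISSON)
        with pytest.raises(ValueError, match="missing"):
            predict(res, DesignMatrix(np.ones((2, 1)), ("other",)))
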