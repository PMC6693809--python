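"""Regression-engine oracles: hand algebra, closed forms, statsmodels
cross-checks, and the complete-case / IPW analysis stages."""

import numpy as np
import pytest

from misslab.amputation import MechanismSpec, ampute, mechanism_catalog
from misslab.dataset import Column, Dataset, DatasetError
from misslab.estimators import (DegenerateOutcomeError, RankDeficientError,
                                SeparationError, fit_cca, fit_full, fit_ipw,
                                fit_logistic, fit_ols)
from misslab.synthetic import CannabisParams, generate_cannabis_population
from conftest import CANNABIS_LINEAR


def _design(x):
    return np.column_stack([np.ones(len(x)), np.asarray(x, float)])


class TestOLS:
    def test_exact_fit(self):
        x = np.array([0.0, 1, 2, 3, 4])
        fit = fit_ols(_design(x), 2 * x + 1, ["intercept", "x"])
        assert fit["x"]["coef"] == pytest.approx(2.0, abs=1e-12)
        assert fit["intercept"]["coef"] == pytest.approx(1.0, abs=1e-12)
        assert fit["x"]["se"] == pytest.approx(0.0, abs=1e-12)

    def test_intercept_only_is_sample_mean(self):
        rng = np.random.default_rng(0)
        y = rng.normal(3.0, 2.0, size=40)
        fit = fit_ols(np.ones((40, 1)), y, ["intercept"])
        assert fit["intercept"]["coef"] == pytest.approx(y.mean(), rel=1e-12)
        assert fit["intercept"]["se"] == pytest.approx(y.std(ddof=1) / np.sqrt(40),
                                                       rel=1e-10)

    def test_hand_normal_equations_three_points(self):
        # X = [[1,0],[1,1],[1,2]], y = [1, 2, 2]; X'X = [[3,3],[3,5]],
        # X'y = [5, 6]; beta = (X'X)^-1 X'y = [7/6, 1/2]
        X = _design([0.0, 1.0, 2.0])
        fit = fit_ols(X, np.array([1.0, 2.0, 2.0]), ["intercept", "x"])
        assert fit["intercept"]["coef"] == pytest.approx(7 / 6, abs=1e-10)
        assert fit["x"]["coef"] == pytest.approx(0.5, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        X = np.column_stack([np.ones(60), rng.normal(size=(60, 2))])
        y = X @ [1.0, 0.5, -0.3] + rng.normal(size=60)
        ours = fit_ols(X, y)
        ref = sm.OLS(y, X).fit()
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.se, ref.bse, atol=1e-10)
        np.testing.assert_allclose(
            [ours.ci_low, ours.ci_high], ref.conf_int().T, atol=1e-8)

    def test_weighted_matches_statsmodels_sandwich(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        X = np.column_stack([np.ones(80), rng.normal(size=80)])
        y = X @ [0.5, 1.0] + rng.normal(size=80)
        w = rng.uniform(0.5, 2.0, size=80)
        ours = fit_ols(X, y, weights=w)
        ref = sm.WLS(y, X, weights=w).fit(cov_type="HC0")
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-10)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-6)

    def test_rank_deficiency_and_negative_weights(self):
        X = np.column_stack([np.ones(10), np.ones(10)])
        with pytest.raises(RankDeficientError):
            fit_ols(X, np.zeros(10))
        with pytest.raises(ValueError):
            fit_ols(np.ones((10, 1)), np.zeros(10), weights=-np.ones(10))


class TestLogistic:
    def test_two_by_two_closed_form(self):
        # exposed cases a=20, exposed noncases b=30, unexposed cases c=40,
        # unexposed noncases d=10: slope = ln(ad/bc) = ln(1/6)
        x = np.repeat([1.0, 1.0, 0.0, 0.0], [20, 30, 40, 10])
        y = np.repeat([1.0, 0.0, 1.0, 0.0], [20, 30, 40, 10])
        fit = fit_logistic(_design(x), y, ["intercept", "x"])
        assert fit["x"]["coef"] == pytest.approx(np.log(1 / 6), abs=1e-8)

    def test_independence_gives_zero_slope(self):
        x = np.tile([0.0, 1.0], 50)
        y = np.repeat([0.0, 1.0], 50)
        fit = fit_logistic(_design(x), y, ["intercept", "x"])
        assert fit["x"]["coef"] == pytest.approx(0.0, abs=1e-10)

    def test_separation_raises(self):
        x = np.arange(10.0)
        y = (x > 4.5).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(_design(x), y)

    def test_one_class_outcome_raises(self):
        with pytest.raises(DegenerateOutcomeError):
            fit_logistic(np.ones((10, 1)), np.ones(10))

    def test_loglik_nondecreasing_over_irls(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=200)
        y = (rng.uniform(size=200) < 1 / (1 + np.exp(-(0.3 + 0.8 * x)))).astype(float)
        trace: list = []
        fit_logistic(_design(x), y, trace=trace)
        assert len(trace) >= 2
        assert all(b >= a - 1e-10 for a, b in zip(trace, trace[1:]))

    def test_matches_statsmodels(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(300), rng.normal(size=(300, 2))])
        y = (rng.uniform(size=300)
             < 1 / (1 + np.exp(-(X @ [0.2, 0.7, -0.4])))).astype(float)
        ours = fit_logistic(X, y)
        ref = sm.Logit(y, X).fit(disp=0)
        np.testing.assert_allclose(ours.coef, ref.params, atol=1e-7)
        np.testing.assert_allclose(ours.se, ref.bse, rtol=1e-5)

    def test_disease_or_equals_exposure_or(self):
        """On complete 2x2 data the log-OR from outcome-on-exposure equals
        the log-OR from exposure-on-outcome — the symmetry behind the
        logistic complete-case exemptions."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            counts = rng.integers(5, 60, size=4)  # a, b, c, d
            x = np.repeat([1.0, 1.0, 0.0, 0.0], counts)
            y = np.repeat([1.0, 0.0, 1.0, 0.0], counts)
            f_xy = fit_logistic(_design(x), y, ["i", "s"])
            f_yx = fit_logistic(_design(y), x, ["i", "s"])
            assert f_xy["s"]["coef"] == pytest.approx(f_yx["s"]["coef"], abs=1e-8)


class TestAnalysisStages:
    def test_cca_identical_to_full_fit_when_complete(self, cannabis_small):
        full = fit_full(cannabis_small, CANNABIS_LINEAR)
        cca = fit_cca(cannabis_small, CANNABIS_LINEAR)
        np.testing.assert_allclose(full.coef, cca.coef, atol=1e-12)
        assert cca.n_used == cannabis_small.n

    def test_cca_drops_exactly_missing_rows(self, cannabis_small):
        amp = ampute(cannabis_small,
                     MechanismSpec("maternal_substance_use", target_rate=0.2),
                     seed=1)
        k = int((~amp.observed("maternal_substance_use")).sum())
        fit = fit_cca(amp, CANNABIS_LINEAR)
        assert fit.n_used == cannabis_small.n - k

    def test_cca_too_few_complete_cases(self):
        cols = [Column("x", role="exposure"), Column("y", role="outcome")]
        vals = np.column_stack([np.arange(5.0), np.arange(5.0)])
        mask = np.zeros((5, 2), dtype=bool)
        mask[:4, 0] = True
        d = Dataset(cols, vals, mask)
        from misslab.estimators import AnalysisModel
        with pytest.raises(DatasetError):
            fit_cca(d, AnalysisModel("y", "x"))

    def test_ipw_constant_weights_equal_unweighted(self, cannabis_small):
        amp = ampute(cannabis_small,
                     MechanismSpec("cannabis_use", target_rate=0.3), seed=2)
        ipw = fit_ipw(amp, CANNABIS_LINEAR, ["sex"])
        cca = fit_cca(amp, CANNABIS_LINEAR)
        # MCAR: the weight model has (asymptotically) no signal, weights are
        # near-constant, so estimates agree closely
        np.testing.assert_allclose(ipw.coef, cca.coef, atol=0.02)
        assert ipw.weights_summary["cv"] < 0.2

    def test_ipw_corrects_outcome_dependent_selection(self):
        """Mechanism d (missingness on outcome + confounder): weighting on
        those predictors removes the CCA bias; omitting the outcome from
        the weight model leaves it (negative control)."""
        R, truth = 60, 1.0
        good, bad, naive = [], [], []
        for ch in np.random.SeedSequence(77).spawn(R):
            s1, s2 = ch.spawn(2)
            d = generate_cannabis_population(CannabisParams(n=2500, seed=s1))
            amp = ampute(d, mechanism_catalog("cannabis")["d"], seed=s2)
            good.append(fit_ipw(amp, CANNABIS_LINEAR,
                                ["depression_21", "maternal_substance_use"]
                                )["cannabis_use[weekly]"]["coef"])
            bad.append(fit_ipw(amp, CANNABIS_LINEAR,
                               ["maternal_substance_use"]
                               )["cannabis_use[weekly]"]["coef"])
            naive.append(fit_cca(amp, CANNABIS_LINEAR)
                         ["cannabis_use[weekly]"]["coef"])
        for est, unbiased in ((good, True), (bad, False), (naive, False)):
            e = np.asarray(est)
            mcse = e.std(ddof=1) / np.sqrt(R)
            if unbiased:
                assert abs(e.mean() - truth) < 3 * mcse
            else:
                assert abs(e.mean() - truth) > 3 * mcse
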