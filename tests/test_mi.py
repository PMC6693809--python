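"""Imputation-engine oracles: Rubin's-rules hand computations, conditional
draw distributions against closed forms, support and preservation
invariants, and FCS behaviour on degenerate inputs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from misslab.amputation import MechanismSpec, ampute
from misslab.dataset import Column, Dataset, DatasetError
from misslab.estimators import FitResult
from misslab.mi import (ImputationConfig, draw_bayesian_linear, draw_pmm,
                        impute_fcs, mi_analyze, pool_rubin)
from misslab.synthetic import CannabisParams, generate_cannabis_population
from conftest import CANNABIS_LINEAR


def _fit(coefs, ses, terms=None):
    coefs = np.asarray(coefs, float)
    ses = np.asarray(ses, float)
    terms = terms or [f"t{i}" for i in range(len(coefs))]
    return FitResult(terms, coefs, ses, coefs - ses, coefs + ses,
                     10.0, 20, "linear")


class TestPoolRubin:
    def test_hand_computed_oracle(self):
        """m=3, estimates {1.0,1.2,1.4}, variances {0.04,0.05,0.06}:
        Q-bar=1.2, W=0.05, B=0.04, T=0.103333..., df=7.5078125."""
        fits = [_fit([e], [np.sqrt(v)]) for e, v in
                zip((1.0, 1.2, 1.4), (0.04, 0.05, 0.06))]
        p = pool_rubin(fits)
        assert p.estimate[0] == pytest.approx(1.2, abs=1e-10)
        assert p.within[0] == pytest.approx(0.05, abs=1e-10)
        assert p.between[0] == pytest.approx(0.04, abs=1e-10)
        assert p.total[0] == pytest.approx(0.05 + (4 / 3) * 0.04, abs=1e-10)
        assert p.df[0] == pytest.approx(7.5078125, abs=1e-6)
        assert 0 <= p.fmi[0] < 1

    def test_degenerate_identical_estimates(self):
        fits = [_fit([2.5], [0.3])] * 4
        p = pool_rubin(fits)
        assert p.between[0] == 0.0
        assert p.total[0] == p.within[0]
        assert np.isinf(p.df[0])
        assert p.estimate[0] == 2.5

    def test_variance_scaling_linearity(self):
        ests, ses = [1.0, 1.3, 0.9], [0.2, 0.25, 0.22]
        p1 = pool_rubin([_fit([e], [s]) for e, s in zip(ests, ses)])
        p2 = pool_rubin([_fit([e], [np.sqrt(2) * s]) for e, s in zip(ests, ses)])
        assert p2.within[0] == pytest.approx(2 * p1.within[0], rel=1e-12)
        assert p2.between[0] == pytest.approx(p1.between[0], rel=1e-12)
        assert p2.estimate[0] == p1.estimate[0]

    def test_mismatched_terms_rejected(self):
        with pytest.raises(DatasetError):
            pool_rubin([_fit([1.0], [0.1], ["a"]), _fit([1.0], [0.1], ["b"])])

    @settings(deadline=None, derandomize=True)
    @given(st.integers(2, 12), st.integers(1, 4), st.integers(0, 10_000))
    def test_rubin_identity_property(self, m, p, seed):
        """T = W + (1 + 1/m) B holds exactly for random inputs."""
        rng = np.random.default_rng(seed)
        fits = [_fit(rng.normal(size=p), rng.uniform(0.05, 2.0, size=p))
                for _ in range(m)]
        pooled = pool_rubin(fits)
        np.testing.assert_allclose(
            pooled.total, pooled.within + (1 + 1 / m) * pooled.between,
            rtol=0, atol=1e-14)
        assert (pooled.between >= 0).all()
        assert ((pooled.fmi >= 0) & (pooled.fmi < 1)).all()


class TestConditionalDraws:
    def test_bayesian_linear_exact_data_zero_noise(self):
        x = np.arange(10.0)
        X = np.column_stack([np.ones(10), x])
        y = 3.0 + 2.0 * x
        vals = draw_bayesian_linear(y, X, np.array([[1.0, 20.0]]),
                                    np.random.default_rng(0))
        assert vals[0] == pytest.approx(43.0, abs=1e-8)

    def test_bayesian_linear_reproducible(self):
        rng_data = np.random.default_rng(1)
        X = np.column_stack([np.ones(30), rng_data.normal(size=30)])
        y = X @ [1.0, 0.5] + rng_data.normal(size=30)
        Xm = X[:5]
        a = draw_bayesian_linear(y, X, Xm, np.random.default_rng(9))
        b = draw_bayesian_linear(y, X, Xm, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)

    def test_bayesian_linear_intercept_only_t_distribution(self):
        """Marginally, intercept-only posterior-predictive draws follow
        ybar + s*sqrt(1+1/n)*t_{n-1}; compare quantiles over 1e5 draws."""
        from scipy import stats
        rng_data = np.random.default_rng(2)
        n = 25
        y = rng_data.normal(5.0, 2.0, size=n)
        X = np.ones((n, 1))
        rng = np.random.default_rng(3)
        draws = np.concatenate([
            draw_bayesian_linear(y, X, np.ones((100, 1)), rng)
            for _ in range(1000)])
        scale = y.std(ddof=1) * np.sqrt(1 + 1 / n)
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            expect = y.mean() + scale * stats.t.ppf(q, n - 1)
            assert np.quantile(draws, q) == pytest.approx(expect, abs=0.05)

    def test_pmm_support_and_nearest_neighbour(self):
        x = np.arange(20.0)
        X = np.column_stack([np.ones(20), x])
        y = 2.0 * x  # noiseless, monotone
        rng = np.random.default_rng(4)
        vals = draw_pmm(y, X, np.array([[1.0, 7.2], [1.0, 3.9]]), 1, rng)
        assert vals[0] == pytest.approx(14.0)  # donor at x=7
        assert vals[1] == pytest.approx(8.0)   # donor at x=4
        # any donor-pool size: imputed values are always observed values
        vals = draw_pmm(y, X, np.column_stack([np.ones(50),
                                               rng.uniform(0, 19, 50)]), 20, rng)
        assert np.isin(vals, y).all()

    def test_pmm_donor_bounds(self):
        X = np.ones((5, 1))
        with pytest.raises(DatasetError):
            draw_pmm(np.arange(5.0), X, X, 6, np.random.default_rng(0))


class TestImputeFcs:
    def test_complete_data_returns_identical_copies(self, cannabis_small):
        cfg = ImputationConfig(m=3, iterations=2, seed=1)
        out = impute_fcs(cannabis_small, cfg)
        assert len(out) == 3
        for d in out:
            assert d == cannabis_small

    def test_observed_cells_preserved_and_support_respected(self):
        d = generate_cannabis_population(CannabisParams(n=800, seed=5))
        amp = ampute(d, [MechanismSpec("cannabis_use", target_rate=0.3),
                         MechanismSpec("conduct_disorder", target_rate=0.2),
                         MechanismSpec("depression_12", target_rate=0.2)],
                     seed=6)
        cfg = ImputationConfig(m=2, iterations=3, seed=7)
        for comp in impute_fcs(amp, cfg):
            for name in amp.names:
                obs = amp.observed(name)
                np.testing.assert_array_equal(comp.values(name)[obs],
                                              amp.values(name)[obs])
            assert np.isin(comp.values("cannabis_use"), [0, 1, 2]).all()
            assert np.isin(comp.values("conduct_disorder"), [0, 1]).all()
            assert not np.isnan(comp.values("depression_12")).any()

    def test_fallback_to_pmm_on_separation(self, caplog):
        """A binary target whose observed part is perfectly separated by a
        predictor makes the logistic conditional fail; the engine falls
        back to pmm and still returns in-support values."""
        import logging
        rng = np.random.default_rng(8)
        n = 60
        x = rng.normal(size=n)
        b = (x > 0).astype(float)  # perfectly separated
        cols = [Column("x", role="outcome"), Column("b", "binary", "exposure")]
        mask = np.zeros((n, 2), dtype=bool)
        mask[:10, 1] = True
        d = Dataset(cols, np.column_stack([x, b]), mask)
        cfg = ImputationConfig(m=2, iterations=1, seed=9)
        with caplog.at_level(logging.WARNING, logger="misslab.mi"):
            out = impute_fcs(d, cfg)
        assert any("falling back to pmm" in r.message for r in caplog.records)
        for comp in out:
            assert np.isin(comp.values("b"), [0, 1]).all()

    def test_no_observed_values_rejected(self):
        cols = [Column("x", role="outcome"), Column("z", role="exposure")]
        mask = np.zeros((5, 2), dtype=bool)
        mask[:, 1] = True
        d = Dataset(cols, np.ones((5, 2)), mask)
        with pytest.raises(DatasetError):
            impute_fcs(d, ImputationConfig(m=2, seed=0))

    def test_config_validation(self):
        with pytest.raises(DatasetError):
            ImputationConfig(m=1).validate()
        with pytest.raises(DatasetError):
            ImputationConfig(m=2, iterations=0).validate()
        with pytest.raises(DatasetError):
            ImputationConfig(m=2, methods={"x": "magic"}).validate()


class TestMiAnalyze:
    def test_complete_data_equals_full_fit(self, cannabis_small):
        from misslab.estimators import fit_full
        pooled = mi_analyze(cannabis_small, CANNABIS_LINEAR,
                            ImputationConfig(m=3, seed=2))
        full = fit_full(cannabis_small, CANNABIS_LINEAR)
        np.testing.assert_allclose(pooled.estimate, full.coef, atol=1e-12)
        assert (pooled.between == 0).all()

    def test_seed_reproducibility(self):
        d = generate_cannabis_population(CannabisParams(n=600, seed=11))
        amp = ampute(d, [MechanismSpec("cannabis_use", target_rate=0.3)], seed=12)
        cfg = ImputationConfig(m=3, iterations=2, seed=13)
        p1 = mi_analyze(amp, CANNABIS_LINEAR, cfg)
        p2 = mi_analyze(amp, CANNABIS_LINEAR, cfg)
        np.testing.assert_array_equal(p1.estimate, p2.estimate)
        np.testing.assert_array_equal(p1.total, p2.total)

    def test_rubin_identity_in_real_run(self):
        d = generate_cannabis_population(CannabisParams(n=800, seed=14))
        amp = ampute(d, [MechanismSpec("cannabis_use", target_rate=0.35)], seed=15)
        p = mi_analyze(amp, CANNABIS_LINEAR, ImputationConfig(m=5, seed=16))
        np.testing.assert_allclose(
            p.total, p.within + (1 + 1 / 5) * p.between, atol=1e-14)
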