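"""Backward-AIC selection, d-separation tests, grouped R² attribution."""

import itertools

import numpy as np
import pandas as pd
import pytest

from phylodom.drivers import (
    backward_stepwise_aic, dsep_test, grouped_r2, residual_normality,
    run_drivers_stage,
)


def _ols_aic(y, X):
    """Gaussian-OLS AIC up to a constant, via plain linear algebra."""
    n = len(y)
    design = np.column_stack([np.ones(n), X]) if X.shape[1] else \
        np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    rss = float(((y - design @ beta) ** 2).sum())
    return n * np.log(rss / n) + 2 * design.shape[1]


def _greedy_oracle(y, X: pd.DataFrame):
    """Independent backward-greedy selection using the lstsq AIC."""
    current = sorted(X.columns)
    aic = _ols_aic(y, X[current].to_numpy())
    while current:
        cands = sorted((_ols_aic(y, X[[c for c in current if c != d]]
                                 .to_numpy()), d) for d in current)
        if cands[0][0] < aic:
            aic = cands[0][0]
            current = [c for c in current if c != cands[0][1]]
        else:
            break
    return current


class TestBackwardStepwise:
    def test_true_predictor_retained_noise_dropped(self):
        keeps_signal, drops_noise = 0, 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = 200
            X = pd.DataFrame({"x1": rng.normal(size=n),
                              "x2": rng.normal(size=n)})
            y = 2 * X["x1"] + rng.normal(size=n)
            res = backward_stepwise_aic(y, X)
            keeps_signal += "x1" in res.retained
            drops_noise += "x2" not in res.retained
        assert keeps_signal == 20          # strong effect never dropped
        assert drops_noise >= 12           # AIC keeps noise ~16% of the time

    def test_pure_noise_often_reduces_to_intercept(self):
        empty = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = pd.DataFrame(rng.normal(size=(150, 4)),
                             columns=list("abcd"))
            y = rng.normal(size=150)
            empty += backward_stepwise_aic(y, X).retained == []
        assert empty >= 11

    def test_matches_independent_greedy_oracle(self):
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            X = pd.DataFrame(rng.normal(size=(120, 6)),
                             columns=[f"v{i}" for i in range(6)])
            y = (X["v0"] + 0.5 * X["v3"] + rng.normal(size=120)).to_numpy()
            assert backward_stepwise_aic(y, X).retained == \
                sorted(_greedy_oracle(y, X))

    def test_reaches_exhaustive_optimum_on_orthogonalish_design(self):
        rng = np.random.default_rng(42)
        X = pd.DataFrame(rng.normal(size=(150, 6)),
                         columns=[f"v{i}" for i in range(6)])
        y = (1.5 * X["v1"] + 0.8 * X["v4"] + rng.normal(size=150)).to_numpy()
        res = backward_stepwise_aic(y, X)
        best = min(
            (_ols_aic(y, X[list(sub)].to_numpy()), sorted(sub))
            for r in range(7)
            for sub in itertools.combinations(X.columns, r))
        assert sorted(res.retained) == best[1]
        assert _ols_aic(y, X[res.retained].to_numpy()) == pytest.approx(best[0])

    def test_column_order_invariance(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(100, 4)), columns=list("dcba"))
        y = (X["a"] * 2 + rng.normal(size=100)).to_numpy()
        r1 = backward_stepwise_aic(y, X)
        r2 = backward_stepwise_aic(y, X[list("abcd")])
        assert r1.retained == r2.retained
        assert r1.aic == pytest.approx(r2.aic)

    def test_collinear_design_rejected(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=50)
        X = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=50)})
        with pytest.raises(ValueError, match="b"):
            backward_stepwise_aic(rng.normal(size=50), X)


class TestDsep:
    def test_type_one_under_full_mediation(self):
        rng = np.random.default_rng(11)
        rejections = 0
        n_rep = 300
        for _ in range(n_rep):
            x = rng.normal(size=400)
            m = x + rng.normal(size=400)
            y = m + rng.normal(size=400)
            rejections += dsep_test(y, x, m)["p"] < 0.05
        assert abs(rejections / n_rep - 0.05) < 0.04

    def test_direct_path_detected(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=500)
            m = x + rng.normal(size=500)
            y = m + 0.5 * x + rng.normal(size=500)
            hits += dsep_test(y, x, m)["p"] < 0.01
        assert hits >= 19

    def test_independent_predictor_estimate_near_zero(self):
        rng = np.random.default_rng(13)
        x = rng.normal(size=2000)
        m = rng.normal(size=2000)
        y = m + rng.normal(size=2000)
        assert abs(dsep_test(y, x, m)["estimate"]) < 0.1

    def test_constant_mediator_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            dsep_test(np.arange(20.0), np.arange(20.0), np.ones(20))

    def test_too_few_cases_rejected(self):
        with pytest.raises(ValueError, match="complete cases"):
            dsep_test(np.arange(5.0), np.arange(5.0), np.arange(5.0))


class TestGroupedR2:
    def test_empty_category_contributes_zero(self):
        rng = np.random.default_rng(20)
        X = pd.DataFrame({"mat": rng.normal(size=100),
                          "grazed": rng.integers(0, 2, 100).astype(float)})
        y = X["mat"] + rng.normal(size=100, scale=0.5)
        out = grouped_r2(y, X, retained=["mat"],
                         groups={"climate": ["mat"], "management": ["grazed"]})
        assert out["management"] == 0.0
        assert out["climate"] > 0.2

    def test_orthogonal_predictors_additive(self):
        rng = np.random.default_rng(21)
        n = 4000
        X = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        y = X["a"] + 2 * X["b"] + rng.normal(size=n)
        out = grouped_r2(y, X, retained=["a", "b"],
                         groups={"ga": ["a"], "gb": ["b"]})
        # each group's ΔR² approximates that variable's marginal R²
        var_y = 1 + 4 + 1
        assert out["ga"] == pytest.approx(1 / var_y, abs=0.03)
        assert out["gb"] == pytest.approx(4 / var_y, abs=0.03)


class TestResidualNormality:
    def test_gaussian_rarely_rejected(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(30)
        ps = []
        for _ in range(40):
            x = rng.normal(size=150)
            y = x + rng.normal(size=150)
            ps.append(residual_normality(
                sm.OLS(y, sm.add_constant(x)).fit()))
        assert np.mean(np.array(ps) < 0.05) < 0.2

    def test_heavy_tails_detected(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(31)
        hits = 0
        for _ in range(20):
            x = rng.normal(size=200)
            y = x + rng.standard_t(2, size=200)
            hits += residual_normality(sm.OLS(y, sm.add_constant(x)).fit()) < 0.05
        assert hits >= 16

    def test_small_sample_rejected(self):
        import statsmodels.api as sm
        fit = sm.OLS(np.arange(7.0) + 0.1, np.ones(7)).fit()
        with pytest.raises(ValueError):
            residual_normality(fit)


def test_run_drivers_stage_recovers_prevalence_effect():
    """A planted linear prevalence → response effect is retained and its
    mediated predictors flagged conditionally independent."""
    rng = np.random.default_rng(55)
    n = 120
    prev = rng.uniform(0.14, 1.0, n)
    desc = pd.DataFrame({
        "graminoid_prevalence": prev,
        "mat": 10 * prev + rng.normal(size=n),   # correlated via prevalence
        "elevation": rng.normal(size=n),
    }, index=[f"site{i}" for i in range(n)])
    resp = pd.DataFrame({
        "delta_ses": -3 * prev + rng.normal(size=n, scale=0.5)},
        index=desc.index)
    out = run_drivers_stage(desc, resp)
    step = out["delta_ses"]["stepwise"]
    assert "graminoid_prevalence" in step.retained
    dsep = out["delta_ses"]["dsep"]
    if "mat" in set(dsep.get("predictor", [])):
        p_mat = dsep.set_index("predictor").loc["mat", "p"]
        assert p_mat > 0.001  # mediation: no strong direct path
    assert out["delta_ses"]["grouped_r2"]["biomass"] > 0.3
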