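"""Penalized-spline mixed model: bases, REML fits, AR(1), reaction norms."""

import numpy as np
import pandas as pd
import pytest

from movescale import gamm
from movescale.gamm import (
    FactorTerm,
    LinearTerm,
    ModelSpec,
    RandomIntercept,
    SmoothTerm,
    build_design,
    fit,
    fit_ar1,
    reaction_norm,
)


def _spec(terms, response="y", scale="monthly", **kw):
    return ModelSpec(response, scale, "test", terms, **kw)


class TestDesign:
    def test_bspline_partition_of_unity(self):
        rng = np.random.default_rng(0)
        x = rng.uniform(0, 10, 500)
        basis = gamm._SmoothBasis(x, 10, False, None, [], "x")
        B = basis._raw(x)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)

    def test_cyclic_partition_of_unity_and_wrap(self):
        x = np.linspace(0.5, 12.49, 200)
        basis = gamm._SmoothBasis(x, 10, True, (0.5, 12.5), [], "month")
        B = basis._raw(x)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-10)
        # periodic: value at both ends of the cycle agree
        np.testing.assert_allclose(basis._raw(np.array([0.5])),
                                   basis._raw(np.array([12.5])), atol=1e-9)

    def test_few_distinct_values_reduce_basis(self):
        df = pd.DataFrame({"y": np.arange(24.0),
                           "x": np.tile([1.0, 2, 3, 4, 5, 6], 4)})
        des = build_design(_spec([SmoothTerm("x", k=10)]), df)
        assert any("reduced" in w for w in des.warnings)
        sm = [b for b in des.blocks if b.kind == "smooth"][0]
        assert sm.sl.stop - sm.sl.start == 5  # 6 basis cols - 1 constraint

    def test_three_distinct_values_fall_back_to_linear(self):
        df = pd.DataFrame({"y": np.arange(9.0), "x": np.tile([1.0, 2, 3], 3)})
        des = build_design(_spec([SmoothTerm("x")]), df)
        assert any("linear" in w for w in des.warnings)
        assert [b.kind for b in des.blocks] == ["intercept", "linear"]

    def test_single_level_factor_dropped_with_warning(self):
        df = pd.DataFrame({"y": np.arange(5.0), "f": ["a"] * 5})
        des = build_design(_spec([FactorTerm("f")]), df)
        assert any("single level" in w for w in des.warnings)
        assert [b.kind for b in des.blocks] == ["intercept"]

    def test_missing_rows_dropped_and_counted(self):
        df = pd.DataFrame({"y": [1.0, 2, np.nan, 4], "x": [1.0, np.nan, 3, 4]})
        des = build_design(_spec([LinearTerm("x")]), df)
        assert des.n_dropped == 2
        assert len(des.y) == 2

    def test_ar1_only_at_daily_scale(self):
        with pytest.raises(ValueError):
            ModelSpec("y", "monthly", "t", [], ar1=True)


class TestFit:
    def test_fixed_lambda_matches_dense_closed_form(self):
        rng = np.random.default_rng(1)
        n = 150
        df = pd.DataFrame({
            "x": rng.uniform(0, 1, n),
            "g": rng.choice(list("abc"), n),
            "w": rng.uniform(0.5, 2.0, n),
        })
        df["y"] = np.sin(6 * df.x) + rng.normal(0, 0.2, n)
        des = build_design(
            _spec([SmoothTerm("x"), RandomIntercept("g")], weights_col="w"), df
        )
        lam = [0.37, 2.2]
        f = fit(des, lambdas=lam)
        W = np.diag(des.w)
        S = np.zeros((des.X.shape[1],) * 2)
        for lv, b in zip(lam, des.penalized_blocks):
            S[b.sl, b.sl] += lv * b.S
        beta = np.linalg.solve(des.X.T @ W @ des.X + S, des.X.T @ W @ des.y)
        assert np.max(np.abs(beta - f.beta)) / np.max(np.abs(beta)) < 1e-8

    def test_zero_penalty_rich_basis_interpolates_noise_free(self):
        rng = np.random.default_rng(2)
        x = np.sort(rng.uniform(0, 1, 25))
        df = pd.DataFrame({"x": x, "y": np.sin(4 * x)})
        des = build_design(_spec([SmoothTerm("x", k=25)]), df)
        f = fit(des, lambdas=[0.0])
        assert float(np.sum(f.residuals**2)) < 1e-8

    def test_linear_truth_recovered(self):
        rng = np.random.default_rng(3)
        n = 500
        df = pd.DataFrame({"x": rng.uniform(0, 1, n)})
        df["y"] = 2 * df.x + rng.normal(0, 0.1, n)
        f = fit(build_design(_spec([SmoothTerm("x")]), df))
        rn = reaction_norm(f, "x")
        line = 2 * rn.grid
        line = line - line.mean()
        central = slice(10, 90)
        assert np.max(np.abs(rn.effect[central] - line[central])) < 0.05
        assert f.edf["x"] < 4.0  # close to the 2-df line, penalty active

    def test_pure_noise_smooth_shrinks(self):
        rng = np.random.default_rng(4)
        n = 500
        df = pd.DataFrame({"x": rng.uniform(0, 1, n),
                           "y": rng.normal(0, 1.0, n)})
        f = fit(build_design(_spec([SmoothTerm("x")]), df))
        rn = reaction_norm(f, "x")
        assert f.edf["x"] < 1.5
        assert np.max(np.abs(rn.effect)) < 1.0  # well inside the noise sd

    def test_weight_scale_invariance(self):
        rng = np.random.default_rng(5)
        n = 200
        df = pd.DataFrame({"x": rng.uniform(0, 1, n), "w": rng.uniform(1, 3, n)})
        df["y"] = np.sin(5 * df.x) + rng.normal(0, 0.2, n)
        des1 = build_design(_spec([SmoothTerm("x")], weights_col="w"), df)
        df2 = df.assign(w=df.w * 10)
        des2 = build_design(_spec([SmoothTerm("x")], weights_col="w"), df2)
        f1 = fit(des1, lambdas=[1.0])
        f2 = fit(des2, lambdas=[1.0])
        np.testing.assert_allclose(f1.beta, f2.beta, rtol=1e-10)

    def test_random_intercept_sd_recovered(self):
        """Animal intercept sd 0.3 at 100 animals x 60 days is estimated
        within [0.15, 0.45]."""
        rng = np.random.default_rng(6)
        n_animals, n_days = 100, 60
        a_eff = rng.normal(0, 0.3, n_animals)
        rows = []
        for a in range(n_animals):
            x = rng.uniform(0, 10, n_days)
            y = np.sin(x) + a_eff[a] + rng.normal(0, 0.4, n_days)
            rows += [(f"a{a}", xi, yi) for xi, yi in zip(x, y)]
        df = pd.DataFrame(rows, columns=["animal_id", "x", "y"])
        f = fit(build_design(
            _spec([SmoothTerm("x"), RandomIntercept("animal_id")]), df
        ))
        assert 0.15 <= f.variance_components["animal_id"] <= 0.45


class TestAR1:
    def _daily_frame(self, rho, n_animals=100, n_days=50, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(n_animals):
            e = np.empty(n_days)
            e[0] = rng.normal()
            innov = rng.normal(0, np.sqrt(1 - rho**2), n_days)
            for t in range(1, n_days):
                e[t] = rho * e[t - 1] + innov[t]
            x = rng.uniform(0, 10, n_days)
            day0 = pd.Timestamp("2012-01-01")
            for t in range(n_days):
                rows.append((f"a{a}", day0 + pd.Timedelta(days=t),
                             x[t], np.sin(x[t]) + e[t]))
        return pd.DataFrame(rows, columns=["animal_id", "bio_day", "x", "y"])

    def test_independent_residuals_rho_near_zero(self):
        df = self._daily_frame(rho=0.0, seed=1)
        f = fit_ar1(build_design(
            ModelSpec("y", "daily", "t", [SmoothTerm("x")], ar1=True), df
        ))
        assert abs(f.rho) < 0.05

    def test_rho_half_recovered(self):
        df = self._daily_frame(rho=0.5, seed=2)
        f = fit_ar1(build_design(
            ModelSpec("y", "daily", "t", [SmoothTerm("x")], ar1=True), df
        ))
        assert 0.4 <= f.rho <= 0.6

    def test_single_day_series_contribute_no_lag_pairs(self):
        sids = np.array([0, 1, 2, 3])
        days = np.array([0, 5, 9, 14])
        start = gamm._runs(sids, days)
        assert start.all()
        resid = np.array([1.0, -1.0, 1.0, -1.0])
        assert gamm._pooled_rho(resid, start) == 0.0


class TestReactionNorm:
    def test_effect_mean_over_data_is_zero(self):
        rng = np.random.default_rng(7)
        n = 300
        df = pd.DataFrame({"x": rng.uniform(0, 1, n)})
        df["y"] = (df.x - 0.5) ** 2 + rng.normal(0, 0.05, n)
        f = fit(build_design(_spec([SmoothTerm("x")]), df))
        sm = [b for b in f.design.blocks if b.kind == "smooth"][0]
        effect_at_data = sm.basis.design(df["x"].to_numpy()) @ f.beta[sm.sl]
        assert abs(effect_at_data.mean()) < 1e-8

    def test_quadratic_truth_concave_with_peak(self):
        rng = np.random.default_rng(8)
        n = 2000
        x = rng.uniform(5, 35, n)
        y = -0.01 * (x - 20.0) ** 2 + rng.normal(0, 0.3, n)
        f = fit(build_design(_spec([SmoothTerm("x")]),
                             pd.DataFrame({"x": x, "y": y})))
        rn = reaction_norm(f, "x")
        assert rn.shape == "concave"
        assert abs(rn.argmax - 20.0) < 3.0

    def test_linear_truth_classified_none(self):
        flags = []
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            n = 800
            x = rng.uniform(0, 10, n)
            y = 0.5 * x + rng.normal(0, 0.3, n)
            f = fit(build_design(_spec([SmoothTerm("x")]),
                                 pd.DataFrame({"x": x, "y": y})))
            flags.append(reaction_norm(f, "x").shape)
        assert flags.count("none") >= 9

    def test_unknown_covariate_raises(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 50),
                           "y": np.linspace(0, 1, 50)})
        f = fit(build_design(_spec([SmoothTerm("x")]), df))
        with pytest.raises(KeyError):
            reaction_norm(f, "zzz")
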