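"""Statistical machinery: standardization, collinearity, mixed models,
AICc ranking, marginal r2, cross-validated AUC, diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats
from scipy.special import expit

import wintrack as wt
from wintrack.models import ModelSpec, _binomial_loglik, aicc, fit_mixed


class TestStandardizer:
    def test_idempotent_on_standardized_data(self, rng):
        x = pd.DataFrame({"a": rng.normal(size=500)})
        z = wt.Standardizer().fit_transform(x)
        z2 = wt.Standardizer().fit_transform(z)
        assert np.allclose(z2, z, atol=1e-10)

    def test_constant_column_rejected_by_name(self):
        x = pd.DataFrame({"good": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            wt.Standardizer().fit(x)

    def test_round_trip_recovers_input(self, rng):
        x = pd.DataFrame({"a": rng.normal(3, 7, 200), "b": rng.uniform(0, 1, 200)})
        sc = wt.Standardizer().fit(x)
        back = sc.inverse_transform(sc.transform(x))
        assert np.allclose(back, x, atol=1e-10)


class TestCollinearity:
    def test_orthogonal_columns_unit_vif(self):
        n = 64
        t = np.arange(n)
        X = pd.DataFrame({"s": np.sin(2 * np.pi * t / n), "c": np.cos(2 * np.pi * t / n)})
        out = wt.collinearity_screen(X)
        assert np.allclose(out["vif"], 1.0, atol=1e-9)
        assert out["ok"]

    def test_duplicated_column_flagged(self, rng):
        a = rng.normal(size=100)
        out = wt.collinearity_screen(pd.DataFrame({"a": a, "b": a + 1e-9 * rng.normal(size=100)}))
        assert ("a", "b") in out["flagged_pairs"]
        assert not out["ok"]

    def test_three_column_closed_form_vif(self, rng):
        """x3 = x1 + x2 + noise: VIF(x3) must equal 1/(1-R^2) of the
        regression of x3 on the others."""
        n = 2000
        x1 = rng.normal(size=n)
        x2 = rng.normal(size=n)
        x3 = x1 + x2 + rng.normal(scale=2.0, size=n)
        X = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        out = wt.collinearity_screen(X)
        import statsmodels.api as sm

        r2 = sm.OLS(x3, sm.add_constant(np.column_stack([x1, x2]))).fit().rsquared
        assert out["vif"]["x3"] == pytest.approx(1 / (1 - r2), rel=1e-6)


class TestAicc:
    def test_closed_form_value(self):
        assert aicc(-100.0, 3, 50) == pytest.approx(206 + 24 / 46)

    def test_approaches_aic_for_large_n(self):
        aic = -2 * (-500.0) + 2 * 5
        assert abs(aicc(-500.0, 5, 10**6) - aic) < 0.01

    def test_identical_fits_rank_with_zero_delta(self, rng):
        data = pd.DataFrame(
            {"y": rng.normal(size=60), "x": rng.normal(size=60), "g": np.repeat([0, 1, 2], 20)}
        )
        spec = ModelSpec("y", ["x"], "g", "gaussian")
        fits = [fit_mixed(spec, data), fit_mixed(spec, data)]
        table = wt.rank_aicc(fits)
        assert table["delta_aicc"].iloc[1] == pytest.approx(0.0, abs=1e-8)

    def test_noise_term_ranks_behind_simpler_model(self, rng):
        """Nested gaussian models where the extra covariate is pure
        noise: AICc prefers the simpler model in a clear majority of
        seeds at large n."""
        wins = 0
        n_seeds = 40
        for s in range(n_seeds):
            r = np.random.default_rng(s)
            n = 800
            data = pd.DataFrame(
                {
                    "x": r.normal(size=n),
                    "junk": r.normal(size=n),
                    "g": np.repeat(np.arange(8), n // 8),
                }
            )
            data["y"] = 0.5 * data["x"] + r.normal(size=n)
            f1 = fit_mixed(ModelSpec("y", ["x"], "g", "gaussian", label="lean"), data)
            f2 = fit_mixed(ModelSpec("y", ["x", "junk"], "g", "gaussian", label="noisy"), data)
            wins += wt.rank_aicc([f1, f2])["label"].iloc[0] == "lean"
        assert wins / n_seeds > 0.5

    def test_mismatched_data_rejected(self, rng):
        d1 = pd.DataFrame({"y": rng.normal(size=40), "x": rng.normal(size=40), "g": [0, 1] * 20})
        d2 = d1.iloc[:30]
        spec = ModelSpec("y", ["x"], "g", "gaussian")
        with pytest.raises(ValueError, match="identical data"):
            wt.rank_aicc([fit_mixed(spec, d1), fit_mixed(spec, d2)])


class TestGaussianMixed:
    def test_no_random_variance_matches_ols(self, rng):
        n = 400
        data = pd.DataFrame({"x": rng.normal(size=n), "g": np.repeat(np.arange(8), 50)})
        data["y"] = 1.0 + 2.0 * data["x"] + rng.normal(scale=0.5, size=n)
        fit = fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), data)
        import statsmodels.api as sm

        ols = sm.OLS(data["y"], sm.add_constant(data["x"])).fit()
        assert fit.params["x"] == pytest.approx(ols.params["x"], abs=0.01)
        assert fit.random_sd < 0.15

    def test_ci_covers_truth_across_seeds(self):
        """95% Wald CIs from the mixed fit cover the generating slope in
        at least 90% of 100 simulated datasets."""
        covered = 0
        for s in range(100):
            r = np.random.default_rng(s)
            g = np.repeat(np.arange(10), 20)
            x = r.normal(size=200)
            y = 1.5 * x + r.normal(scale=0.5, size=10)[g] + r.normal(size=200)
            data = pd.DataFrame({"y": y, "x": x, "g": g})
            fit = fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), data)
            lo, hi = fit.conf_int.loc["x"]
            covered += lo <= 1.5 <= hi
        assert covered >= 90

    def test_marginal_r2_zero_when_no_fixed_effects_matter(self, rng):
        n = 300
        data = pd.DataFrame({"x": rng.normal(size=n), "g": np.repeat(np.arange(6), 50)})
        data["y"] = rng.normal(size=n)
        fit = fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), data)
        assert wt.marginal_r2(fit) < 0.03

    def test_marginal_r2_recovers_variance_share(self):
        """Known decomposition: slope 1 on unit-variance x, random SD
        0.5, residual SD 0.5 -> share = 1/(1+0.25+0.25) = 2/3."""
        r = np.random.default_rng(7)
        n = 5000
        g = np.repeat(np.arange(50), n // 50)
        x = r.normal(size=n)
        y = x + r.normal(scale=0.5, size=50)[g] + r.normal(scale=0.5, size=n)
        fit = fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), pd.DataFrame({"y": y, "x": x, "g": g}))
        assert wt.marginal_r2(fit) == pytest.approx(2 / 3, abs=0.05)


class TestBinomialMixed:
    @staticmethod
    def _tiny():
        r = np.random.default_rng(3)
        n = 24
        g = np.repeat([0, 1, 2], 8)
        x = r.normal(size=n)
        b = np.array([0.8, -0.4, 0.1])
        y = (r.uniform(size=n) < expit(0.3 + x + b[g])).astype(float)
        w = np.where(y == 1, 1.0, 0.5)
        return pd.DataFrame({"y": y, "x": x, "g": g, "w": w})

    def test_quadrature_matches_brute_force_integration(self):
        """The Gauss-Hermite marginal log-likelihood equals direct
        numerical integration of the random intercept on a tiny
        fixture."""
        data = self._tiny()
        X = np.column_stack([np.ones(len(data)), data["x"]])
        y = data["y"].to_numpy()
        codes = data["g"].to_numpy()
        w = data["w"].to_numpy()
        theta = np.array([0.2, 0.9, np.log(0.6)])
        nodes, qw = np.polynomial.hermite.hermgauss(40)
        lognorm = np.log(qw) - 0.5 * np.log(np.pi)
        got = _binomial_loglik(theta, X, y, codes, 3, w, nodes, lognorm)

        sigma = np.exp(theta[-1])
        eta0 = X @ theta[:2]
        brute = 0.0
        for g in range(3):
            m = codes == g

            def integrand(b, m=m):
                eta = eta0[m] + b
                ll = (w[m] * (y[m] * eta - np.logaddexp(0, eta))).sum()
                return np.exp(ll) * stats.norm.pdf(b, 0, sigma)

            val, _ = integrate.quad(integrand, -8 * sigma, 8 * sigma, limit=200)
            brute += np.log(val)
        assert got == pytest.approx(brute, abs=1e-6)

    def test_weighted_fit_equals_duplicated_row_oracle(self):
        """Available rows at weight 1/2 reproduce the fit where every
        used row is duplicated (equal total class contribution)."""
        data = self._tiny()
        spec_w = ModelSpec("y", ["x"], "g", "binomial", weights="w")
        fit_w = fit_mixed(spec_w, data)
        dup = pd.concat([data, data[data["y"] == 1]], ignore_index=True)
        fit_d = fit_mixed(ModelSpec("y", ["x"], "g", "binomial"), dup)
        # identical MLEs up to optimizer tolerance
        assert fit_w.params["x"] == pytest.approx(fit_d.params["x"], abs=5e-3)

    def test_duplicate_available_halve_weight_invariance(self, rng):
        """Doubling every available row while halving its weight leaves
        the coefficients unchanged."""
        n = 300
        g = np.repeat(np.arange(5), 60)
        x = rng.normal(size=n)
        y = (rng.uniform(size=n) < expit(-0.5 * x)).astype(float)
        d = pd.DataFrame({"y": y, "x": x, "g": g, "w": np.where(y == 1, 1.0, 0.5)})
        avail = d[d["y"] == 0].assign(w=lambda t: t["w"] / 2)
        doubled = pd.concat([d[d["y"] == 1].assign(w=1.0), avail, avail], ignore_index=True)
        spec = ModelSpec("y", ["x"], "g", "binomial", weights="w")
        f1 = fit_mixed(spec, d)
        f2 = fit_mixed(spec, doubled)
        assert f1.params["x"] == pytest.approx(f2.params["x"], abs=1e-3)

    def test_recovers_known_slope(self):
        r = np.random.default_rng(11)
        n = 4000
        g = np.repeat(np.arange(10), n // 10)
        x = r.normal(size=n)
        y = (r.uniform(size=n) < expit(-1.0 * x + r.normal(scale=0.5, size=10)[g])).astype(float)
        fit = fit_mixed(ModelSpec("y", ["x"], "g", "binomial"), pd.DataFrame({"y": y, "x": x, "g": g}))
        assert fit.params["x"] == pytest.approx(-1.0, abs=0.12)
        assert 0.2 < fit.random_sd < 1.0

    def test_degenerate_single_class_rejected(self):
        d = pd.DataFrame({"y": np.ones(20), "x": np.arange(20.0), "g": [0, 1] * 10})
        with pytest.raises(ValueError, match="one class"):
            fit_mixed(ModelSpec("y", ["x"], "g", "binomial"), d)


class TestCvAuc:
    def test_perfectly_separable_fixture(self):
        n = 200
        x = np.r_[np.linspace(-3, -1, n // 2), np.linspace(1, 3, n // 2)]
        d = pd.DataFrame({"y": (x > 0).astype(float), "x": x, "g": np.tile([0, 1], n // 2)})
        out = wt.cv_auc(ModelSpec("y", ["x"], "g", "binomial"), d, k=5, seed=0)
        assert np.allclose(out["fold_auc"], 1.0)

    def test_null_predictors_give_chance_auc(self, rng):
        n = 10_000
        d = pd.DataFrame(
            {
                "y": rng.integers(0, 2, n).astype(float),
                "x": rng.normal(size=n),
                "g": rng.integers(0, 10, n),
            }
        )
        out = wt.cv_auc(ModelSpec("y", ["x"], "g", "binomial"), d, k=5, seed=1, n_quad=9)
        assert abs(out["mean"] - 0.5) < 0.03

    def test_auc_equals_pairwise_rank_oracle(self):
        """Ten-row example: AUC must equal the brute-force probability
        that a positive outscores a negative, ties counting half."""
        y = np.array([1, 0, 1, 1, 0, 0, 1, 0, 0, 1])
        s = np.array([0.9, 0.3, 0.8, 0.3, 0.3, 0.1, 0.75, 0.7, 0.2, 0.6])
        pos = s[y == 1]
        neg = s[y == 0]
        brute = np.mean([(p > q) + 0.5 * (p == q) for p in pos for q in neg])
        assert wt.auc_rank(y, s) == pytest.approx(brute, abs=1e-12)


class TestDiagnostics:
    def test_perfect_fit_residuals_zero(self):
        d = pd.DataFrame({"x": np.arange(40.0), "g": [0, 1] * 20})
        d["y"] = 2 * d["x"] + 1
        fit = fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), d)
        out = wt.diagnostics(fit)
        assert np.abs(out["residuals"]).max() < 1e-6

    def test_gaussian_truth_straight_qq(self, rng):
        d = pd.DataFrame({"x": rng.normal(size=1000), "g": np.repeat(np.arange(10), 100)})
        d["y"] = d["x"] + rng.normal(size=1000)
        out_g = wt.diagnostics(fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), d))
        assert out_g["qq_correlation"] > 0.99
        d2 = d.copy()
        d2["y"] = d2["x"] + rng.standard_cauchy(size=1000)
        out_h = wt.diagnostics(fit_mixed(ModelSpec("y", ["x"], "g", "gaussian"), d2))
        assert out_h["qq_correlation"] < out_g["qq_correlation"]
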