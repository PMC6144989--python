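"""Used-available tables, trail-scale screening, RSF ranking, temporal
activity, and functional responses."""

import warnings

import numpy as np
import pandas as pd
import pytest
import shapely
from shapely.geometry import Polygon

import wintrack as wt
from wintrack.models import ModelSpec, fit_mixed


def unit_square(side=1.0):
    return Polygon([(0, 0), (side, 0), (side, side), (0, side)])


class TestSampleAvailable:
    def test_counts_and_containment(self, rng):
        poly = unit_square(100.0)
        pts = wt.sample_available(poly, 10, ratio=2, rng=rng)
        assert pts.shape == (20, 2)
        assert shapely.contains_xy(poly, pts[:, 0], pts[:, 1]).all()

    def test_ratio_one(self, rng):
        assert wt.sample_available(unit_square(10.0), 7, ratio=1, rng=rng).shape == (7, 2)

    def test_degenerate_polygon_rejected(self, rng):
        line = Polygon([(0, 0), (1, 0), (2, 0)])
        with pytest.raises(ValueError, match="degenerate"):
            wt.sample_available(line, 5, rng=rng)

    def test_quadrant_uniformity(self):
        """Chi-square over a 4-quadrant partition is non-significant in
        at least 90% of seeds."""
        from scipy.stats import chisquare

        poly = unit_square(2.0)
        ok = 0
        n_seeds = 30
        for s in range(n_seeds):
            pts = wt.sample_available(poly, 200, ratio=2, rng=np.random.default_rng(s))
            q = (pts[:, 0] > 1).astype(int) * 2 + (pts[:, 1] > 1).astype(int)
            _, p = chisquare(np.bincount(q, minlength=4))
            ok += p > 0.05
        assert ok >= 0.9 * n_seeds


class TestUseAvailableTable:
    def test_ratio_weights_and_containment(self, small_scenario):
        sc = small_scenario
        surfs = {"snowmobile": sc.surfaces[("snowmobile", 1000.0)]}
        tab = wt.build_use_available_table(
            sc.fixes, surfs, canopy=sc.canopy, grid=sc.config.grid,
            rng=np.random.default_rng(0),
        )
        for (_, _), g in tab.groupby(["animal_id", "year"]):
            n_used = (g["used"] == 1).sum()
            assert (g["used"] == 0).sum() == 2 * n_used
        assert (tab.loc[tab["used"] == 1, "weight"] == 1.0).all()
        assert (tab.loc[tab["used"] == 0, "weight"] == 0.5).all()
        # used rows fall inside their animal's 95% MCP by construction
        for (a, _), g in tab.groupby(["animal_id", "year"]):
            f = sc.fixes[sc.fixes["animal_id"] == a]
            mcp = wt.mcp_home_range(f[["x", "y"]].to_numpy(), 95)
            u = g[g["used"] == 1]
            assert shapely.contains_xy(
                mcp.buffer(1e-6), u["x"].to_numpy(), u["y"].to_numpy()
            ).all()
        assert set(tab["period"]) <= {"day", "night"}


def _trail_table(effect: str, n_per_animal=260, n_animals=6, seed=0):
    """Used-available rows where use either clusters within 250 m of a
    trail or is independent of it."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        n_used = n_per_animal
        d_avail = rng.uniform(0, 2000, 2 * n_used)
        if effect == "near":
            d_used = rng.uniform(0, 250, n_used)
        else:
            d_used = rng.uniform(0, 2000, n_used)
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": f"a{a}",
                    "year": 2012,
                    "used": np.r_[np.ones(n_used), np.zeros(2 * n_used)],
                    "weight": np.r_[np.ones(n_used), np.full(2 * n_used, 0.5)],
                    "dist_trail_backcountry_ski": np.r_[d_used, d_avail],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestSelectTrailScale:
    def test_near_trail_use_prefers_small_scale(self):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = wt.select_trail_scale(_trail_table("near"), "backcountry_ski", n_quad=7)
        if out["form"] == "binary":
            assert out["value"] == 250.0
        else:
            assert out["value"] <= 250.0

    def test_trail_independent_use_gives_flat_ranking(self):
        """Without any trail effect the 8 forms should separate by only
        a few AICc units in most seeds."""
        flat = 0
        for s in range(5):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = wt.select_trail_scale(
                    _trail_table("none", seed=s), "backcountry_ski", n_quad=7
                )
            flat += out["ranking"]["delta_aicc"].iloc[-1] < 6
        assert flat >= 3

    def test_single_candidate_returned_unchanged(self):
        out = wt.select_trail_scale(
            _trail_table("none"), "backcountry_ski", forms=[("decay", 500.0)]
        )
        assert out["form"] == "decay" and out["value"] == 500.0

    def test_no_trail_sentinel_returns_none(self):
        tab = _trail_table("none")
        tab["dist_trail_backcountry_ski"] = np.nan
        with pytest.warns(UserWarning, match="no trails"):
            assert wt.select_trail_scale(tab, "backcountry_ski") is None


def _rsf_fixture(beta, seed=0, n_animals=6, n_used=300):
    """Direct used-available rows from a known exponential selection
    model on a standardized intensity covariate."""
    rng = np.random.default_rng(seed)
    rows = []
    for a in range(n_animals):
        z_avail = rng.normal(size=8 * n_used)
        keep = rng.uniform(size=8 * n_used) < np.exp(beta * z_avail) / np.exp(
            np.abs(beta) * 4
        )
        z_used = z_avail[keep][:n_used]
        z_av = rng.normal(size=2 * n_used)
        rows.append(
            pd.DataFrame(
                {
                    "animal_id": f"a{a}",
                    "year": 2012,
                    "used": np.r_[np.ones(len(z_used)), np.zeros(2 * n_used)],
                    "weight": np.r_[np.ones(len(z_used)), np.full(2 * n_used, 0.5)],
                    "intensity_snowmobile": np.r_[z_used, z_av],
                    "canopy": rng.normal(size=len(z_used) + 2 * n_used),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


class TestFitRsf:
    def test_strong_avoidance_recovered_in_best_model(self):
        tab = _rsf_fixture(-2.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = wt.fit_rsf(tab, "snowmobile", cv=False, n_quad=7,
                             standardize_covariates=False)
        best = out["best"]
        assert "intensity_snowmobile" in best.params.index
        coef = best.params["intensity_snowmobile"]
        assert coef < 0 and coef == pytest.approx(-2.0, abs=0.4)

    def test_null_effect_keeps_base_model_competitive(self):
        """With no intensity effect the canopy-only base model sits
        within 2 AICc of the top in most seeds."""
        close = 0
        for s in range(5):
            tab = _rsf_fixture(0.0, seed=s, n_animals=4, n_used=200)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                out = wt.fit_rsf(tab, "snowmobile", cv=False, n_quad=7,
                                 standardize_covariates=False)
            r = out["ranking"]
            delta = float(r.loc[r["label"] == "canopy", "delta_aicc"].iloc[0])
            close += delta < 2.0
        assert close >= 3

    def test_predictions_invariant_to_availability_ratio(self, small_scenario):
        """Slope coefficients agree between 1:2 and 1:10 designs (the
        intercept absorbs the ratio)."""
        sc = small_scenario
        surfs = {"snowmobile": sc.surfaces[("snowmobile", 1000.0)]}
        fits = {}
        for ratio in (2, 10):
            tab = wt.build_use_available_table(
                sc.fixes, surfs, canopy=sc.canopy, grid=sc.config.grid,
                ratio=ratio, rng=np.random.default_rng(5),
            )
            spec = ModelSpec("used", ["canopy", "intensity_snowmobile"],
                             "animal_id", "binomial", weights="weight")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fits[ratio] = fit_mixed(spec, tab, n_quad=7)
        se = fits[2].bse["intensity_snowmobile"]
        diff = fits[2].params["intensity_snowmobile"] - fits[10].params["intensity_snowmobile"]
        assert abs(diff) < 3 * se


class TestTemporalActivity:
    @staticmethod
    def _activity_fixture(b_day_west, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for a in range(8):
            area = "west" if a % 2 == 0 else "east"
            n = 1000
            z = rng.normal(size=n)
            period = np.where(rng.uniform(size=n) < 0.5, "day", "night")
            b = b_day_west if area == "west" else 0.0
            eta = 0.4 + b * z * (period == "day")
            active = (rng.uniform(size=n) < 1 / (1 + np.exp(-eta))).astype(float)
            rows.append(pd.DataFrame({
                "animal_id": f"a{a}", "area": area, "period": period,
                "intensity_snowmobile": z, "active": active,
            }))
        return pd.concat(rows, ignore_index=True)

    def test_day_activity_declines_only_where_generated(self):
        tab = self._activity_fixture(-1.2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = wt.fit_temporal_activity(tab, "snowmobile", cv=False, n_quad=7)
        curves = out["curves"]
        wd = curves["west_day"]["p_active"]
        slope_west_day = wd.iloc[-1] - wd.iloc[0]
        en = curves["east_night"]["p_active"]
        slope_east_night = en.iloc[-1] - en.iloc[0]
        assert slope_west_day < -0.2
        # the stratum with no generated effect stays comparatively flat
        assert abs(slope_east_night) < 0.5 * abs(slope_west_day)

    def test_all_active_degenerate(self):
        tab = self._activity_fixture(0.0)
        tab["active"] = 1.0
        with pytest.raises(ValueError, match="degenerate"):
            wt.fit_temporal_activity(tab, "snowmobile")


class TestFunctionalResponse:
    @staticmethod
    def _fr_table(x, y):
        rows = []
        for i, (xa, ya) in enumerate(zip(x, y)):
            rows.append({"animal_id": f"i{i}", "year": 2012, "used": 1, "intensity_hybrid": ya})
            rows.append({"animal_id": f"i{i}", "year": 2012, "used": 0, "intensity_hybrid": xa})
        return pd.DataFrame(rows)

    def test_use_equal_availability_gives_unit_slope_and_ratios(self, rng):
        x = rng.uniform(0.5, 2.0, 12)
        out = wt.functional_response(self._fr_table(x, x), "hybrid")
        assert out["slope"] == pytest.approx(1.0, abs=1e-9)
        assert np.allclose(out["individuals"]["selection_ratio"], 1.0)
        assert not out["functional_response_supported"]

    def test_zero_availability_individual_excluded(self, rng):
        x = np.r_[rng.uniform(0.5, 2.0, 11), 0.0]
        y = np.r_[x[:11] * 1.0, 0.3]
        with pytest.warns(UserWarning, match="zero/undefined"):
            out = wt.functional_response(self._fr_table(x, y + rng.normal(0, 0.01, 12)), "hybrid")
        assert len(out["individuals"]) == 11

    def test_too_few_individuals_rejected(self, rng):
        x = rng.uniform(0.5, 1.0, 4)
        with pytest.raises(ValueError, match=">= 5"):
            wt.functional_response(self._fr_table(x, x), "hybrid")

    def test_quadratic_truth_detected(self, rng):
        x = rng.uniform(0.1, 1.0, 20)
        y = 0.1 + x - 2.0 * x**2 + rng.normal(0, 0.05, 20)
        out = wt.functional_response(self._fr_table(x, y), "hybrid")
        assert out["best_form"] == "quadratic"
        assert out["functional_response_supported"]

    def test_ratio_minus_one_table_convention(self, rng):
        x = rng.uniform(0.5, 2.0, 8)
        y = 0.5 * x
        out = wt.functional_response(self._fr_table(x, y), "hybrid")
        ind = out["individuals"]
        assert np.allclose(ind["ratio_minus_1"], -0.5)
        assert ind["relative_availability"].max() == pytest.approx(1.0)
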