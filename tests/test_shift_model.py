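"""Weighted regression, best subsets, parsimony selection, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

import edgeshift as es
from edgeshift.shift_model import (
    RankDeficientError,
    per_size_best,
)


class TestWlsFit:
    def test_perfect_fit(self):
        x = np.arange(10.0)
        tab = pd.DataFrame({"shift_km": 2 * x, "x": x, "weight": 1.0})
        m = es.wls_fit(tab, ("x",))
        # on the standardized scale the slope is 2 * SD(x)
        assert m.params["x"] == pytest.approx(2 * np.std(x, ddof=1))
        assert m.r2 == pytest.approx(1.0)
        assert m.adj_r2 == pytest.approx(1.0)
        assert m.pred_r2 == pytest.approx(1.0)

    def test_null_model_is_weighted_mean(self, regression_table):
        m = es.wls_fit(regression_table, ())
        w = regression_table["weight"]
        y = regression_table["shift_km"]
        assert m.params["Intercept"] == pytest.approx((w * y).sum() / w.sum())
        assert m.r2 == pytest.approx(0.0)

    def test_loglik_invariant_to_weight_rescaling(self, regression_table):
        # sum(log w) and the n*log(RSS_w/n) terms cancel exactly, so
        # coefficients, R2, logLik and hence AIC ignore weight rescaling
        m1 = es.wls_fit(regression_table, ("x1", "x2"))
        doubled = regression_table.assign(weight=2 * regression_table["weight"])
        m2 = es.wls_fit(doubled, ("x1", "x2"))
        assert np.allclose(m1.params, m2.params)
        assert m1.r2 == pytest.approx(m2.r2)
        assert m1.loglik == pytest.approx(m2.loglik)
        assert m1.aic == pytest.approx(m2.aic)

    def test_matches_statsmodels_wls(self, regression_table):
        import statsmodels.api as sm

        m = es.wls_fit(regression_table, ("x1", "x2"))
        X = sm.add_constant(
            np.column_stack(
                [
                    (regression_table[c] - regression_table[c].mean())
                    / regression_table[c].std(ddof=1)
                    for c in ("x1", "x2")
                ]
            )
        )
        ref = sm.WLS(
            regression_table["shift_km"], X, weights=regression_table["weight"]
        ).fit()
        assert np.allclose(m.params.to_numpy(), ref.params)
        assert np.allclose(m.bse.to_numpy(), ref.bse)
        assert np.allclose(m.pvalues.to_numpy(), ref.pvalues)

    def test_matches_direct_loss_minimization(self, regression_table):
        m = es.wls_fit(regression_table, ("x1", "x2", "f"))
        d = m.design

        def loss(beta):
            r = d.y - d.X @ beta
            return np.sum(d.w * r**2)

        def grad(beta):
            return -2 * d.X.T @ (d.w * (d.y - d.X @ beta))

        res = optimize.minimize(
            loss, np.zeros(m.k), jac=grad, method="BFGS",
            options={"gtol": 1e-12, "maxiter": 1000},
        )
        assert np.max(np.abs(res.x - m.params.to_numpy())) < 1e-8

    def test_rank_deficient_design_names_alias(self, regression_table):
        tab = regression_table.assign(x3=regression_table["x1"])
        with pytest.raises(RankDeficientError, match="x3"):
            es.wls_fit(tab, ("x1", "x2", "x3"))

    def test_zero_variance_predictor_rejected(self, regression_table):
        tab = regression_table.assign(const=1.0)
        with pytest.raises(ValueError, match="zero variance"):
            es.wls_fit(tab, ("const",))

    def test_reference_level_controls_contrasts(self, regression_table):
        m = es.wls_fit(
            regression_table, ("f",), reference_levels={"f": ["c", "a", "b"]}
        )
        assert "f[a]" in m.params.index and "f[c]" not in m.params.index


class TestBestSubsets:
    def test_two_candidates_give_powerset(self, regression_table):
        cands = es.best_subsets(regression_table, ("x1", "x2"))
        assert sorted(c.predictors for c in cands) == [
            (), ("x1",), ("x1", "x2"), ("x2",)
        ]

    def test_per_size_best_matches_exhaustive_recomputation(self, regression_table):
        candidates = ("x1", "x2", "f")
        cands = es.best_subsets(regression_table, candidates)
        for size in (1, 2, 3):
            best = [c for c in cands if c.size == size and c.best_in_size]
            assert len(best) == 1
            brute = max(
                (
                    es.wls_fit(regression_table, s).r2
                    for s in itertools.combinations(candidates, size)
                ),
            )
            assert best[0].r2 == pytest.approx(brute)

    def test_noise_predictor_increases_aic_on_average(self):
        # adding a pure-noise predictor raises the AIC in expectation
        rng = np.random.default_rng(17)
        deltas = []
        for _ in range(300):
            n = 100
            x = rng.normal(size=n)
            noise = rng.normal(size=n)
            tab = pd.DataFrame(
                {"shift_km": 2 * x + rng.normal(size=n), "x": x, "noise": noise}
            )
            small = es.wls_fit(tab, ("x",), weights=None)
            big = es.wls_fit(tab, ("x", "noise"), weights=None)
            deltas.append(big.aic - small.aic)
        assert np.mean(deltas) > 0


class TestSelectFinal:
    # per-size AIC vectors as printed for the three species groups; the
    # parsimony rule picks sizes 3, 3 and 1
    MOTHS = [2911.2071, 2894.5814, 2888.1533, 2887.7337, 2887.3376,
             2888.7340, 2890.3699, 2892.1833]
    BIRDS = [992.2917, 987.7673, 983.1005, 983.7848, 984.0905,
             985.6845, 987.1365, 989.0148]
    BUTTERFLIES = [673.4953, 675.0447, 674.8316, 675.7916, 677.6021,
                   678.9105, 680.8292, 682.8228]

    @pytest.mark.parametrize(
        "aics,expected_size",
        [(MOTHS, 3), (BIRDS, 3), (BUTTERFLIES, 1)],
    )
    def test_reproduces_published_choices(self, aics, expected_size):
        sel = es.select_final(list(enumerate(aics, start=1)), delta=2.0)
        assert sel.size == expected_size

    def test_size_tie_broken_by_lower_aic(self):
        sel = es.select_final([(2, 100.5), (2, 100.0), (3, 99.0)], delta=2.0)
        assert sel.aic == 100.0

    def test_larger_model_needs_two_full_units(self):
        assert es.select_final([(1, 102.0), (2, 100.1)]).size == 1
        assert es.select_final([(1, 102.1), (2, 100.0)]).size == 2

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            es.select_final([])


class TestDrop1:
    def test_dropping_only_predictor_reproduces_null_rss(self, regression_table):
        m = es.wls_fit(regression_table, ("x1",))
        null = es.wls_fit(regression_table, ())
        table = es.drop1(m)
        assert table.loc[table["dropped"] == "x1", "rss"].iloc[0] == pytest.approx(
            null.rss_w
        )

    def test_factor_drops_as_block(self, regression_table):
        tab = regression_table.assign(
            f4=np.tile(["a", "b", "c", "d"], len(regression_table) // 4)
        )
        m = es.wls_fit(tab, ("x1", "f4"))
        table = es.drop1(m)
        assert table.loc[table["dropped"] == "f4", "ddf"].iloc[0] == 3

    def test_delta_ss_is_rss_increase(self, regression_table):
        m = es.wls_fit(regression_table, ("x1", "x2"))
        table = es.drop1(m)
        row = table[table["dropped"] == "x1"].iloc[0]
        assert row["delta_ss"] == pytest.approx(row["rss"] - m.rss_w)
        assert (table["delta_ss"].dropna() >= 0).all()


class TestDiagnostics:
    def test_orthonormal_design_unit_vifs(self):
        n = 64
        t = np.arange(n)
        tab = pd.DataFrame(
            {
                "shift_km": np.cos(2 * np.pi * 3 * t / n),
                "a": np.cos(2 * np.pi * t / n),
                "b": np.sin(2 * np.pi * 2 * t / n),
            }
        )
        m = es.wls_fit(tab, ("a", "b"), weights=None)
        diag = es.diagnostics(m)
        assert diag["gvif"]["a"] == pytest.approx(1.0, abs=1e-8)
        assert diag["gvif"]["b"] == pytest.approx(1.0, abs=1e-8)

    def test_injected_outlier_dominates_cooks_distance(self):
        rng = np.random.default_rng(23)
        n = 60
        x = rng.normal(size=n)
        y = 1.0 + 0.5 * x + rng.normal(0, 0.3, n)
        x[0], y[0] = 4.0, -10.0  # gross outlier at high leverage
        tab = pd.DataFrame({"shift_km": y, "x": x})
        m = es.wls_fit(tab, ("x",), weights=None)
        diag = es.diagnostics(m)
        d = diag["cooks_distance"]
        assert np.argmax(d) == 0
        assert d[0] > diag["cooks_threshold"]
        assert 0 in diag["influential"]

    def test_tiny_sample_skipped_with_warning(self):
        tab = pd.DataFrame({"shift_km": [1.0, 2.0], "weight": [1.0, 1.0]})
        m = es.wls_fit(tab, ())
        with pytest.warns(UserWarning, match="skipped"):
            assert es.diagnostics(m) == {"skipped": True}


class TestPredictProfile:
    def test_prediction_at_mean_matches_all_means_point(self, regression_table):
        m = es.wls_fit(regression_table, ("x1", "x2"))
        prof = es.predict_profile(m, "x1", n_points=201)
        mean_x1 = regression_table["x1"].mean()
        # the profile is linear, so interpolating to the focus variable's
        # mean must reproduce the all-means prediction (the intercept on
        # the standardized scale)
        at_mean = np.interp(mean_x1, prof["x1"], prof["predicted"])
        assert at_mean == pytest.approx(m.params["Intercept"])

    def test_slope_is_coefficient_rescaled_by_sd(self, regression_table):
        m = es.wls_fit(regression_table, ("x1", "x2"))
        prof = es.predict_profile(m, "x1", n_points=50)
        slope = np.polyfit(prof["x1"], prof["predicted"], 1)[0]
        sd = regression_table["x1"].std(ddof=1)
        assert slope == pytest.approx(m.params["x1"] / sd)

    def test_one_curve_per_categorical_combination(self, regression_table):
        m = es.wls_fit(regression_table, ("x1", "f"))
        prof = es.predict_profile(m, "x1", n_points=10)
        assert set(prof["f"]) == {"a", "b", "c"}
        assert len(prof) == 30

    def test_focus_must_be_in_model(self, regression_table):
        m = es.wls_fit(regression_table, ("x1",))
        with pytest.raises(ValueError):
            es.predict_profile(m, "x2")


class TestSelectionPipeline:
    def test_per_size_best_ordering(self, regression_table):
        cands = es.best_subsets(regression_table, ("x1", "x2", "f"))
        bests = per_size_best(cands)
        assert [c.size for c in bests] == [1, 2, 3]
        sel = es.select_final(bests)
        assert set(sel.chosen.predictors) <= {"x1", "x2", "f"}
        assert sel.trace["chosen"].sum() == 1
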