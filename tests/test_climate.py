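"""Climate module: station filtering, plot prediction, trends, variability."""

import numpy as np
import pandas as pd
import pytest

from jspva.climate import (
    PRECIPITATION, TEMPERATURE, filter_stations, fit_weighted_trend,
    predict_plot_climate,
)
from jspva.climate import test_precip_variability as precip_variability


def make_stations(elevs, years, value_fn, variable=TEMPERATURE, sd=1.0,
                  noise=None, rng=None):
    rows = []
    for s, e in enumerate(elevs):
        for y in years:
            v = value_fn(e, y)
            if noise is not None:
                v += rng.normal(0, noise)
            rows.append((f"S{s}", e, y, variable, v,
                         sd if variable == TEMPERATURE else np.nan))
    return pd.DataFrame(rows, columns=["station_id", "elevation_m", "year",
                                       "variable", "value", "value_sd"])


class TestFilterStations:
    def test_rule_on_mixed_elevations(self):
        st = make_stations([900, 1100, 1600], [2002], lambda e, y: 15.0)
        kept = filter_stations(st, [1050, 1200, 1350], 175)
        assert sorted(kept["elevation_m"].unique()) == [900, 1100]

    def test_boundary_is_inclusive(self):
        st = make_stations([1000], [2002], lambda e, y: 15.0)
        kept = filter_stations(st, [1000], 0)
        assert len(kept) == 1
        kept = filter_stations(st, [1175], 175)
        assert len(kept) == 1

    def test_empty_result_raises(self):
        st = make_stations([500], [2002], lambda e, y: 15.0)
        with pytest.raises(ValueError, match="no stations within"):
            filter_stations(st, [1200], 175)


class TestPredictPlotClimate:
    def test_perfect_linear_data_predicts_exactly(self):
        st = make_stations([1000, 1100, 1300], [2002, 2003, 2004],
                           lambda e, y: 20.0 - 0.005 * e)
        plots = pd.DataFrame({"plot_id": ["p"], "region": ["tr"],
                              "elevation_m": [1200.0], "area_ha": [10.0]})
        est = predict_plot_climate(st, plots, TEMPERATURE)
        assert np.allclose(est["mu"], 14.0, atol=1e-8)
        assert np.all(est["sigma"] < 1e-6)

    def test_matches_weighted_least_squares_oracle(self):
        # small synthetic table; oracle = weighted normal equations by hand
        rng = np.random.default_rng(7)
        elevs = [950.0, 1150.0, 1400.0]
        years = [2002, 2003]
        sds = {950.0: 0.8, 1150.0: 1.2, 1400.0: 2.0}
        rows = []
        for e in elevs:
            for y in years:
                rows.append((f"S{e}", e, y, TEMPERATURE,
                             18 - 0.004 * e + 0.3 * (y - 2002) + rng.normal(0, 0.5),
                             sds[e]))
        st = pd.DataFrame(rows, columns=["station_id", "elevation_m", "year",
                                         "variable", "value", "value_sd"])
        plots = pd.DataFrame({"plot_id": ["p"], "region": ["tr"],
                              "elevation_m": [1200.0], "area_ha": [10.0]})
        est = predict_plot_climate(st, plots, TEMPERATURE)

        # oracle: WLS with year dummies + centered elevation, weights 1/sd
        elev = st["elevation_m"].to_numpy()
        X = np.column_stack([(st["year"] == 2002).astype(float),
                             (st["year"] == 2003).astype(float),
                             elev - elev.mean()])
        W = np.diag(1.0 / st["value_sd"].to_numpy())
        yv = st["value"].to_numpy()
        XtWX = X.T @ W @ X
        beta = np.linalg.solve(XtWX, X.T @ W @ yv)
        resid = yv - X @ beta
        s2 = float(resid @ W @ resid) / (len(yv) - 3)
        cov = s2 * np.linalg.inv(XtWX)
        for j, y in enumerate(years):
            x0 = np.zeros(3)
            x0[j] = 1.0
            x0[2] = 1200.0 - elev.mean()
            mu_o = float(x0 @ beta)
            se_o = float(np.sqrt(x0 @ cov @ x0))
            row = est[est["year"] == y].iloc[0]
            assert row["mu"] == pytest.approx(mu_o, abs=1e-10)
            assert row["sigma"] == pytest.approx(se_o, rel=1e-8)

    def test_higher_elevation_is_cooler(self):
        rng = np.random.default_rng(3)
        st = make_stations([1000, 1150, 1300], range(2002, 2012),
                           lambda e, y: 20.0 - 0.006 * e + 0.05 * (y - 2002),
                           noise=0.3, rng=rng)
        plots = pd.DataFrame({"plot_id": ["lo", "hi"], "region": ["tr"] * 2,
                              "elevation_m": [1050.0, 1350.0],
                              "area_ha": [10.0, 10.0]})
        est = predict_plot_climate(st, plots, TEMPERATURE)
        lo = est[est["plot_id"] == "lo"]["mu"].mean()
        hi = est[est["plot_id"] == "hi"]["mu"].mean()
        assert hi < lo

    def test_sigma_shrinks_with_residual_variance(self):
        plots = pd.DataFrame({"plot_id": ["p"], "region": ["tr"],
                              "elevation_m": [1200.0], "area_ha": [10.0]})
        sig = {}
        for noise in (1.0, 0.1):
            rng = np.random.default_rng(11)
            st = make_stations([1000, 1150, 1300], range(2002, 2008),
                               lambda e, y: 20 - 0.005 * e, noise=noise, rng=rng)
            sig[noise] = predict_plot_climate(st, plots, TEMPERATURE)["sigma"].mean()
        assert sig[0.1] < sig[1.0]

    def test_single_elevation_raises(self):
        st = make_stations([1000], [2002, 2003], lambda e, y: 15.0)
        plots = pd.DataFrame({"plot_id": ["p"], "region": ["tr"],
                              "elevation_m": [1000.0], "area_ha": [1.0]})
        with pytest.raises(ValueError, match="singular|2 distinct"):
            predict_plot_climate(st, plots, TEMPERATURE)

    def test_missing_year_warns_and_omits(self):
        st = make_stations([1000, 1300], [2002, 2004], lambda e, y: 15.0)
        plots = pd.DataFrame({"plot_id": ["p"], "region": ["tr"],
                              "elevation_m": [1100.0], "area_ha": [1.0],
                              "first_year": [2002], "last_year": [2004]})
        with pytest.warns(UserWarning, match="2003"):
            est = predict_plot_climate(st, plots, TEMPERATURE)
        assert sorted(est["year"]) == [2002, 2004]


class TestWeightedTrend:
    def test_noiseless_recovery_is_exact(self):
        st = make_stations([1000, 1200, 1400], range(2002, 2012),
                           lambda e, y: 2.0 + 0.07 * (y - 2000) - 0.005 * e)
        tr = fit_weighted_trend(st, TEMPERATURE)
        assert tr.slope == pytest.approx(0.07, abs=1e-10)
        assert tr.ci95[1] - tr.ci95[0] < 1e-8

    def test_constant_weights_match_unweighted(self):
        rng = np.random.default_rng(5)
        st = make_stations([1000, 1200, 1400], range(2002, 2012),
                           lambda e, y: 16 + 0.06 * (y - 2002) - 0.005 * e,
                           sd=1.7, noise=0.4, rng=rng)
        t1 = fit_weighted_trend(st, TEMPERATURE, weights="inverse_sd")
        t2 = fit_weighted_trend(st, TEMPERATURE, weights="none")
        assert t1.slope == pytest.approx(t2.slope, abs=1e-12)

    def test_matches_wls_normal_equations_oracle(self):
        rng = np.random.default_rng(9)
        rows = []
        for e in (1000.0, 1200.0, 1400.0):
            for y in range(2002, 2010):
                rows.append((f"S{e}", e, y, TEMPERATURE,
                             16 + 0.05 * (y - 2002) - 0.004 * e + rng.normal(0, 0.5),
                             rng.uniform(0.5, 2.5)))
        st = pd.DataFrame(rows, columns=["station_id", "elevation_m", "year",
                                         "variable", "value", "value_sd"])
        tr = fit_weighted_trend(st, TEMPERATURE)
        year = st["year"].to_numpy(dtype=float)
        elev = st["elevation_m"].to_numpy()
        X = np.column_stack([np.ones(len(st)),
                             year - (year.min() + year.max()) / 2,
                             elev - elev.mean()])
        W = np.diag(1.0 / st["value_sd"].to_numpy())
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ st["value"].to_numpy())
        assert tr.slope == pytest.approx(beta[1], abs=1e-10)

    def test_recovers_true_slope_within_2se(self):
        n_rep = 500  # coverage of a 2*SE band is ~95%; require >= 93%
        hits = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(100 + rep)
            st = make_stations([1000, 1200, 1400], range(2002, 2017),
                               lambda e, y: 16 + 0.07 * (y - 2002) - 0.005 * e,
                               noise=0.9, rng=rng)
            tr = fit_weighted_trend(st, TEMPERATURE)
            if abs(tr.slope - 0.07) <= 2 * tr.slope_se:
                hits += 1
        assert hits >= 0.93 * n_rep

    def test_interaction_period_reports_ci(self):
        rng = np.random.default_rng(21)
        st = make_stations([1000, 1300], range(2002, 2020),
                           lambda e, y: 16 + (0.02 if y < 2012 else 0.10) * (y - 2002)
                           - 0.005 * e, noise=0.3, rng=rng)
        tr = fit_weighted_trend(st, TEMPERATURE, interaction_period=2012)
        assert tr.interaction is not None
        lo, hi = tr.interaction_ci95
        assert lo < tr.interaction < hi

    def test_missing_sd_raises_for_weighted_fit(self):
        st = make_stations([1000, 1300], range(2002, 2010),
                           lambda e, y: 2000.0, variable=PRECIPITATION)
        with pytest.raises(ValueError, match="value_sd"):
            fit_weighted_trend(st, PRECIPITATION, weights="inverse_sd")


class TestPrecipVariability:
    @staticmethod
    def _simulate(rng, n_years=34, elevs=(950.0, 1100.0, 1250.0, 1400.0,
                                          1550.0, 1700.0), sd_growth=0.0):
        rows = []
        years = range(2002, 2002 + n_years)
        for y in years:
            frac = (y - 2002) / (n_years - 1)
            sd = 200.0 * (1.0 + sd_growth * frac)
            for s, e in enumerate(elevs):
                rows.append((f"S{s}", e, y, PRECIPITATION,
                             2000 + 0.5 * e + rng.normal(0, sd), np.nan))
        return pd.DataFrame(rows, columns=["station_id", "elevation_m", "year",
                                           "variable", "value", "value_sd"])

    def test_holds_size_under_homoscedastic_null(self):
        # |t| < 2 in >= 90% of replicates at n=204 station-years; the
        # absolute-residual regression has mildly inflated size (~0.07)
        n_rep = 500
        rejections = 0
        for rep in range(n_rep):
            rng = np.random.default_rng(500 + rep)
            res = precip_variability(self._simulate(rng))
            if abs(res.t_stat) >= 2:
                rejections += 1
        assert rejections <= 0.10 * n_rep

    def test_detects_sd_doubling(self):
        power = 0
        for rep in range(20):
            rng = np.random.default_rng(900 + rep)
            res = precip_variability(self._simulate(rng, sd_growth=1.0))
            if res.slope > 0 and res.p_value < 0.05:
                power += 1
        assert power >= 15

    def test_invariant_to_constant_shift(self):
        rng = np.random.default_rng(77)
        st = self._simulate(rng)
        res1 = precip_variability(st)
        st2 = st.copy()
        st2["value"] += 500.0
        res2 = precip_variability(st2)
        assert res1.slope == pytest.approx(res2.slope, abs=1e-9)
        assert res1.t_stat == pytest.approx(res2.t_stat, abs=1e-6)

    def test_constant_residuals_raise(self):
        st = make_stations([1000, 1300], range(2002, 2010),
                           lambda e, y: 2000 + 0.5 * e, variable=PRECIPITATION)
        with pytest.raises(ValueError, match="degenerate|constant"):
            precip_variability(st)
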