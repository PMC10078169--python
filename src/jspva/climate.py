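"""Plot-level climate covariates from station data, and long-term trends.

Climate stations sit along the elevation gradient near (but not on) the
study plots, so plot-level covariates are obtained from a linear model with
a shared elevation slope and a separate intercept for each year, predicting
the mean and its standard error at each plot's elevation.  Early-breeding
temperature is itself a mean of daily values, so every temperature
regression is weighted by the reciprocal of the per-station SD of those
daily values.

Station tables are plain data frames with columns
``station_id, elevation_m, year, variable, value, value_sd`` where
``variable`` is ``early_breeding_temperature`` (°C) or
``annual_precipitation`` (mm; no value_sd).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

TEMPERATURE = "early_breeding_temperature"
PRECIPITATION = "annual_precipitation"
STATION_COLUMNS = ["station_id", "elevation_m", "year", "variable", "value", "value_sd"]


@dataclass(frozen=True)
class ClimateTrend:
    """Fitted long-term trend of a climate variable.

    slope / slope_se are in variable units per year and feed the future
    climate random walk used in forecasting.  When a changepoint interaction
    was requested, ``interaction`` is the difference in slope (after minus
    before) and ``interaction_ci95`` its 95% confidence interval.
    """

    variable: str
    region: str
    slope: float
    slope_se: float
    ci95: tuple[float, float]
    n: int
    interaction: float | None = None
    interaction_ci95: tuple[float, float] | None = None


@dataclass(frozen=True)
class PrecipVariabilityTest:
    """Result of the two-stage precipitation-variability regression."""

    slope: float
    t_stat: float
    p_value: float
    n: int


def _check_stations(stations: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in STATION_COLUMNS if c not in stations.columns and c != "value_sd"]
    if missing:
        raise ValueError(f"station table missing columns: {missing}")
    if "value_sd" not in stations.columns:
        stations = stations.assign(value_sd=np.nan)
    return stations


def filter_stations(stations: pd.DataFrame, plot_elevations, tolerance: float = 175.0
                    ) -> pd.DataFrame:
    """Keep stations within ``tolerance`` meters of any plot elevation.

    The comparison is inclusive: a station exactly ``tolerance`` meters from
    the nearest plot is retained.
    """
    if tolerance < 0:
        raise ValueError("tolerance must be non-negative")
    stations = _check_stations(stations)
    plot_elev = np.asarray(list(plot_elevations), dtype=float)
    if plot_elev.size == 0:
        raise ValueError("no plot elevations given")
    dist = np.abs(stations["elevation_m"].to_numpy(dtype=float)[:, None] - plot_elev[None, :])
    keep = dist.min(axis=1) <= tolerance
    out = stations.loc[keep].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"no stations within {tolerance} m of the plot elevations")
    return out


def _design_year_intercepts(df: pd.DataFrame) -> tuple[np.ndarray, list, np.ndarray]:
    """Design matrix: one intercept per year plus a centered elevation trend."""
    years = np.sort(df["year"].unique())
    elev_c = df["elevation_m"].to_numpy(dtype=float)
    elev_mean = elev_c.mean()
    X = np.zeros((len(df), len(years) + 1))
    for j, y in enumerate(years):
        X[df["year"].to_numpy() == y, j] = 1.0
    X[:, -1] = elev_c - elev_mean
    return X, list(years), np.array([elev_mean])


def predict_plot_climate(stations: pd.DataFrame, plots: pd.DataFrame,
                         variable: str) -> pd.DataFrame:
    """Predict the plot-level covariate mean and its SE for every plot-year.

    Fits ``value ~ C(year) + elevation`` (elevation slope shared across
    years) on the station records of ``variable``; temperature fits are
    weighted by 1/value_sd.  Returns a frame with columns
    ``plot_id, year, variable, mu, sigma`` where sigma is the standard error
    of the fitted mean at the plot elevation (the covariate enters the
    demographic model as an uncertain mean, not as a new observation).

    Years with no station data are absent from the result (with a warning).
    """
    stations = _check_stations(stations)
    df = stations[stations["variable"] == variable].copy()
    if df.empty:
        raise ValueError(f"no station records for variable {variable!r}")
    if df["elevation_m"].nunique() < 2:
        raise ValueError("need stations at >= 2 distinct elevations to fit the "
                         "elevation trend (singular design)")
    X, years, elev_mean = _design_year_intercepts(df)
    yvals = df["value"].to_numpy(dtype=float)
    if variable == TEMPERATURE:
        sd = df["value_sd"].to_numpy(dtype=float)
        if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
            raise ValueError("temperature records need positive value_sd for weighting")
        fit = sm.WLS(yvals, X, weights=1.0 / sd).fit()
    else:
        fit = sm.OLS(yvals, X).fit()

    requested_years = None
    if {"first_year", "last_year"}.issubset(plots.columns):
        requested_years = {
            p.plot_id: range(int(p.first_year), int(p.last_year) + 1)
            for p in plots.itertuples(index=False)
        }
    rows = []
    for p in plots.itertuples(index=False):
        elev = float(p.elevation_m) - elev_mean[0]
        plot_years = requested_years[p.plot_id] if requested_years else years
        for y in plot_years:
            if y not in years:
                warnings.warn(f"no {variable} station data for year {y}; "
                              f"plot {p.plot_id} year omitted", stacklevel=2)
                continue
            x = np.zeros(len(years) + 1)
            x[years.index(y)] = 1.0
            x[-1] = elev
            pred = fit.get_prediction(x[None, :])
            rows.append((p.plot_id, int(y), variable,
                         float(pred.predicted_mean[0]), float(pred.se_mean[0])))
    return pd.DataFrame(rows, columns=["plot_id", "year", "variable", "mu", "sigma"])


def fit_weighted_trend(stations: pd.DataFrame, variable: str,
                       weights: str = "inverse_sd",
                       interaction_period: int | None = None,
                       region: str = "unspecified") -> ClimateTrend:
    """Linear time trend of a climate variable, accounting for elevation.

    Fits ``value ~ year + elevation`` (both centered) with observation
    weights 1/value_sd when ``weights="inverse_sd"``.  With
    ``interaction_period`` the model adds a year x period interaction
    (period = before/after the changepoint year) and reports the interaction
    estimate with its 95% CI alongside the base-period slope.
    """
    if weights not in ("inverse_sd", "none"):
        raise ValueError("weights must be 'inverse_sd' or 'none'")
    stations = _check_stations(stations)
    df = stations[stations["variable"] == variable]
    if df.empty:
        raise ValueError(f"no station records for variable {variable!r}")
    if df["year"].nunique() < 3:
        raise ValueError("need >= 3 years of data to fit a trend")
    year = df["year"].to_numpy(dtype=float)
    year_c = year - (year.min() + year.max()) / 2.0
    elev_c = df["elevation_m"].to_numpy(dtype=float)
    elev_c = elev_c - elev_c.mean()
    cols = [np.ones_like(year_c), year_c, elev_c]
    names = ["intercept", "year", "elevation"]
    if interaction_period is not None:
        period = (year >= interaction_period).astype(float)
        cols += [period, year_c * period]
        names += ["period", "year:period"]
    X = np.column_stack(cols)
    yvals = df["value"].to_numpy(dtype=float)
    if weights == "inverse_sd":
        sd = df["value_sd"].to_numpy(dtype=float)
        if np.any(~np.isfinite(sd)) or np.any(sd <= 0):
            raise ValueError("weights='inverse_sd' requires positive value_sd on "
                             "every record")
        fit = sm.WLS(yvals, X, weights=1.0 / sd).fit()
    else:
        fit = sm.OLS(yvals, X).fit()
    ci = fit.conf_int(alpha=0.05)
    j = names.index("year")
    interaction = interaction_ci = None
    if interaction_period is not None:
        ji = names.index("year:period")
        interaction = float(fit.params[ji])
        interaction_ci = (float(ci[ji, 0]), float(ci[ji, 1]))
    return ClimateTrend(
        variable=variable, region=region,
        slope=float(fit.params[j]), slope_se=float(fit.bse[j]),
        ci95=(float(ci[j, 0]), float(ci[j, 1])), n=len(df),
        interaction=interaction, interaction_ci95=interaction_ci,
    )


def test_precip_variability(stations: pd.DataFrame) -> PrecipVariabilityTest:
    """Has annual precipitation become more variable over time?

    Stage 1 fits precipitation with a separate intercept per year and an
    elevation trend; stage 2 regresses the absolute residuals on year and
    elevation.  A positive, significant stage-2 year slope indicates
    increasing interannual variability.  Two-sided t-test with residual
    degrees of freedom.
    """
    stations = _check_stations(stations)
    df = stations[stations["variable"] == PRECIPITATION]
    if df["year"].nunique() < 4:
        raise ValueError("need >= 4 years of precipitation data")
    X1, _, _ = _design_year_intercepts(df)
    yvals = df["value"].to_numpy(dtype=float)
    stage1 = sm.OLS(yvals, X1).fit()
    abs_resid = np.abs(stage1.resid)
    if np.allclose(abs_resid, abs_resid[0]):
        raise ValueError("residuals are (numerically) constant; variability test "
                         "is degenerate")
    year = df["year"].to_numpy(dtype=float)
    year_c = year - (year.min() + year.max()) / 2.0
    elev_c = df["elevation_m"].to_numpy(dtype=float)
    elev_c = elev_c - elev_c.mean()
    X2 = np.column_stack([np.ones_like(year_c), year_c, elev_c])
    stage2 = sm.OLS(abs_resid, X2).fit()
    return PrecipVariabilityTest(slope=float(stage2.params[1]),
                                 t_stat=float(stage2.tvalues[1]),
                                 p_value=float(stage2.pvalues[1]),
                                 n=len(df))
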