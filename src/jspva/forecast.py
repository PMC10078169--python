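"""Population-viability forecasting from posterior draws.

For each posterior draw the population is projected forward from the last
data year: survivors are binomial thins of the SY/ASY cohorts with the
draw's survival rates, and new recruits enter from an additional augmented
pool of M_future pseudo-individuals, each joining a future year with
probability (n1+n2)_{prev} * gamma_{prev} / M_future (the expected SY
abundance over the future bound).  Climate-variant forecasts drive the
rates with a per-draw random-walk covariate path built from the fitted
long-term climate trend; the time variant extends the year index.
Extinction risk is the percentage of trajectories at zero abundance in the
horizon year.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .climate import ClimateTrend
from .infer import JollySeberResults, PosteriorSamples
from .datasets import (
    I_ALPHA, I_B0G, I_B0P_ASY, I_B0P_SY, I_B1G, I_B1G_POST, I_B1P,
    I_B1P_POST, I_B2G, N_SCALAR_PARAMS,
)


@dataclass
class ForecastResult:
    """Posterior forecast trajectories and the extinction indicator.

    trajectories has shape (draws, n_years) and covers the last data year
    through the horizon; ``w_paths`` holds the covariate paths on the model's
    standardized scale.
    """

    years: np.ndarray
    trajectories: np.ndarray
    w_paths: np.ndarray
    m_future: int
    area_ha: float

    @property
    def extinct(self) -> np.ndarray:
        return self.trajectories[:, -1] == 0

    def summary(self) -> pd.DataFrame:
        dens = self.trajectories / self.area_ha
        lo, med, hi = np.percentile(dens, [2.5, 50.0, 97.5], axis=0)
        return pd.DataFrame({"year": self.years, "median_density": med,
                             "cri_2.5": lo, "cri_97.5": hi}).set_index("year")


def extinction_risk(result: ForecastResult) -> float:
    """Percentage of forecast trajectories at zero abundance in the horizon year."""
    if result.trajectories.shape[0] == 0:
        raise ValueError("empty forecast")
    return 100.0 * float(result.extinct.mean())


def simulate_future_climate(trend: ClimateTrend | tuple, w_last, horizon: int,
                            rng=None, n_paths: int | None = None) -> np.ndarray:
    """Random-walk future covariate: w_{t+1} ~ Normal(w_t + slope, slope_se).

    ``trend`` may be a ClimateTrend or a plain (slope, slope_se) pair in the
    units of ``w_last``.  Returns an array of shape (n_paths, horizon) (or
    (horizon,) if ``w_last`` is scalar and n_paths is None).
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    if isinstance(trend, ClimateTrend):
        slope, se = trend.slope, trend.slope_se
    else:
        slope, se = trend
    if rng is None:
        rng = np.random.default_rng(0)
    w_last = np.asarray(w_last, dtype=float)
    scalar = w_last.ndim == 0 and n_paths is None
    n = 1 if scalar else (n_paths if w_last.ndim == 0 else w_last.shape[0])
    w = np.broadcast_to(w_last, (n,)).astype(float).copy()
    out = np.empty((n, horizon))
    for h in range(horizon):
        w = w + slope + (se * rng.standard_normal(n) if se > 0 else 0.0)
        out[:, h] = w
    return out[0] if scalar else out


def forecast_population(results: JollySeberResults, horizon_year: int,
                        climate_trend: ClimateTrend | tuple | None = None,
                        m_future: int = 2400, seed: int = 0) -> ForecastResult:
    """Forecast abundance from the last data year through ``horizon_year``.

    One stochastic trajectory (and, for climate variants, one future
    covariate path) per posterior draw, propagating parameter uncertainty,
    demographic stochasticity and future climate uncertainty.  Density
    dependence acts on the realized forecast density each year, with the
    same convention as fitting.
    """
    model = results.model
    samples: PosteriorSamples = results.samples
    years = samples.years
    last = int(years[-1])
    if horizon_year < last:
        raise ValueError("horizon before the last data year")
    variant = model.trend.variant
    if variant != "time" and climate_trend is None:
        raise ValueError("climate variants need a fitted ClimateTrend for the "
                         "future covariate random walk")

    T = len(years)
    theta = samples.theta.reshape(-1, samples.theta.shape[-1])
    nD = theta.shape[0]
    n1 = samples.n1.reshape(nD, T)[:, -1].astype(np.int64).copy()
    n2 = samples.n2.reshape(nD, T)[:, -1].astype(np.int64).copy()

    H = horizon_year - last
    rng = np.random.Generator(np.random.Philox(key=seed))
    area = model.data.area_ha
    dp = model.density_power

    # covariate paths on the standardized model scale
    if variant == "time":
        ts = model.ts
        step = ts[1] - ts[0] if T > 1 else 1.0
        future = ts[-1] + step * np.arange(1, H + 1)
        w_paths = np.broadcast_to(future, (nD, H)).copy() if H else np.zeros((nD, 0))
        w_now = np.full(nD, ts[-1])
    else:
        if isinstance(climate_trend, ClimateTrend):
            slope, se = climate_trend.slope, climate_trend.slope_se
        else:
            slope, se = climate_trend
        slope_std = slope / model.covariate_scale
        se_std = se / model.covariate_scale
        w_now = theta[:, N_SCALAR_PARAMS + T - 1].copy()
        w_paths = (simulate_future_climate((slope_std, se_std), w_now, H, rng=rng)
                   if H else np.zeros((nD, 0)))

    # trend coefficients: beyond the changepoint every future year is "post"
    use_post = model.trend.changepoint is not None
    b1g = theta[:, I_B1G_POST] if use_post else theta[:, I_B1G]
    b1p = theta[:, I_B1P_POST] if use_post else theta[:, I_B1P]
    alpha = theta[:, I_ALPHA]
    b0g = theta[:, I_B0G]
    b2g = theta[:, I_B2G]
    b0sy = theta[:, I_B0P_SY]
    b0asy = theta[:, I_B0P_ASY]

    traj = np.empty((nD, H + 1), dtype=np.int64)
    traj[:, 0] = n1 + n2
    entered = np.zeros(nD, dtype=np.int64)
    w_cur = w_now
    for h in range(H):
        ed = (n1 + n2) / area
        edp = ed ** dp
        gam = alpha / (1.0 + np.exp(-(b0g + b1g * w_cur - b2g * edp)))
        phi_sy = 1.0 / (1.0 + np.exp(-(b0sy + b1p * w_cur)))
        phi_asy = 1.0 / (1.0 + np.exp(-(b0asy + b1p * w_cur)))
        q = np.clip((n1 + n2) * gam / m_future, 0.0, 1.0)
        at_risk = m_future - entered
        recruits = rng.binomial(at_risk, q)
        if np.any(entered + recruits >= m_future):
            raise RuntimeError("future augmentation bound exhausted; "
                               "increase m_future")
        entered += recruits
        survivors = rng.binomial(n1, phi_sy) + rng.binomial(n2, phi_asy)
        n1 = recruits.astype(np.int64)
        n2 = survivors.astype(np.int64)
        traj[:, h + 1] = n1 + n2
        w_cur = w_paths[:, h]

    return ForecastResult(years=np.arange(last, horizon_year + 1),
                          trajectories=traj, w_paths=w_paths,
                          m_future=m_future, area_ha=area)
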