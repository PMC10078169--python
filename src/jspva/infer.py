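"""Posterior sampling, convergence assessment and posterior summaries."""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd

from . import _engine
from .datasets import (
    AGE_ASY, AugmentedState, ModelParams, N_SCALAR_PARAMS,
    PARAM_NAMES, I_ALPHA, I_B0C, I_B0G, I_B0P_ASY, I_B0P_SY, I_B1C, I_B1G,
    I_B1G_POST, I_B1P, I_B1P_POST, I_B2G, I_K, I_PETA, I_PI1, I_PR, I_TAU,
)

_EN = _engine


@dataclass
class PosteriorSamples:
    """Posterior draws for one fitted plot/variant.

    theta has shape (chains, draws, n_params) in the fixed parameter layout
    (scalars first, then the latent covariate values); n1/n2/N hold the
    realized SY/ASY/total abundances of the augmented state at each draw.
    """

    theta: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    N: np.ndarray
    param_names: list
    sampled_names: list
    years: np.ndarray
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.theta.shape[0]

    @property
    def n_draws(self) -> int:
        return self.theta.shape[1]

    def flat(self, name: str) -> np.ndarray:
        """All draws of one named parameter, chains concatenated."""
        j = self.param_names.index(name)
        return self.theta[:, :, j].reshape(-1)

    def to_inference_data(self) -> az.InferenceData:
        post = {}
        for name in self.sampled_names:
            j = self.param_names.index(name)
            post[name] = self.theta[:, :, j]
        post["N"] = self.N
        post["n1"] = self.n1
        post["n2"] = self.n2
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            idata = az.from_dict(
                posterior=post,
                coords={"year": self.years},
                dims={"N": ["year"], "n1": ["year"], "n2": ["year"]},
            )
        idata.posterior.attrs.update(
            {k: str(v) for k, v in self.meta.items()})
        return idata

    def to_netcdf(self, path) -> None:
        self.to_inference_data().to_netcdf(str(path))


def _initial_state(data):
    """Latent trajectories consistent with the detections.

    Marked females: entry at capture (one year earlier for ASY-aged
    captures after the first year), death after the last detection.
    Enough augmented females are placed as one-year residents to cover the
    unmarked counts.
    """
    T, M = data.T, data.M
    b = np.full(M, T, dtype=np.int64)
    a1 = np.zeros(M, dtype=np.int64)
    d = np.full(M, -1, dtype=np.int64)
    fc = data.first_capture
    last = data.last_detection
    for i in range(data.n_obs):
        age = int(data.age_at_capture[i])
        if age == AGE_ASY:
            if fc[i] == 0:
                b[i] = 0
                a1[i] = 1
            else:
                b[i] = fc[i] - 1
        else:
            b[i] = fc[i]
            a1[i] = 0
        d[i] = last[i]
    # cover the unmarked counts with one-year augmented residents
    U = np.zeros(T, dtype=int)
    for i in range(data.n_obs):
        for t in range(b[i], d[i] + 1):
            if t < fc[i]:
                U[t] += 1
    nxt = data.n_obs
    for t in range(T):
        deficit = int(data.unmarked_count[t]) - int(U[t])
        while deficit > 0 and nxt < M:
            b[nxt] = t
            d[nxt] = t
            nxt += 1
            deficit -= 1
    return b, a1, d


def _default_init_params(model, rng) -> np.ndarray:
    T = model.data.T
    theta = np.zeros(N_SCALAR_PARAMS + T)
    theta[I_ALPHA] = 1.0 * np.exp(0.3 * rng.standard_normal())
    theta[I_B2G] = 0.01
    for j in (I_B0G, I_B1G, I_B1G_POST, I_B1P, I_B1P_POST, I_B1C):
        theta[j] = 0.3 * rng.standard_normal()
    theta[I_B0P_SY] = -0.3 + 0.3 * rng.standard_normal()
    theta[I_B0P_ASY] = 0.3 + 0.3 * rng.standard_normal()
    theta[I_B0C] = 1.0 + 0.3 * rng.standard_normal()
    theta[I_K] = 0.7
    theta[I_TAU] = 0.5
    n1_0 = int(model.data.unmarked_count[0]) + int(np.sum(model.data.first_capture == 0)) + 1
    theta[I_PI1] = min(max(n1_0 / model.data.M, 2.0 / model.data.M), 0.9)
    theta[I_PETA] = 0.8
    theta[I_PR] = model.priors.pr_mean
    if model.trend.variant != "time":
        theta[N_SCALAR_PARAMS:] = model.mu_std
    return theta


def _state_from_arrays(b, a1, d, T, M) -> AugmentedState:
    z = np.zeros((M, T), dtype=np.int8)
    for i in range(M):
        if b[i] < T:
            z[i, b[i]:d[i] + 1] = 1
    return AugmentedState(b=b.copy(), a1=a1.copy(), z=z)


def run_mcmc(model, draws: int = 2000, adapt: int = 500, chains: int = 3,
             seed: int = 0, sample_params: bool = True,
             init_params: ModelParams | None = None) -> "JollySeberResults":
    """Sample the joint posterior of the model with the compiled kernel.

    Deterministic given (seed, settings).  Initial latent states are read
    off the detections; if the resulting joint density is not finite the
    initialization is retried (up to 100 times) with additional full-span
    augmented females and jittered parameters before giving up.
    """
    if draws < 1 or adapt < 0 or chains < 1:
        raise ValueError("draws/adapt/chains must be positive")
    data = model.data
    T, M = data.T, data.M
    variant = 0 if model.trend.variant == "time" else 1
    cp = np.zeros(T, dtype=np.int8)
    if model.cp_mask is not None:
        cp[model.cp_mask] = 1
    ts = model.ts.astype(float)
    mu = model.mu_std if variant else np.zeros(T)
    sig = model.sigma_std if variant else np.ones(T)
    sample_pr = bool(data.single_day.any())
    pr_a, pr_b = model.priors.pr_beta_shapes()

    fc = data.first_capture.astype(np.int64)
    aged = data.age_at_capture.astype(np.int64)
    ydat = data.resight.astype(np.int64).reshape(data.n_obs, T)
    lastdet = data.last_detection.astype(np.int64)
    u = data.unmarked_count.astype(np.int64)
    sdflag = data.single_day.astype(np.int8)

    # Metropolis update table: (param index, transform, prior, block)
    rows = [
        (I_ALPHA, _EN.T_LOG, _EN.P_EXPON, _EN.B_ENTRY),
        (I_B0G, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_ENTRY),
        (I_B1G, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_ENTRY),
        (I_B2G, _EN.T_LOG, _EN.P_HALFNORMAL, _EN.B_ENTRY),
        (I_B0P_SY, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_SURV),
        (I_B0P_ASY, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_SURV),
        (I_B1P, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_SURV),
        (I_B0C, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_CAP),
        (I_B1C, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_CAP),
        (I_PI1, _EN.T_LOGIT, _EN.P_UNIFORM, _EN.B_ENTRY),
        (I_PETA, _EN.T_LOGIT, _EN.P_UNIFORM, _EN.B_RES),
    ]
    if model.trend.changepoint is not None:
        rows.insert(3, (I_B1G_POST, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_ENTRY))
        rows.append((I_B1P_POST, _EN.T_IDENT, _EN.P_NORMAL, _EN.B_SURV))
    if sample_pr:
        rows.append((I_PR, _EN.T_LOGIT, _EN.P_BETA, _EN.B_RES))
    mh_idx = np.array([r[0] for r in rows], dtype=np.int64)
    mh_tcode = np.array([r[1] for r in rows], dtype=np.int64)
    mh_pcode = np.array([r[2] for r in rows], dtype=np.int64)
    mh_bcode = np.array([r[3] for r in rows], dtype=np.int64)

    rng = np.random.Generator(np.random.Philox(seed))
    b0_init, a1_init, d_init = _initial_state(data)
    if init_params is not None:
        theta0 = init_params.to_vector()
        if theta0.shape[0] == N_SCALAR_PARAMS:
            theta0 = np.concatenate([theta0, mu if variant else np.zeros(T)])
    else:
        theta0 = _default_init_params(model, rng)
        # retry until the reference joint density is finite
        ok = False
        for attempt in range(100):
            state = _state_from_arrays(b0_init, a1_init, d_init, T, M)
            params = ModelParams.from_vector(theta0)
            if np.isfinite(model.joint_log_density(params, state)):
                ok = True
                break
            # add full-span augmented females and jitter the parameters
            free = np.flatnonzero(b0_init >= T)
            extra = free[:max(1, len(free) // 20)]
            b0_init[extra] = 0
            d_init[extra] = T - 1
            theta0 = _default_init_params(model, rng)
        if not ok:
            n1c, n2c, Nc = state.abundance()
            raise RuntimeError(
                "could not find a finite-density initial state after 100 "
                f"attempts; N={Nc.tolist()}, u={data.unmarked_count.tolist()}, "
                f"theta={np.round(theta0, 3).tolist()}")

    n_par = N_SCALAR_PARAMS + T
    theta_out = np.empty((chains, draws, n_par))
    n1_out = np.empty((chains, draws, T), dtype=np.int64)
    n2_out = np.empty((chains, draws, T), dtype=np.int64)
    N_out = np.empty((chains, draws, T), dtype=np.int64)
    for c in range(chains):
        chain_seed = int((seed * 1000003 + 7919 * c + 1) % (2 ** 31 - 1))
        to = np.empty((draws, n_par))
        o1 = np.empty((draws, T), dtype=np.int64)
        o2 = np.empty((draws, T), dtype=np.int64)
        oN = np.empty((draws, T), dtype=np.int64)
        _EN.run_chain(chain_seed, adapt, draws,
                      T, M, float(data.area_ha), int(model.density_power),
                      data.n_obs, fc, aged, ydat, lastdet, u, sdflag,
                      variant, cp, ts, np.asarray(mu, float), np.asarray(sig, float),
                      model.priors.sd_beta, model.priors.alpha_rate,
                      pr_a, pr_b, model.priors.sd_w,
                      1 if sample_params else 0, 1 if sample_pr else 0,
                      mh_idx, mh_tcode, mh_pcode, mh_bcode,
                      theta0.copy(), b0_init.copy(), a1_init.copy(), d_init.copy(),
                      to, o1, o2, oN)
        theta_out[c] = to
        n1_out[c], n2_out[c], N_out[c] = o1, o2, oN

    w_names = [f"w_{y}" for y in data.years]
    sampled = [PARAM_NAMES[i] for i in mh_idx] + ["k", "tau"]
    if variant:
        sampled += w_names
    meta = {
        "seed": seed, "chains": chains, "draws": draws, "adapt": adapt,
        "variant": model.trend.variant, "changepoint": model.trend.changepoint,
        "M": M, "area_ha": data.area_ha, "plot_id": data.plot_id,
        "data_hash": hashlib.sha256(
            data.capture.tobytes() + data.resight.tobytes()
            + data.unmarked_count.tobytes()).hexdigest()[:16],
    }
    samples = PosteriorSamples(
        theta=theta_out, n1=n1_out, n2=n2_out, N=N_out,
        param_names=PARAM_NAMES + w_names, sampled_names=sampled,
        years=data.years.copy(), meta=meta)
    return JollySeberResults(model, samples)


def assess_convergence(samples: PosteriorSamples,
                       rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Split R-hat and effective sample size for every reported quantity.

    Covers each sampled scalar parameter and each yearly abundance N_t.
    Quantities with (numerically) constant draws are marked ``degenerate``
    and flagged rather than producing NaN failures downstream.
    """
    if samples.n_chains < 2:
        raise ValueError("convergence assessment needs at least two chains")
    idata = samples.to_inference_data()
    rows = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name in list(samples.sampled_names) + [f"N_{y}" for y in samples.years]:
            if name.startswith("N_"):
                year = int(name[2:])
                j = int(np.flatnonzero(samples.years == year)[0])
                draws = samples.N[:, :, j].astype(float)
            else:
                j = samples.param_names.index(name)
                draws = samples.theta[:, :, j]
            degenerate = bool(np.ptp(draws) == 0)
            if degenerate:
                rhat = np.nan
                ess = np.nan
            else:
                da = az.convert_to_dataset({"x": draws})
                rhat = float(az.rhat(da)["x"].values)
                ess = float(az.ess(da)["x"].values)
            rows.append((name, rhat, ess, degenerate,
                         degenerate or not np.isfinite(rhat) or rhat > rhat_threshold))
    return pd.DataFrame(rows, columns=["parameter", "rhat", "ess_bulk",
                                       "degenerate", "flagged"]).set_index("parameter")


def summarize_posterior(samples: PosteriorSamples, area_ha: float | None = None
                        ) -> pd.DataFrame:
    """Median and equal-tailed 95% CrI for parameters and yearly density."""
    if samples.n_draws == 0:
        raise ValueError("no posterior draws to summarize")
    if area_ha is None:
        area_ha = float(samples.meta.get("area_ha", 1.0))
    rows = []
    for name in samples.sampled_names:
        j = samples.param_names.index(name)
        x = samples.theta[:, :, j].reshape(-1)
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        rows.append((name, med, lo, hi))
    for j, y in enumerate(samples.years):
        x = samples.N[:, :, j].reshape(-1).astype(float)
        lo, med, hi = np.percentile(x, [2.5, 50.0, 97.5])
        rows.append((f"N_{y}", med, lo, hi))
        xd = x / area_ha
        lo, med, hi = np.percentile(xd, [2.5, 50.0, 97.5])
        rows.append((f"density_{y}", med, lo, hi))
    return pd.DataFrame(rows, columns=["parameter", "median", "cri_2.5",
                                       "cri_97.5"]).set_index("parameter")


class JollySeberResults:
    """Posterior results of a fitted :class:`jspva.model.JollySeberModel`.

    Carries the draws, exposes summaries and diagnostics, and is the entry
    point for population-viability forecasting.
    """

    def __init__(self, model, samples: PosteriorSamples):
        self.model = model
        self.samples = samples

    def summary(self) -> pd.DataFrame:
        return summarize_posterior(self.samples, self.model.data.area_ha)

    def convergence(self, rhat_threshold: float = 1.1) -> pd.DataFrame:
        return assess_convergence(self.samples, rhat_threshold)

    def rhat(self) -> pd.Series:
        return self.convergence()["rhat"]

    def ess(self) -> pd.Series:
        return self.convergence()["ess_bulk"]

    def median_abundance(self) -> np.ndarray:
        return np.median(self.samples.N.reshape(-1, self.samples.N.shape[-1]), axis=0)

    def forecast(self, horizon_year: int, climate_trend=None,
                 m_future: int = 2400, seed: int = 0):
        from .forecast import forecast_population
        return forecast_population(self, horizon_year=horizon_year,
                                   climate_trend=climate_trend,
                                   m_future=m_future, seed=seed)

    def save(self, path) -> None:
        """Persist draws with metadata (seed, settings, data hash) as NetCDF."""
        self.samples.to_netcdf(path)
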