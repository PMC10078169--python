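"""Synthetic data with the statistical structure the analysis assumes.

The generator emulates a long-term demographic study of breeding female
songbirds on elevation-graded forest plots: climate stations along the
elevation gradient with a linear warming trend, a local population whose
recruitment and apparent survival follow logit-linear trends with negative
density dependence, and an observation layer of single captures with
probabilistic ageing, resightings, degraded single-day surveys, and yearly
binomial counts of unmarked females.

Default settings describe a declining trailing-edge-like plot: T=15 years,
an 18-ha plot holding roughly 12-20 females, an augmented superpopulation
of M=150 (comfortably above the expected ~100 cumulative entries), warming
of 0.07 deg C/yr along a -0.006 deg C/m lapse rate, and trend effects of
magnitude ~0.3-0.4 on the logit scale.

All randomness flows from a single counter-based (Philox) stream seeded by
``SimulationConfig.seed``; identical configs give identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate import PRECIPITATION, TEMPERATURE
from .datasets import (
    AGE_AHY, AGE_ASY, AGE_SY, AugmentedState, EncounterDataset, ModelParams,
)
from .model import _gamma_series, _phi_series, year_index


@dataclass(frozen=True)
class ClimateScenario:
    """Linear climate field: value = intercept + year_slope*(year-ref_year)
    + elev_slope*(elev-ref_elevation) + shared year anomaly + station noise.

    ``value_sd`` is the reported SD of daily values (temperature only); the
    shared year anomaly is what makes the true plot-level covariate vary
    between years beyond the trend.
    """

    variable: str = TEMPERATURE
    intercept: float = 16.1
    elev_slope: float = -0.006
    year_slope: float = 0.07
    noise_sd: float = 0.3
    interannual_sd: float = 0.5
    value_sd: float | None = 2.0
    ref_elevation: float = 1200.0
    ref_year: int = 2002


DEFAULT_PRECIP = ClimateScenario(
    variable=PRECIPITATION, intercept=2283.0, elev_slope=0.62, year_slope=5.0,
    noise_sd=120.0, interannual_sd=300.0, value_sd=None)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic plot."""

    T: int = 15
    M: int = 150
    area_ha: float = 18.0
    first_year: int = 2002
    expected_n1: float = 12.0
    params: ModelParams = field(default_factory=lambda: ModelParams(
        alpha=1.0, beta0_gamma=-0.2, beta1_gamma=-0.3, beta2_gamma=0.05,
        beta0_phi_sy=-0.5, beta0_phi_asy=0.1, beta1_phi=-0.4,
        beta0_cap=1.0, beta1_cap=0.0, k=0.8, tau=0.5, p_eta=0.85, p_r=0.61))
    temperature: ClimateScenario = field(default_factory=ClimateScenario)
    precipitation: ClimateScenario = field(default_factory=lambda: DEFAULT_PRECIP)
    n_stations: int = 6
    plot_elevation: float = 1200.0
    single_day_years: tuple = ()
    density_power: int = 2
    seed: int = 0

    def __post_init__(self):
        if self.T < 2:
            raise ValueError("T must be >= 2")
        if self.M <= self.expected_n1:
            raise ValueError("M must exceed the expected initial abundance")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.first_year, self.first_year + self.T)

    @property
    def pi1(self) -> float:
        return self.expected_n1 / self.M

    def rng(self, salt: int = 0) -> np.random.Generator:
        return np.random.Generator(np.random.Philox(key=self.seed + (salt << 20)))


@dataclass
class TruthRecord:
    """Full latent truth of one simulated population."""

    b: np.ndarray
    a1: np.ndarray
    z: np.ndarray
    n1: np.ndarray
    n2: np.ndarray
    N: np.ndarray
    gamma: np.ndarray
    phi: np.ndarray  # (2, T-1)
    pi: np.ndarray   # realized entry probabilities, length T+1
    w: np.ndarray
    years: np.ndarray

    def state(self) -> AugmentedState:
        return AugmentedState(b=self.b.copy(), a1=self.a1.copy(), z=self.z.copy())

    def to_dict(self) -> dict:
        return {
            "years": self.years.tolist(), "N": self.N.tolist(),
            "n1": self.n1.tolist(), "n2": self.n2.tolist(),
            "b": self.b.tolist(), "a1": self.a1.tolist(),
            "gamma": self.gamma.tolist(), "pi": self.pi.tolist(),
            "w": self.w.tolist(),
        }


def simulate_climate(config: SimulationConfig, rng=None) -> pd.DataFrame:
    """Station-year climate records for both variables.

    Stations sit evenly within +-150 m of the plot; temperature records
    carry the per-station SD of daily values.
    """
    if config.n_stations < 2:
        raise ValueError("need at least two stations")
    if rng is None:
        rng = config.rng(salt=1)
    elevs = np.linspace(config.plot_elevation - 150.0,
                        config.plot_elevation + 150.0, config.n_stations)
    rows = []
    for scen in (config.temperature, config.precipitation):
        anomalies = rng.normal(0.0, scen.interannual_sd, size=config.T)
        for t, year in enumerate(config.years):
            for s, elev in enumerate(elevs):
                value = (scen.intercept
                         + scen.year_slope * (year - scen.ref_year)
                         + scen.elev_slope * (elev - scen.ref_elevation)
                         + anomalies[t]
                         + rng.normal(0.0, scen.noise_sd))
                sd = scen.value_sd if scen.value_sd is not None else np.nan
                rows.append((f"ST{s:02d}", elev, int(year), scen.variable,
                             value, sd))
    return pd.DataFrame(rows, columns=["station_id", "elevation_m", "year",
                                       "variable", "value", "value_sd"])


def true_plot_covariate(config: SimulationConfig, scenario: ClimateScenario,
                        rng=None) -> np.ndarray:
    """True covariate at the plot: trend plus shared interannual anomaly."""
    if rng is None:
        rng = config.rng(salt=2)
    anomalies = rng.normal(0.0, scenario.interannual_sd, size=config.T)
    return (scenario.intercept
            + scenario.year_slope * (config.years - scenario.ref_year)
            + scenario.elev_slope * (config.plot_elevation - scenario.ref_elevation)
            + anomalies)


def standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / (sd if sd > 0 else 1.0)


def simulate_population(config: SimulationConfig, covariate=None,
                        rng=None) -> TruthRecord:
    """Simulate the latent population under the generative model.

    ``covariate`` is the per-year trend variable on the coefficient scale
    (defaults to the centered/scaled year index, i.e. the time variant).
    Entries are sequential: each pseudo-individual not yet entered joins
    year t with conditional probability pi_t / (1 - sum_{s<t} pi_s), where
    pi_t = (n1+n2)_{t-1} * gamma_{t-1} / M from the realized abundances.
    """
    T, M = config.T, config.M
    if covariate is None:
        w = year_index(T)
    else:
        w = np.asarray(covariate, dtype=float)
        if w.shape != (T,):
            raise ValueError("covariate must have length T")
    if rng is None:
        rng = config.rng(salt=3)
    p = config.params.replace(pi1=config.pi1)

    b = np.full(M, T, dtype=np.int64)
    a1 = np.zeros(M, dtype=np.int64)
    z = np.zeros((M, T), dtype=np.int8)
    n1 = np.zeros(T, dtype=np.int64)
    n2 = np.zeros(T, dtype=np.int64)
    N = np.zeros(T, dtype=np.int64)
    pi = np.zeros(T + 1)
    gam = np.zeros(T - 1)
    phi = _phi_series(p, w, None)

    enter0 = rng.random(M) < p.pi1
    b[enter0] = 0
    z[enter0, 0] = 1
    a1[enter0] = (rng.random(int(enter0.sum())) < p.tau).astype(np.int64)
    n1[0] = int((enter0 & (a1 == 0)).sum())
    n2[0] = int((enter0 & (a1 == 1)).sum())
    N[0] = n1[0] + n2[0]
    pi[0] = p.pi1
    remaining = 1.0 - p.pi1

    ages = np.ones(M, dtype=np.int64)  # current age class of alive females
    ages[enter0] = a1[enter0]

    for t in range(1, T):
        # survival t-1 -> t
        alive_prev = z[:, t - 1] == 1
        surv_p = np.where(ages == 0, phi[0, t - 1], phi[1, t - 1])
        survived = alive_prev & (rng.random(M) < surv_p)
        z[survived, t] = 1
        ages[survived] = 1
        # recruitment
        ed = N[t - 1] / config.area_ha
        g = float(_gamma_series(p, w[t - 1:t + 1],
                                np.array([N[t - 1], 0]), config.area_ha,
                                None, config.density_power)[0])
        gam[t - 1] = g
        pi_t = (n1[t - 1] + n2[t - 1]) * g / M
        pi[t] = pi_t
        if pi_t > remaining + 1e-12:
            raise RuntimeError("cumulative entry probability exceeded 1; "
                               "reduce recruitment or increase M")
        cond = pi_t / remaining if remaining > 0 else 0.0
        at_risk = b >= T
        entered = at_risk & (rng.random(M) < cond)
        b[entered] = t
        z[entered, t] = 1
        ages[entered] = 0
        remaining -= pi_t
        alive_now = z[:, t] == 1
        n1[t] = int((alive_now & (ages == 0)).sum())
        n2[t] = int((alive_now & (ages == 1)).sum())
        N[t] = n1[t] + n2[t]
        if int((b < T).sum()) >= M:
            raise RuntimeError("augmentation bound exhausted; increase M")
    pi[T] = remaining
    return TruthRecord(b=b, a1=a1, z=z, n1=n1, n2=n2, N=N, gamma=gam,
                       phi=phi, pi=pi, w=w, years=config.years)


def simulate_observations(truth: TruthRecord, params: ModelParams,
                          area_ha: float, m: int | None = None,
                          single_day_years=(), rng=None, seed: int = 0,
                          plot_id: str = "sim") -> EncounterDataset:
    """Overlay the observation process on a latent truth.

    Unmarked alive females are captured with probability p^c_t and marked
    from then on; captures are aged SY/ASY with probability k, AHY
    otherwise.  Marked females are resighted with probability p_eta (times
    p_r in single-day years, including the capture year); unmarked alive
    females are counted with the same detection.  The returned dataset
    carries ``truth_indices`` mapping its rows back to the truth.
    """
    if rng is None:
        rng = np.random.Generator(np.random.Philox(key=seed + (4 << 20)))
    M, T = truth.z.shape
    if m is None:
        m = M
    years = truth.years
    ts = year_index(years)
    pc = 1.0 / (1.0 + np.exp(-(params.beta0_cap + params.beta1_cap * ts)))
    sd_mask = np.isin(years, np.asarray(list(single_day_years), dtype=int))
    pe = params.p_eta * np.where(sd_mask, params.p_r, 1.0)
    ages = truth.state().ages()

    cap = np.zeros((M, T), dtype=np.int8)
    res = np.zeros((M, T), dtype=np.int8)
    agecls = np.zeros(M, dtype=np.int8)
    fc = np.full(M, T, dtype=np.int64)
    u = np.zeros(T, dtype=np.int64)
    for t in range(T):
        alive = truth.z[:, t] == 1
        unmarked = alive & (fc > t)
        newly = unmarked & (rng.random(M) < pc[t])
        cap[newly, t] = 1
        fc[newly] = t
        for i in np.flatnonzero(newly):
            if rng.random() < params.k:
                agecls[i] = AGE_SY if ages[i, t] == 0 else AGE_ASY
            else:
                agecls[i] = AGE_AHY
        marked_alive = alive & (fc <= t)
        res[marked_alive, t] = (rng.random(int(marked_alive.sum())) < pe[t]).astype(np.int8)
        n_unmarked = int((alive & (fc > t)).sum())
        u[t] = rng.binomial(n_unmarked, pe[t])

    observed = np.flatnonzero(fc < T)
    ds = EncounterDataset(
        years=years, capture=cap[observed].reshape(len(observed), T),
        age_at_capture=agecls[observed], resight=res[observed].reshape(len(observed), T),
        unmarked_count=u, m=m, area_ha=area_ha,
        single_day_years=tuple(np.asarray(list(single_day_years), dtype=int)),
        plot_id=plot_id,
        individual_ids=[f"F{i:04d}" for i in observed])
    ds.truth_indices = observed
    return ds


def simulate_dataset(config: SimulationConfig, variant: str = "time"):
    """End-to-end draw: climate stations, latent truth, observed dataset.

    Returns ``(stations, dataset, truth)``.  For climate variants the
    demographic covariate is the standardized true plot-level series of the
    chosen variable; for the time variant it is the scaled year index.
    """
    stations = simulate_climate(config)
    if variant == "time":
        cov = None
    elif variant == "temperature":
        cov = standardize(true_plot_covariate(config, config.temperature))
    elif variant == "precipitation":
        cov = standardize(true_plot_covariate(config, config.precipitation))
    else:
        raise ValueError(f"unknown variant {variant!r}")
    truth = simulate_population(config, covariate=cov)
    ds = simulate_observations(
        truth, config.params.replace(pi1=config.pi1), config.area_ha,
        m=config.M, single_day_years=config.single_day_years,
        rng=config.rng(salt=4))
    return stations, ds, truth
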