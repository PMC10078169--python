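"""Data-augmented Jolly-Seber model integrating mark-resight and count data.

The local population of breeding females on one plot is represented by M
augmented pseudo-individuals.  Each has a latent entry year b_i (T+1 means
"never enters"), an alive trajectory z_{i,t} driven by age-specific apparent
survival, and an age that is SY in the entry year and ASY afterwards (the
first study year uses an age-ratio parameter tau instead).  Per-capita
recruitment follows a logistic function with negative density dependence
and a trend in either time or a climate covariate; apparent survival is
logit-linear in the same trend.  Observations consist of a single capture
(with probabilistic ageing), subsequent resightings, and yearly binomial
counts of unmarked females.

Entry probabilities use the realized SY/ASY abundances of the current
augmented state:

    pi_t = (n1_{t-1} + n2_{t-1}) * gamma_{t-1} / M,      t = 2..T,

with pi_1 a free parameter and pi_{T+1} = 1 - sum_t pi_t.  Entries are
realized sequentially in time — each not-yet-entered pseudo-individual
enters year t with conditional probability pi_t / (1 - sum_{s<t} pi_s) — so
each individual's likelihood contribution telescopes to exactly pi_{b_i}
evaluated along the realized trajectory, and the latent density is properly
normalized.  States whose cumulative entry probability exceeds one receive
density zero (log-density -inf) rather than raising.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln

from .datasets import (
    AGE_ASY, AGE_SY, AugmentedState, EncounterDataset, ModelParams,
    PriorSpec, TrendSpec,
)

NEG_INF = -np.inf


def season_miss_probability(p_visit: float = 0.61, n_visits: int = 10) -> float:
    """Probability of never detecting a present female across a whole season.

    With per-visit detection ``p_visit`` and ``n_visits`` independent
    territory visits this is (1 - p_visit)^n_visits; at the observed visit
    effort it is far below 1e-3, which is why the resight probability p_eta
    measures breeding presence on the plot (temporary emigration) rather
    than detection failure.
    """
    if not 0.0 <= p_visit <= 1.0 or n_visits < 1:
        raise ValueError("need 0 <= p_visit <= 1 and n_visits >= 1")
    return float((1.0 - p_visit) ** n_visits)


def year_index(years_or_T) -> np.ndarray:
    """Centered year index scaled to unit SD (numerical stability of logits)."""
    if np.isscalar(years_or_T):
        years = np.arange(int(years_or_T), dtype=float)
    else:
        years = np.asarray(years_or_T, dtype=float)
    sd = years.std()
    return (years - years.mean()) / (sd if sd > 0 else 1.0)


def _slope_per_year(base: float, post: float, cp_mask: np.ndarray | None, T: int) -> np.ndarray:
    if cp_mask is None:
        return np.full(T, base)
    return np.where(cp_mask, post, base)


def _safe_log(p) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(p)


def recruitment_rate(params: ModelParams, w, ed, density_power: int = 2,
                     post: bool = False):
    """Per-capita recruitment rate gamma, bounded in (0, alpha).

    gamma = alpha / (1 + exp(-(beta0 + beta1*w - beta2*ED^density_power)))
    with ED the female density (females/ha).
    """
    w = np.asarray(w, dtype=float)
    ed = np.asarray(ed, dtype=float)
    b1 = params.beta1_gamma_post if post else params.beta1_gamma
    lin = params.beta0_gamma + b1 * w - params.beta2_gamma * ed ** density_power
    return params.alpha * expit(lin)


def survival_probability(params: ModelParams, age, w, post: bool = False):
    """Apparent survival: logit(phi_j) = beta0_phi_j + beta1_phi * w.

    ``age`` is 0 for SY, 1 for ASY; the trend coefficient is shared across
    age classes and only the intercept differs.
    """
    age = np.asarray(age)
    w = np.asarray(w, dtype=float)
    b0 = np.where(age == 0, params.beta0_phi_sy, params.beta0_phi_asy)
    b1 = params.beta1_phi_post if post else params.beta1_phi
    return expit(b0 + b1 * w)


def _gamma_series(params: ModelParams, w: np.ndarray, N: np.ndarray, area: float,
                  cp_mask, density_power: int) -> np.ndarray:
    """gamma_t for transitions t -> t+1 (t = 1..T-1), from realized density."""
    T = len(w)
    b1 = _slope_per_year(params.beta1_gamma, params.beta1_gamma_post, cp_mask, T)
    ed = N[:-1] / area
    lin = params.beta0_gamma + b1[:-1] * w[:-1] - params.beta2_gamma * ed ** density_power
    return params.alpha * expit(lin)


def _phi_series(params: ModelParams, w: np.ndarray, cp_mask) -> np.ndarray:
    """(2, T-1) apparent survival by age class for transitions t -> t+1."""
    T = len(w)
    b1 = _slope_per_year(params.beta1_phi, params.beta1_phi_post, cp_mask, T)
    lin = b1[:-1] * w[:-1]
    return expit(np.stack([params.beta0_phi_sy + lin, params.beta0_phi_asy + lin]))


def entry_probabilities(params: ModelParams, state: AugmentedState, w, M: int,
                        area: float = 1.0, cp_mask=None,
                        density_power: int = 2) -> np.ndarray:
    """Entry probabilities pi_1..pi_{T+1} from the realized augmented state.

    pi_{T+1} absorbs the remaining mass and may be negative if the
    parameters imply cumulative entry probability above one; the latent
    density treats that as an invalid state (-inf), not an exception.
    """
    w = np.asarray(w, dtype=float)
    T = len(w)
    n1, n2, N = state.abundance()
    gam = _gamma_series(params, w, N, area, cp_mask, density_power)
    pi = np.empty(T + 1)
    pi[0] = params.pi1
    pi[1:T] = (n1[:-1] + n2[:-1]) * gam / M
    pi[T] = 1.0 - pi[:T].sum()
    return pi


def latent_log_density(params: ModelParams, state: AugmentedState, w,
                       area: float = 1.0, cp_mask=None,
                       density_power: int = 2) -> float:
    """Joint log-density of the latent entries, first-year ages and survival.

    Returns -inf for structurally impossible states (alive before entry,
    resurrection, entry probabilities that cannot be realized).
    """
    if not state.is_consistent():
        return NEG_INF
    w = np.asarray(w, dtype=float)
    T, M = state.T, state.M
    pi = entry_probabilities(params, state, w, M, area, cp_mask, density_power)
    if pi[T] < 0 or np.any(pi < 0):
        return NEG_INF
    entered = state.b < T
    counts = np.bincount(state.b, minlength=T + 1)
    with np.errstate(divide="ignore"):
        logpi = np.log(pi)
    if np.any((counts > 0) & ~np.isfinite(logpi)):
        return NEG_INF
    ll = float(np.dot(counts, np.where(counts > 0, logpi, 0.0)))

    first = entered & (state.b == 0)
    n_first = int(first.sum())
    if n_first:
        n_asy = int((state.a1[first] == 1).sum())
        n_sy = n_first - n_asy
        with np.errstate(divide="ignore"):
            if n_asy:
                ll += n_asy * np.log(params.tau)
            if n_sy:
                ll += n_sy * np.log1p(-params.tau)
        if not np.isfinite(ll):
            return NEG_INF

    phi = _phi_series(params, w, cp_mask)  # (2, T-1)
    ages = state.ages()
    with np.errstate(divide="ignore"):
        logphi, log1mphi = np.log(phi), np.log1p(-phi)
    for i in range(M):
        bi = int(state.b[i])
        if bi >= T:
            continue
        alive = np.flatnonzero(state.z[i])
        d = int(alive[-1])
        for t in range(bi, d):
            ll += logphi[ages[i, t], t]
        if d < T - 1:
            ll += log1mphi[ages[i, d], d]
        if not np.isfinite(ll):
            return NEG_INF
    return ll


def observation_log_density(params: ModelParams, state: AugmentedState,
                            data: EncounterDataset) -> float:
    """Log-density of captures, resightings and unmarked counts given the state.

    Unmarked alive females are captured with probability p^c_t (logit-linear
    in time) and aged to SY/ASY with probability k (AHY otherwise); an aged
    capture that contradicts the latent age has density zero.  Marked
    females are resighted with probability p_eta (times p_r in single-day
    survey years), and the count of unmarked females is binomial with the
    same detection.
    """
    T, M = state.T, state.M
    if data.T != T or data.M != M:
        raise ValueError("state and data dimensions disagree")
    ts = year_index(data.years)
    pc = expit(params.beta0_cap + params.beta1_cap * ts)
    pe = params.p_eta * np.where(data.single_day, params.p_r, 1.0)
    with np.errstate(divide="ignore"):
        lpc_aged = np.log(pc * params.k)
        lpc_ahy = np.log(pc * (1.0 - params.k))
        l1mpc = np.log1p(-pc)
        lpe, l1mpe = np.log(pe), np.log1p(-pe)

    fc = data.first_capture
    ages = state.ages()
    ll = 0.0
    for i in range(data.n_obs):
        f = int(fc[i])
        if state.z[i, f] != 1:
            return NEG_INF  # captured therefore alive
        aged = int(data.age_at_capture[i])
        if aged == AGE_SY:
            if ages[i, f] != 0:
                return NEG_INF
            ll += lpc_aged[f]
        elif aged == AGE_ASY:
            if ages[i, f] != 1:
                return NEG_INF
            ll += lpc_aged[f]
        else:  # AHY
            ll += lpc_ahy[f]
        for t in range(T):
            zi = state.z[i, t]
            if t < f:
                if data.capture[i, t]:
                    return NEG_INF
                if zi:
                    ll += l1mpc[t]
            else:  # marked from the capture year on; resight channel
                if data.resight[i, t]:
                    if not zi:
                        return NEG_INF
                    ll += lpe[t]
                elif zi:
                    ll += l1mpe[t]
        if not np.isfinite(ll):
            return NEG_INF

    for i in range(data.n_obs, M):  # never captured
        for t in np.flatnonzero(state.z[i]):
            ll += l1mpc[t]

    # unmarked females: alive and not yet captured
    marked_from = np.full(M, T, dtype=int)
    marked_from[:data.n_obs] = fc
    t_idx = np.arange(T)
    unmarked = t_idx[None, :] < marked_from[:, None]
    U = (state.z.astype(bool) & unmarked).sum(axis=0)
    u = data.unmarked_count
    if np.any(u > U):
        return NEG_INF
    ll += float(np.sum(gammaln(U + 1) - gammaln(u + 1) - gammaln(U - u + 1)
                       + u * lpe + (U - u) * l1mpe))
    if not np.isfinite(ll):
        return NEG_INF
    return ll


def covariate_log_density(params: ModelParams, mu, sigma) -> float:
    """Measurement model for the plot-level climate covariate.

    The predicted plot-level mean mu_t is a noisy observation of the latent
    true covariate w_t:  mu_t ~ Normal(w_t, sigma_t).
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    if np.any(sigma <= 0):
        raise ValueError("covariate prediction SEs must be positive")
    w = np.asarray(params.w, dtype=float)
    if w.shape != mu.shape:
        raise ValueError("params.w must hold one latent value per modeled year")
    return float(np.sum(-0.5 * np.log(2 * np.pi) - np.log(sigma)
                        - 0.5 * ((mu - w) / sigma) ** 2))


def prior_log_density(params: ModelParams, priors: PriorSpec = PriorSpec(), *,
                      changepoint: bool = False, include_pr: bool = True,
                      n_w: int = 0) -> float:
    """Joint log prior density.

    Gaussian (mean 0, SD sd_beta) priors on regression coefficients, a
    half-Gaussian on the density-dependence coefficient (negative density
    dependence only), Exponential(alpha_rate) on the recruitment bound,
    Uniform(0,1) on k, tau, pi_1 and p_eta, a moment-matched Beta on p_r,
    and Normal(0, sd_w) on each latent covariate value.
    """
    for v in (params.k, params.tau, params.pi1, params.p_eta, params.p_r):
        if not 0.0 <= v <= 1.0:
            return NEG_INF
    if params.alpha <= 0 or params.beta2_gamma < 0:
        return NEG_INF
    sd = priors.sd_beta
    betas = [params.beta0_gamma, params.beta1_gamma, params.beta0_phi_sy,
             params.beta0_phi_asy, params.beta1_phi, params.beta0_cap,
             params.beta1_cap]
    if changepoint:
        betas += [params.beta1_gamma_post, params.beta1_phi_post]

    def _norm(x, s):
        return -0.5 * np.log(2 * np.pi) - np.log(s) - 0.5 * (x / s) ** 2

    ll = float(sum(_norm(b, sd) for b in betas))
    ll += np.log(2.0) + _norm(params.beta2_gamma, sd)      # half-normal
    ll += np.log(priors.alpha_rate) - priors.alpha_rate * params.alpha
    if include_pr:
        a, b = priors.pr_beta_shapes()
        with np.errstate(divide="ignore"):
            ll += ((a - 1) * np.log(params.p_r) + (b - 1) * np.log1p(-params.p_r)
                   - betaln(a, b))
        if not np.isfinite(ll):
            return NEG_INF
    if n_w:
        ll += float(np.sum(_norm(np.asarray(params.w[:n_w]), priors.sd_w)))
    return ll


class JollySeberModel:
    """Data-augmented Jolly-Seber model for one plot and one trend variant.

    Parameters
    ----------
    data : EncounterDataset
        Histories, counts, augmentation bound and plot metadata.
    trend : TrendSpec
        Which trend (time / temperature / precipitation) drives recruitment
        and survival, with an optional changepoint year.
    climate : pandas.DataFrame, optional
        Plot-level climate estimates with columns ``year, mu, sigma``
        (output of :func:`jspva.climate.predict_plot_climate`); required
        for the climate variants.  Covariates are centered and scaled to
        unit SD internally; coefficients act on that scale.
    priors : PriorSpec
    density_power : int
        Exponent on density in the recruitment function (2 by default,
        i.e. gamma depends on ED^2; 1 selects plain ED).

    Examples
    --------
    >>> model = JollySeberModel(data, TrendSpec("time"))
    >>> result = model.fit(draws=2000, adapt=500, chains=3, seed=1)
    >>> result.summary()  # doctest: +SKIP
    """

    def __init__(self, data: EncounterDataset, trend: TrendSpec = TrendSpec("time"),
                 climate: pd.DataFrame | None = None,
                 priors: PriorSpec = PriorSpec(), density_power: int = 2):
        self.data = data
        self.trend = trend
        self.priors = priors
        if density_power not in (1, 2):
            raise ValueError("density_power must be 1 or 2")
        self.density_power = int(density_power)
        self.ts = year_index(data.years)
        T = data.T

        if trend.changepoint is not None:
            if not data.years[0] < trend.changepoint <= data.years[-1]:
                raise ValueError("changepoint must lie within the observed years")
            self.cp_mask = data.years >= trend.changepoint
        else:
            self.cp_mask = None

        if trend.variant == "time":
            self.mu_std = None
            self.sigma_std = None
            self.covariate_center = 0.0
            self.covariate_scale = 1.0
        else:
            if climate is None:
                raise ValueError(f"variant {trend.variant!r} needs plot-level "
                                 "climate estimates")
            cl = climate.sort_values("year")
            cl_years = cl["year"].to_numpy(dtype=int)
            if not np.array_equal(cl_years, data.years):
                raise ValueError("climate estimates must cover exactly the data years")
            mu = cl["mu"].to_numpy(dtype=float)
            sigma = cl["sigma"].to_numpy(dtype=float)
            if np.any(sigma <= 0):
                raise ValueError("climate sigma must be positive")
            self.covariate_center = float(mu.mean())
            scale = float(mu.std())
            self.covariate_scale = scale if scale > 0 else 1.0
            self.mu_std = (mu - self.covariate_center) / self.covariate_scale
            self.sigma_std = sigma / self.covariate_scale
        self._T = T

    # ----- reference joint density (tests, enumeration oracles) ----------
    def effective_w(self, params: ModelParams) -> np.ndarray:
        if self.trend.variant == "time":
            return self.ts
        return np.asarray(params.w, dtype=float)

    def joint_log_density(self, params: ModelParams, state: AugmentedState,
                          include_prior: bool = True) -> float:
        """Latent + observation (+ covariate + prior) log density."""
        w = self.effective_w(params)
        ll = latent_log_density(params, state, w, self.data.area_ha,
                                self.cp_mask, self.density_power)
        if not np.isfinite(ll):
            return NEG_INF
        ll += observation_log_density(params, state, self.data)
        if not np.isfinite(ll):
            return NEG_INF
        if self.trend.variant != "time":
            ll += covariate_log_density(params, self.mu_std, self.sigma_std)
        if include_prior:
            ll += prior_log_density(
                params, self.priors,
                changepoint=self.trend.changepoint is not None,
                include_pr=bool(self.data.single_day.any()),
                n_w=self._T if self.trend.variant != "time" else 0)
        return ll

    # ----- fitting --------------------------------------------------------
    def fit(self, draws: int = 2000, adapt: int = 500, chains: int = 3,
            seed: int = 0, sample_params: bool = True,
            init_params: ModelParams | None = None):
        """Sample the posterior; returns a :class:`jspva.infer.JollySeberResults`.

        Default desk-scale settings are 3 chains x 2,000 kept draws after
        500 adaptation iterations; set ``draws=35000, adapt=1000`` for
        full-scale runs.
        """
        from .infer import run_mcmc
        return run_mcmc(self, draws=draws, adapt=adapt, chains=chains,
                        seed=seed, sample_params=sample_params,
                        init_params=init_params)
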