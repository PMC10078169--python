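# jspva

Integrated Bayesian Jolly–Seber demography with climate trends and
population-viability forecasting.

`jspva` is for population ecologists analysing long-term mark–resight
studies of territorial breeding animals — the motivating system is
color-banded female songbirds censused yearly on forest plots along an
elevation gradient.  It answers three questions for a single study plot:
how many breeding females were present each year, whether recruitment and
apparent survival trend with time or with climate (early-breeding
temperature, annual precipitation), and how likely the local population is
to be extinct by a horizon year under those trends.

## The model

An open population of females is represented by M augmented
pseudo-individuals with latent entry years b_i ∈ {1, …, T+1} (T+1 = never
enters), alive states z_{i,t} with N_t = Σ_i z_{i,t}, and ages (SY =
first-time breeder, ASY = experienced).  Per-capita recruitment is a
bounded logistic with negative density dependence,

    γ_t = α / (1 + exp(−(β0γ + β1γ w_t − β2γ ED_t²))),   ED_t = N_t / area,

entry probabilities follow the realized abundances,
π_t = (n1_{t−1} + n2_{t−1}) γ_{t−1} / M, and apparent survival is
logit-linear with age-specific intercepts and a shared trend,
logit(φ_{j,t}) = β0φ_j + β1φ w_t.  The trend covariate w_t is the year
index or a latent true climate value observed through the plot-level
prediction μ_t^w ~ Normal(w_t, σ_t^w) from an elevation regression of
nearby climate stations.  Observations integrate three channels: a single
capture per female (aged SY/ASY with probability k, ambiguous AHY
otherwise), subsequent resightings with probability p^η (times p^r in
single-day survey years), and yearly binomial counts of unmarked females.
Posterior sampling uses the package's own Metropolis-within-Gibbs sampler
(numba-compiled), with exact enumeration of each individual's latent
trajectory; forecasts project every posterior draw forward with a fresh
augmented pool and, for climate variants, a random-walk future covariate
built from the fitted station trend.  See `docs/methods.md` for the full
account.

## Worked example

```python
from jspva import (JollySeberModel, SimulationConfig, TrendSpec,
                   extinction_risk, simulate_dataset)

stations, data, truth = simulate_dataset(SimulationConfig(seed=11), variant="time")
model = JollySeberModel(data, TrendSpec("time"))
result = model.fit(draws=2000, adapt=500, chains=3, seed=1)
print(result.summary().loc[["beta1_phi", "beta0_phi_asy", "p_eta", "N_2016"]].round(3))
forecast = result.forecast(horizon_year=2040, seed=1)
print(f"extinction risk by 2040: {extinction_risk(forecast):.1f}%")
```

prints

```
               median  cri_2.5  cri_97.5
parameter
beta1_phi      -0.801   -1.315    -0.330
beta0_phi_asy  -0.239   -0.730     0.206
p_eta           0.861    0.799     0.912
N_2016          0.000    0.000     0.000
extinction risk by 2040: 100.0%
```

The simulated plot (95 marked females over 15 years, true survival trend
−0.4 per SD of the year index) declines from 15 females to local
extinction by 2014.  The posterior recovers the negative survival trend
(median −0.80, 95% CrI −1.32 to −0.33), estimates the resight/presence
probability p^η at 0.86 (truth 0.85), pins the 2016 abundance at zero,
and — with survival and recruitment still declining — every forecast
trajectory is extinct by 2040.

The same analysis is scriptable from the shell:

```sh
jspva simulate --seed 11 --out fixture        # climate + encounters + counts
jspva fit --config fixture/config.yaml        # posterior summaries
jspva forecast --config fixture/config.yaml --horizon 2040
jspva report --out fixture/run
```

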