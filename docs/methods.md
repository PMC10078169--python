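# Methods

## The model

`jspva` fits an open-population Jolly–Seber model, parameter-expanded by
data augmentation, that integrates two data streams collected on one study
plot: individual capture–resight histories of marked breeding females and
yearly counts of unmarked females.  The population is represented by M
pseudo-individuals (M far above the plausible number of females ever
entering the plot).  Each pseudo-individual i carries

* an entry year `b_i ∈ {1, …, T, T+1}` (T+1 = never enters),
* alive states `z_{i,t}` with `N_t = Σ_i z_{i,t}`,
* an age class `a_{i,t}` (0 = SY, first-time breeder; 1 = ASY,
  experienced breeder): SY in the entry year and ASY afterwards, except
  that first-study-year entrants are ASY with probability τ (the initial
  age ratio).

### Demographic process

Per-capita recruitment from year t to t+1 is a bounded logistic with
negative density dependence and a trend in a covariate `w_t`:

    γ_t = α / (1 + exp(−(β0γ + β1γ·w_t − β2γ·ED_t²)))

with `ED_t = N_t / area` the realized female density (females/ha) and
`β2γ ≥ 0`.  The exponent on density is configurable (`density_power`,
default 2).  Apparent survival is age-specific and logit-linear in the
same covariate, with a shared trend and age-specific intercepts:

    logit(φ_{j,t}) = β0φ_j + β1φ·w_t,   j ∈ {SY, ASY}.

`w_t` is one of: the centered year index scaled to unit SD (time variant);
the latent true early-breeding temperature; or the latent true annual
precipitation (both standardized by the observed plot-level series).  A
changepoint year may split β1γ and β1φ into separate before/after
coefficients.

### Entry probabilities and normalization

Entry probabilities follow the realized-abundance convention:
`π_1` is a free parameter and, for t ≥ 2,

    π_t = (n1_{t−1} + n2_{t−1}) · γ_{t−1} / M,

with `n1, n2` the realized SY/ASY abundances of the current augmented
state.  Because π depends on the evolving state, the joint density is
defined by the sequential construction: each not-yet-entered
pseudo-individual enters year t with conditional probability
`π_t / (1 − Σ_{s<t} π_s)`.  The product over years telescopes, so each
individual contributes exactly `π_{b_i}` (or the leftover mass `π_{T+1}`)
evaluated along the realized trajectory, and the latent density sums to
one by construction — the test suite verifies this by exhaustive
enumeration on M ≤ 3, T ≤ 2 instances.  Parameter/state combinations whose
cumulative entry probability exceeds one receive density zero (log-density
−∞), not an exception; in practice this means M must comfortably exceed
the cumulative number of entries, as in any data-augmented Jolly–Seber
fit.

### Observation process

Unmarked alive females are captured once with probability
`logit(p^c_t) = β0c + β1c·t` and are marked from the capture year on.  A
capture is aged to its true SY/ASY class with probability k and recorded
as the ambiguous AHY class otherwise; an aged capture that contradicts the
latent age has density zero.  Marked females are resighted with
probability `p^η` — with the season-long visit effort the probability of
missing a present female is `(1−0.61)^10 < 10⁻³`, so `p^η` measures
breeding presence on the plot (temporary emigration) rather than detection
failure.  In years surveyed on a single day, detection is degraded to
`p^η·p^r`, with an informative Beta prior on `p^r` moment-matched to mean
0.61, SD 0.27.  The yearly count of unmarked females is
`u_t ~ Binomial(U_t, p^η[·p^r])` with `U_t` the number of alive, not-yet-
captured females.

Climate covariates carry measurement error: the plot-level prediction
`μ_t^w` from the elevation regression is modeled as
`μ_t^w ~ Normal(w_t, σ_t^w)` and the latent `w_t` are sampled.

### Priors

Normal(0, 10) on all regression coefficients (standardized covariate
scale), half-Normal(10) on β2γ (negative density dependence only),
Exponential(1) on α, Uniform(0,1) on k, τ, π_1 and p^η, the
moment-matched Beta on p^r, and Normal(0, 10) on each latent `w_t`.  All
hyperparameters are adjustable through `PriorSpec`.  The exact "vague"
prior variances of the original analysis are not published; SD 10 on
standardized covariates is effectively flat over the plausible logit
range.

## Sampler

No general-purpose PPL is used; the package ships its own
Metropolis-within-Gibbs sampler with a numba-compiled kernel.  Each sweep:

1. **Latent trajectories** — for every pseudo-individual, the full
   conditional over all trajectories `(b, a_1, death year)` compatible with
   its detections is enumerated exactly (O(T²) candidates) and sampled.
   Candidate evaluation is O(alive span) thanks to per-sweep tables of
   `γ_t(N)` on the integer abundance grid and prefix sums of the
   per-individual observation terms.  Entry terms account for the effect
   of the individual's trajectory on every other individual's entry
   probability (the realized-count coupling).
2. **Parameters** — conjugate Beta draws for k and τ; adaptive random-walk
   Metropolis on transformed scales (log for α and β2γ, logit for
   probabilities, identity for coefficients) for the rest, each against
   only the likelihood block it touches; per-year Metropolis updates of
   the latent `w_t` for climate variants.  Step sizes adapt toward a 0.44
   acceptance rate during the adaptation phase and are then frozen.

Invalid configurations (counts exceeding the unmarked pool, cumulative
entry probability above one) use a −10⁹ sentinel instead of −∞ so an
infeasible initial state anneals into the support.  Latent states
initialize from the detections (entry at capture, one year earlier for
ASY-aged captures, death after the last detection) plus one-year augmented
residents covering the unmarked counts; parameters initialize from
weakly-dispersed values jittered per chain.  If the reference joint
density is still not finite, initialization retries (up to 100 times) with
additional full-span augmented females before raising.

Correctness is established two ways: the pure-NumPy reference densities
normalize over exhaustive enumeration, and the kernel's sampled latent
marginals at fixed parameters match the enumeration posterior within
Monte-Carlo error.

Default desk-scale settings are 3 chains × 2,000 kept draws after 500
adaptation iterations (a single fit of the default synthetic plot takes
seconds); full-scale runs mirror the original analysis at 3 × 35,000 with
1,000 adaptation iterations.  Convergence is summarized by split R-hat and
bulk ESS (via ArviZ) for every sampled scalar and every `N_t`, flagging
R-hat > 1.1; constant chains are flagged as degenerate rather than
erroring.

Known behavior: α and β0γ are individually weakly identified (only
γ = α·expit(β0γ + …) is well constrained when the trend is weak), so their
chains mix slowly and the trend coefficient β1γ has wide credible
intervals.  This is a property of the bounded-logistic recruitment model,
not of the sampler; abundance and survival quantities are unaffected.

## Climate module

Plot-level covariates come from a per-region linear model with a separate
intercept for each year and a shared elevation slope, fitted to stations
within 175 m of the plot elevations; predictions at the plot elevation
give `μ_t^w` and `σ_t^w` (the SE of the fitted mean, since the covariate
enters the demographic model as an uncertain mean, not a new observation).
All temperature regressions are weighted by 1/SD of the daily values
(literally the reciprocal of the SD, not the reciprocal variance).
Long-term trends regress the value on year and elevation (both centered);
the optional year × period interaction tests whether warming differed
before/after a changepoint.  The precipitation-variability test regresses
absolute residuals from the year-intercept model on year and elevation;
its two-stage construction has mildly inflated size (≈0.07 at the nominal
0.05 level with ~200 station-years), which the test suite documents.

## Forecasting

For each posterior draw the population is projected from the last data
year to the horizon (2040 by default): binomial survival of the SY/ASY
cohorts, and recruits entering from a fresh augmented pool of
M_future = 2,400, each joining a future year with probability
`(n1+n2)_{prev}·γ_{prev} / M_future` (expected SY abundance over the
future bound; no leftover-mass renormalization, matching the forecast
construction rather than the fitting one).  Density dependence acts on the
realized forecast density.  Climate variants drive the rates with one
random-walk covariate path per posterior draw,
`w_{t+1} ~ Normal(w_t + μ_trend, σ_trend)`, using the slope and SE of the
fitted station trend converted to the model's standardized scale; the time
variant extends the year index deterministically.  Extinction risk is the
percentage of trajectories with zero females in the horizon year.

## Synthetic data

The generator draws station-year climate records (linear elevation and
year trends, a shared interannual anomaly, station noise, and a reported
daily-SD for temperature), simulates the latent population under exactly
the generative rules above, and overlays the observation layer.  All
randomness flows from one counter-based Philox stream per configuration,
so identical configs give byte-identical outputs.

Default study conditions describe a declining trailing-edge-like plot:
T = 15 years from 2002, an 18-ha plot at 1,200 m with E[N₁] = 12 females,
M = 150 (comfortably above the ~100 expected cumulative entries), warming
of 0.07 °C/yr on a −0.006 °C/m lapse rate, recruitment
α = 1, β0γ = −0.2, β1γ = −0.3, β2γ = 0.05, survival intercepts −0.5 (SY)
and 0.1 (ASY) with trend β1φ = −0.4, capture logit 1.0, ageing probability
k = 0.8, τ = 0.5, p^η = 0.85.  With the negative trends the population
declines from ~15 to a handful of females — the regime where
population-viability questions are interesting.  M = 150 caps the feasible
superpopulation: larger, stable populations need a proportionally larger
M, exactly as in the original augmentation (M = 600).

What the generator does *not* emulate: within-season visit structure (the
season is a single occasion), mis-ageing (aged captures are always
correct), individual heterogeneity in detection or survival, and spatial
structure beyond the elevation regression.  Passing recovery tests
therefore show that the estimator inverts its own generative model at
realistic sizes — not that real field data meet these assumptions.

## Numerical choices

* Year index and climate covariates centered and scaled to unit SD before
  entering logit-linear terms; slopes are per SD of the covariate.
* Equal-tailed percentile summaries (2.5/50/97.5, linear interpolation).
* Probability-zero observations contribute −∞ through guarded logs; the
  sampler kernel uses the −10⁹ sentinel described above.
* Binomial coefficients via integer lgamma tables (exact for counts ≤ M).
* Forecast trajectories and abundances are integers throughout; densities
  are reported per hectare.

## Limitations

* Weak identifiability of (α, β0γ), inherited from the bounded-logistic
  recruitment form.
* The realized-count entry convention conditions on cumulative entry
  probability ≤ 1; fits with M too close to the realized superpopulation
  size concentrate posterior mass on that boundary.
* Single-plot models only; no cross-plot sharing of parameters.
* The changepoint variant estimates separate trends given a known
  changepoint year; it does not infer the changepoint.
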