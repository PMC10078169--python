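"""Core data containers: encounter data, trend specification, priors, parameters.

The encounter dataset holds, for a single study plot, the individual
capture/resight histories of marked females together with the yearly counts
of unmarked females and the data-augmentation bound M.  Only females that
were captured (and hence marked) at least once appear as individual rows;
females that were seen but never captured contribute solely to the unmarked
counts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AGE_NONE, AGE_SY, AGE_ASY, AGE_AHY = 0, 1, 2, 3
AGE_CODES = {"NA": AGE_NONE, "": AGE_NONE, "SY": AGE_SY, "ASY": AGE_ASY, "AHY": AGE_AHY}
AGE_LABELS = {v: k for k, v in AGE_CODES.items() if k != ""}

VARIANTS = ("time", "temperature", "precipitation")


@dataclass(frozen=True)
class TrendSpec:
    """Which trend drives recruitment and survival.

    variant
        ``"time"`` uses a (centered, scaled) year index; ``"temperature"``
        and ``"precipitation"`` use plot-level climate estimates, treated as
        noisy observations of a latent true covariate.
    changepoint
        Optional calendar year splitting the trend coefficient into separate
        before/after effects (the slope applies to years ``< changepoint``
        vs ``>= changepoint``).
    """

    variant: str = "time"
    changepoint: int | None = None

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}, got {self.variant!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the prior distributions.

    Regression coefficients get Normal(0, sd_beta) priors; the recruitment
    bound alpha an Exponential(alpha_rate); the density-dependence
    coefficient a half-Normal (support restricted to negative density
    dependence); single-day detection p_r a Beta moment-matched to
    (pr_mean, pr_sd); latent covariate values Normal(0, sd_w) on the
    standardized scale.  k, tau, pi_1 and p_eta are Uniform(0, 1).
    """

    sd_beta: float = 10.0
    alpha_rate: float = 1.0
    pr_mean: float = 0.61
    pr_sd: float = 0.27
    sd_w: float = 10.0

    def pr_beta_shapes(self) -> tuple[float, float]:
        return beta_moment_match(self.pr_mean, self.pr_sd)


def beta_moment_match(mean: float, sd: float) -> tuple[float, float]:
    """Shape parameters (a, b) of the Beta distribution with given mean/SD."""
    if not 0 < mean < 1:
        raise ValueError("mean must be in (0, 1)")
    var = sd * sd
    if var >= mean * (1 - mean):
        raise ValueError("sd too large for a Beta distribution with this mean")
    nu = mean * (1 - mean) / var - 1.0
    return mean * nu, (1 - mean) * nu


# Parameter vector layout used throughout the package (fixed order; the
# trailing block holds the T latent covariate values).
PARAM_NAMES = [
    "alpha",
    "beta0_gamma",
    "beta1_gamma",
    "beta1_gamma_post",
    "beta2_gamma",
    "beta0_phi_sy",
    "beta0_phi_asy",
    "beta1_phi",
    "beta1_phi_post",
    "beta0_cap",
    "beta1_cap",
    "k",
    "tau",
    "pi1",
    "p_eta",
    "p_r",
]
N_SCALAR_PARAMS = len(PARAM_NAMES)
(I_ALPHA, I_B0G, I_B1G, I_B1G_POST, I_B2G, I_B0P_SY, I_B0P_ASY, I_B1P,
 I_B1P_POST, I_B0C, I_B1C, I_K, I_TAU, I_PI1, I_PETA, I_PR) = range(N_SCALAR_PARAMS)


@dataclass
class ModelParams:
    """One draw of all demographic and observation parameters.

    Regression coefficients act on the standardized covariate scale.
    ``w`` holds the latent true covariate values (length T); for the time
    variant it is the centered/scaled year index.
    """

    alpha: float = 1.0
    beta0_gamma: float = 0.0
    beta1_gamma: float = 0.0
    beta1_gamma_post: float = 0.0
    beta2_gamma: float = 0.0
    beta0_phi_sy: float = 0.0
    beta0_phi_asy: float = 0.0
    beta1_phi: float = 0.0
    beta1_phi_post: float = 0.0
    beta0_cap: float = 0.0
    beta1_cap: float = 0.0
    k: float = 0.5
    tau: float = 0.5
    pi1: float = 0.1
    p_eta: float = 0.9
    p_r: float = 0.61
    w: np.ndarray = field(default_factory=lambda: np.zeros(0))

    def to_vector(self) -> np.ndarray:
        vec = np.empty(N_SCALAR_PARAMS + len(self.w))
        for i, name in enumerate(PARAM_NAMES):
            vec[i] = getattr(self, name)
        vec[N_SCALAR_PARAMS:] = self.w
        return vec

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParams":
        kwargs = {name: float(vec[i]) for i, name in enumerate(PARAM_NAMES)}
        return cls(w=np.asarray(vec[N_SCALAR_PARAMS:], dtype=float), **kwargs)

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def validate(self) -> None:
        for name in ("k", "tau", "pi1", "p_eta", "p_r"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.beta2_gamma < 0:
            raise ValueError("beta2_gamma must be non-negative (negative density dependence)")


class EncounterDataset:
    """Capture/resight histories plus unmarked counts for one plot.

    Parameters
    ----------
    years : array of calendar years (consecutive), length T.
    capture : (n_obs, T) 0/1, capture events.  Each marked female is
        captured exactly once (she is resighted, not recaptured, afterwards).
    age_at_capture : (n_obs,) age-class code recorded at capture
        (AGE_SY, AGE_ASY or AGE_AHY).
    resight : (n_obs, T) 0/1 resightings; only valid from the capture year on.
    unmarked_count : (T,) yearly count of unmarked females.
    m : augmentation bound (superpopulation size), m >= n_obs.
    area_ha : plot area in hectares.
    single_day_years : calendar years in which the plot was surveyed on a
        single day only (detection degraded by p_r).
    """

    def __init__(self, years, capture, age_at_capture, resight, unmarked_count,
                 m, area_ha, single_day_years=(), plot_id="plot",
                 individual_ids=None):
        self.years = np.asarray(years, dtype=int)
        self.T = len(self.years)
        if self.T < 2:
            raise ValueError("need at least two years of data")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be consecutive")
        self.capture = np.asarray(capture, dtype=np.int8).reshape(-1, self.T)
        self.resight = np.asarray(resight, dtype=np.int8).reshape(-1, self.T)
        self.n_obs = self.capture.shape[0]
        self.age_at_capture = np.asarray(age_at_capture, dtype=np.int8)
        self.unmarked_count = np.asarray(unmarked_count, dtype=int)
        self.M = int(m)
        self.area_ha = float(area_ha)
        self.plot_id = str(plot_id)
        self.single_day = np.isin(self.years, np.asarray(list(single_day_years), dtype=int))
        if individual_ids is None:
            individual_ids = [f"F{i:04d}" for i in range(self.n_obs)]
        self.individual_ids = list(individual_ids)
        self._validate()

    def _validate(self) -> None:
        if self.M < self.n_obs:
            raise ValueError(f"augmentation bound M={self.M} smaller than number "
                             f"of marked females {self.n_obs}")
        if self.unmarked_count.shape != (self.T,) or np.any(self.unmarked_count < 0):
            raise ValueError("unmarked_count must be length-T and non-negative")
        if self.n_obs and self.resight.shape != self.capture.shape:
            raise ValueError("capture and resight must have the same shape")
        ncap = self.capture.sum(axis=1)
        if np.any(ncap != 1):
            raise ValueError("each marked female must have exactly one capture event")
        if self.n_obs and (self.age_at_capture.shape != (self.n_obs,) or
                           np.any(~np.isin(self.age_at_capture, [AGE_SY, AGE_ASY, AGE_AHY]))):
            raise ValueError("age_at_capture must be SY, ASY or AHY for every female")
        fc = self.first_capture
        for i in range(self.n_obs):
            if np.any(self.resight[i, :fc[i]] == 1):
                raise ValueError(f"female {self.individual_ids[i]} resighted before capture")

    @property
    def first_capture(self) -> np.ndarray:
        """Year index of the (single) capture for each marked female."""
        if self.n_obs == 0:
            return np.zeros(0, dtype=np.int64)
        return np.argmax(self.capture, axis=1).astype(np.int64)

    @property
    def marked(self) -> np.ndarray:
        """(n_obs, T) marked status; 1 from the capture year onward."""
        fc = self.first_capture
        t = np.arange(self.T)
        return (t[None, :] >= fc[:, None]).astype(np.int8)

    @property
    def first_detection(self) -> np.ndarray:
        return self.first_capture  # resights never precede the capture

    @property
    def last_detection(self) -> np.ndarray:
        fc = self.first_capture
        t = np.arange(self.T)
        det = (self.capture == 1) | (self.resight == 1)
        last = np.where(det, t[None, :], -1).max(axis=1)
        return np.maximum(last, fc)

    # ----- I/O ------------------------------------------------------------
    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """Return (encounters, counts) data frames in the package CSV dialect."""
        rows = []
        fc = self.first_capture
        for i in range(self.n_obs):
            for t in range(self.T):
                cap = int(self.capture[i, t])
                res = int(self.resight[i, t])
                if cap == 0 and res == 0 and not (fc[i] <= t):
                    continue  # nothing observed and not yet marked
                age = AGE_LABELS[int(self.age_at_capture[i])] if cap else "NA"
                rows.append((self.individual_ids[i], int(self.years[t]), cap, age, res))
        enc = pd.DataFrame(rows, columns=["individual_id", "year", "captured",
                                          "age_class", "resighted"])
        counts = pd.DataFrame({"year": self.years, "unmarked_count": self.unmarked_count})
        return enc, counts

    def to_csv(self, encounters_path, counts_path) -> None:
        enc, counts = self.to_frames()
        enc.to_csv(encounters_path, index=False)
        counts.to_csv(counts_path, index=False)

    @classmethod
    def from_frames(cls, encounters: pd.DataFrame, counts: pd.DataFrame, *,
                    m, area_ha, single_day_years=(), plot_id="plot") -> "EncounterDataset":
        counts = counts.sort_values("year")
        years = counts["year"].to_numpy(dtype=int)
        year_index = {y: t for t, y in enumerate(years)}
        ids = list(dict.fromkeys(encounters["individual_id"]))
        idx = {v: i for i, v in enumerate(ids)}
        n = len(ids)
        T = len(years)
        capture = np.zeros((n, T), dtype=np.int8)
        resight = np.zeros((n, T), dtype=np.int8)
        age = np.zeros(n, dtype=np.int8)
        for rec in encounters.itertuples(index=False):
            if rec.year not in year_index:
                raise ValueError(f"encounter year {rec.year} not covered by the counts file")
            i, t = idx[rec.individual_id], year_index[rec.year]
            if int(rec.captured):
                capture[i, t] = 1
                code = AGE_CODES.get(str(rec.age_class).strip(), AGE_NONE)
                if code == AGE_NONE:
                    raise ValueError(f"capture of {rec.individual_id} in {rec.year} "
                                     "lacks an age class (SY/ASY/AHY)")
                age[i] = code
            if int(rec.resighted):
                resight[i, t] = 1
        return cls(years, capture, age, resight,
                   counts["unmarked_count"].to_numpy(dtype=int),
                   m=m, area_ha=area_ha, single_day_years=single_day_years,
                   plot_id=plot_id, individual_ids=ids)

    @classmethod
    def from_csv(cls, encounters_path, counts_path, **kwargs) -> "EncounterDataset":
        return cls.from_frames(pd.read_csv(encounters_path), pd.read_csv(counts_path), **kwargs)


@dataclass
class AugmentedState:
    """Latent state of the data-augmented population.

    b : (M,) entry year index in 0..T (T means "never enters").
    a1 : (M,) first-year age (0 SY, 1 ASY); only meaningful where b == 0.
    z : (M, T) alive indicators.
    """

    b: np.ndarray
    a1: np.ndarray
    z: np.ndarray

    @property
    def M(self) -> int:
        return self.z.shape[0]

    @property
    def T(self) -> int:
        return self.z.shape[1]

    def ages(self) -> np.ndarray:
        """(M, T) latent age class (0 SY, 1 ASY), defined where alive."""
        T = self.T
        t = np.arange(T)[None, :]
        b = self.b[:, None]
        age = np.where(t == b, 0, 1)
        first_asy = (self.b == 0) & (self.a1 == 1)
        age[first_asy, 0] = 1
        return age.astype(np.int8)

    def abundance(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Return (n1, n2, N) per year: SY, ASY and total alive females."""
        age = self.ages()
        n1 = ((self.z == 1) & (age == 0)).sum(axis=0)
        n2 = ((self.z == 1) & (age == 1)).sum(axis=0)
        return n1, n2, n1 + n2

    def is_consistent(self) -> bool:
        """Check the deterministic structure (entry, contiguity, no zombies)."""
        M, T = self.M, self.T
        for i in range(M):
            bi = int(self.b[i])
            zi = self.z[i]
            if bi >= T:
                if zi.any():
                    return False
                continue
            if np.any(zi[:bi] != 0) or zi[bi] != 1:
                return False
            alive = np.flatnonzero(zi)
            if np.any(np.diff(alive) != 1):  # resurrection
                return False
        return True
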