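"""Synthetic neonatal cohorts with known ground truth.

Two cohorts are generated, mirroring the structure of a longitudinal
*training* study (daily weights through day 10 on a few hundred babies,
first weight within 6 h of delivery, no multiples or neonatal deaths) and a
large *application* study (one weight per live birth at a right-skewed
postnatal age, with weights missing for a non-random ~12% concentrated in
neonatal deaths and preterm babies).

Each baby carries a latent weight trajectory anchored at a true birth
weight: an exponential (log-linear) decline to a nadir at ``nadir_time``
days, losing the fraction ``nadir_frac`` of birth weight, an exponential
regain reaching the birth weight again at ``return_time`` days, then linear
postnatal growth.  Observed weights are the trajectory evaluated at the
measurement time plus independent Gaussian measurement noise.  Per-baby
parameters are drawn from right-skewed distributions whose medians are the
generator's calibration targets (nadir at 2.1 days, 4.3% relative loss,
return at 4.5 days among babies that regain within 10 days, 84/457 never
regaining in the window).

A separate linear-mixed-model mode (:func:`simulate_lmm_training_cohort`)
generates repeated weights directly from a random-intercept + random-slope
model with configured covariance ``G`` and residual variance, for
variance-component recovery studies where the linear model is exactly true.

Hidden truth (trajectory parameters, true size-for-gestational-age and
low-birth-weight status, the missingness probability) is returned in a
sidecar table keyed by baby id and is never mixed into the observable table.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm, truncnorm

from .classification import classify_lbw, classify_size_for_ga, synthetic_standard

__all__ = [
    "SimConfig",
    "TrajectoryParams",
    "SimulatedCohort",
    "trajectory_weight",
    "simulate_training_cohort",
    "simulate_application_cohort",
    "simulate_lmm_training_cohort",
]


@dataclass
class TrajectoryParams:
    """Latent weight-trajectory parameters for one baby (grams / days)."""

    birth_weight: float
    nadir_time: float
    nadir_frac: float
    return_time: float
    growth_rate: float = 30.0

    def __post_init__(self):
        if not self.birth_weight > 0:
            raise ValueError("birth_weight must be positive")
        if not self.nadir_time > 0:
            raise ValueError("nadir_time must be positive")
        if not 0.0 <= self.nadir_frac < 1.0:
            raise ValueError("nadir_frac must be in [0, 1)")
        if self.return_time < self.nadir_time:
            raise ValueError("return_time must be >= nadir_time")

    @property
    def nadir_weight(self) -> float:
        return self.birth_weight * (1.0 - self.nadir_frac)

    def __call__(self, t):
        return trajectory_weight(
            t,
            self.birth_weight,
            self.nadir_time,
            self.nadir_frac,
            self.return_time,
            self.growth_rate,
        )


def trajectory_weight(t, birth_weight, nadir_time, nadir_frac, return_time, growth_rate):
    """Evaluate the piecewise trajectory (vectorised over ``t`` and params).

    Log-linear decline on [0, nadir_time] to ``birth_weight*(1-nadir_frac)``,
    log-linear regain on (nadir_time, return_time] back to ``birth_weight``,
    then linear growth at ``growth_rate`` g/day.  Continuous and piecewise
    monotone by construction.
    """
    t = np.asarray(t, dtype=float)
    bw = np.asarray(birth_weight, dtype=float)
    tn = np.asarray(nadir_time, dtype=float)
    fr = np.asarray(nadir_frac, dtype=float)
    tr = np.asarray(return_time, dtype=float)
    g = np.asarray(growth_rate, dtype=float)
    t, bw, tn, fr, tr, g = np.broadcast_arrays(t, bw, tn, fr, tr, g)

    log_drop = np.log1p(-fr)  # log(1 - nadir_frac) <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        frac_down = np.where(tn > 0, np.clip(t / np.where(tn > 0, tn, 1.0), 0, 1), 1.0)
        span = tr - tn
        frac_up = np.where(span > 0, (t - tn) / np.where(span > 0, span, 1.0), 1.0)
        frac_up = np.clip(frac_up, 0, 1)
    w_down = bw * np.exp(log_drop * frac_down)
    w_up = bw * np.exp(log_drop * (1.0 - frac_up))
    w_growth = bw + g * (t - tr)
    w = np.where(t <= tn, w_down, np.where(t <= tr, w_up, w_growth))
    return w


_FRACTION_FIELDS = (
    "never_return_frac",
    "male_frac_training",
    "male_frac_application",
    "multiples_frac",
    "death_frac",
    "ltfu_frac",
    "facility_frac",
    "nadir_frac_median",
    "miss_sex_frac",
    "miss_parity_frac",
    "miss_survival_frac",
    "miss_edu_frac",
)

_POSITIVE_FIELDS = (
    "bw_resid_sd",
    "nadir_time_median",
    "return_time_median",
    "ga_sd_training",
    "ga_sd_application",
    "maternal_age_sd",
    "day0_time_median_h",
    "visit_time_facility_median_h",
    "visit_time_home_median_h",
    "lmm_sigma",
)


@dataclass
class SimConfig:
    """Generator configuration; defaults are the documented calibration.

    All weights are grams, times in days unless a field name says hours.
    """

    n_babies_training: int = 457
    n_births_application: int = 31116
    seed: int = 0

    # ---- birth-weight model (grams) -------------------------------------
    bw_intercept: float = 2810.0
    bw_male: float = 85.0
    bw_first_birth: float = -100.0
    bw_ga_slope_below40: float = 110.0   # g per week, GA < 40
    bw_ga_slope_above40: float = 30.0    # g per week, GA >= 40
    bw_maternal_age: float = 4.0         # g per year, centred
    bw_education: float = 2.0            # g per year of schooling, centred
    bw_multiple: float = -659.0
    bw_death: float = -324.0
    bw_resid_sd: float = 350.0
    bw_floor: float = 500.0
    maternal_age_center: float = 22.5
    education_center: float = 3.0

    # ---- trajectory ------------------------------------------------------
    nadir_time_median: float = 2.1
    nadir_time_log_sd: float = 0.07
    nadir_frac_median: float = 0.043
    nadir_frac_logit_sd: float = 0.35
    return_time_median: float = 4.5      # median among babies returning <=10 d
    never_return_frac: float = 84.0 / 457.0
    followup_window_days: float = 10.0
    postnatal_growth_rate: float = 30.0  # g/day once birth weight is regained
    noise_sd: float = 30.0

    # ---- covariates ------------------------------------------------------
    male_frac_training: float = 0.576
    male_frac_application: float = 0.519
    ga_mean_training: float = 39.7
    ga_sd_training: float = 2.55
    ga_mean_application: float = 39.4
    ga_sd_application: float = 2.4
    ga_min: float = 23.0
    ga_max: float = 44.8
    maternal_age_mean: float = 22.5
    maternal_age_sd: float = 4.5
    maternal_age_min: float = 15.0
    maternal_age_max: float = 45.0
    education_probs: tuple = (0.67, 0.085, 0.245)  # none / 1-5 y / 6+ y
    parity_probs: tuple = (0.315, 0.274, 0.196, 0.108, 0.107)  # 0,1,2,3,4+
    multiples_frac: float = 0.016
    death_frac: float = 0.033
    ltfu_frac: float = 0.035
    death_day_mean: float = 3.0
    births_per_woman_extra: float = 0.38  # extra births per woman ~ Poisson
    facility_frac: float = 0.581

    # ---- measurement timing ---------------------------------------------
    day0_time_median_h: float = 4.1
    day0_time_log_sd: float = 0.383
    day0_max_h: float = 6.0
    visit_time_facility_median_h: float = 11.5
    visit_time_facility_log_sd: float = 1.2
    visit_time_home_median_h: float = 30.0
    visit_time_home_log_sd: float = 2.3

    # ---- missing-weight mechanism (logistic, log-odds) -------------------
    miss_intercept: float = -2.25
    miss_death: float = 2.6
    miss_preterm: float = 0.33
    miss_nulliparous: float = 0.15
    miss_education: float = 0.02  # per year of schooling
    # small covariate missingness (independent)
    miss_sex_frac: float = 0.003
    miss_parity_frac: float = 0.005
    miss_survival_frac: float = 0.0014
    miss_edu_frac: float = 0.001

    # ---- linear-mixed-model generator mode -------------------------------
    lmm_G: tuple = ((160000.0, -1600.0), (-1600.0, 400.0))
    lmm_sigma: float = 50.0

    def validate(self) -> "SimConfig":
        if self.n_babies_training <= 0:
            raise ValueError("n_babies_training must be positive")
        if self.n_births_application <= 0:
            raise ValueError("n_births_application must be positive")
        for name in _FRACTION_FIELDS:
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in _POSITIVE_FIELDS:
            v = getattr(self, name)
            if not v > 0:
                raise ValueError(f"{name} must be positive, got {v}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if abs(sum(self.education_probs) - 1) > 1e-9:
            raise ValueError("education_probs must sum to 1")
        if abs(sum(self.parity_probs) - 1) > 1e-9:
            raise ValueError("parity_probs must sum to 1")
        if self.return_time_median <= self.nadir_time_median:
            raise ValueError("return_time_median must exceed nadir_time_median")
        if self.return_time_median >= self.followup_window_days:
            raise ValueError("return_time_median must lie inside the follow-up window")
        G = np.asarray(self.lmm_G, dtype=float)
        if G.shape != (2, 2) or not np.allclose(G, G.T):
            raise ValueError("lmm_G must be a symmetric 2x2 matrix")
        if np.linalg.eigvalsh(G)[0] < -1e-8:
            raise ValueError("lmm_G must be positive semi-definite")
        return self

    # -- derived regain-interval distribution ------------------------------
    def regain_lognormal_params(self) -> tuple[float, float]:
        """(mu, sigma) of the log-normal regain interval Δ = return − nadir.

        Solved so that, with the nadir at its median time, P(nadir+Δ > window)
        equals ``never_return_frac`` and the median of Δ among returners maps
        the median return time onto ``return_time_median``.
        """
        med = self.return_time_median - self.nadir_time_median
        q = self.never_return_frac
        if q <= 0.0 or q >= 1.0:
            return float(np.log(med)), 0.5
        hi = self.followup_window_days - self.nadir_time_median
        z_hi = norm.ppf(1.0 - q)
        z_med = norm.ppf((1.0 - q) / 2.0)
        sigma = float(np.log(hi / med) / (z_hi - z_med))
        mu = float(np.log(med) - z_med * sigma)
        return mu, sigma

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["education_probs"] = list(self.education_probs)
        d["parity_probs"] = list(self.parity_probs)
        d["lmm_G"] = [list(r) for r in self.lmm_G]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_dict(cls, raw: dict) -> "SimConfig":
        raw = dict(raw)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("education_probs", "parity_probs"):
            if key in raw:
                raw[key] = tuple(raw[key])
        if "lmm_G" in raw:
            raw["lmm_G"] = tuple(tuple(r) for r in raw["lmm_G"])
        return cls(**raw).validate()

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})


@dataclass
class SimulatedCohort:
    """Observable table plus hidden-truth sidecar (same ``baby_id`` key)."""

    observed: pd.DataFrame
    truth: pd.DataFrame
    kind: str  # 'training' | 'application' | 'training_lmm'

    def save(self, out_dir, prefix: str | None = None) -> tuple[Path, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        prefix = prefix or self.kind
        obs = out_dir / f"{prefix}_observed.tsv"
        tru = out_dir / f"{prefix}_truth.tsv"
        self.observed.to_csv(obs, sep="\t", index=False)
        self.truth.to_csv(tru, sep="\t", index=False)
        return obs, tru

    @classmethod
    def load(cls, out_dir, kind: str, prefix: str | None = None) -> "SimulatedCohort":
        out_dir = Path(out_dir)
        prefix = prefix or kind
        observed = pd.read_csv(out_dir / f"{prefix}_observed.tsv", sep="\t")
        truth = pd.read_csv(out_dir / f"{prefix}_truth.tsv", sep="\t")
        return cls(observed=observed, truth=truth, kind=kind)


# ---------------------------------------------------------------------------
# sampling helpers


def _trunc_normal(rng, mean, sd, lo, hi, size):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def _trunc_lognormal_below(rng, median, log_sd, upper, size):
    """Log-normal draws conditioned on being <= upper (inverse-CDF)."""
    mu = np.log(median)
    p_hi = norm.cdf((np.log(upper) - mu) / log_sd)
    u = rng.uniform(0.0, p_hi, size=size)
    return np.exp(mu + log_sd * norm.ppf(u))


def _sample_education(rng, cfg: SimConfig, n):
    group = rng.choice(3, size=n, p=np.asarray(cfg.education_probs))
    years = np.zeros(n)
    years[group == 1] = rng.integers(1, 6, size=(group == 1).sum())
    years[group == 2] = rng.integers(6, 13, size=(group == 2).sum())
    return years


def _sample_parity(rng, cfg: SimConfig, n):
    parity = rng.choice(5, size=n, p=np.asarray(cfg.parity_probs)).astype(float)
    many = parity == 4
    parity[many] = 4 + rng.poisson(1.0, size=many.sum())
    return parity


def _sample_trajectories(rng, cfg: SimConfig, n):
    nadir_time = np.exp(
        rng.normal(np.log(cfg.nadir_time_median), cfg.nadir_time_log_sd, size=n)
    )
    if cfg.nadir_frac_median <= 0.0:
        nadir_frac = np.zeros(n)
    else:
        logit_med = np.log(cfg.nadir_frac_median / (1.0 - cfg.nadir_frac_median))
        logit = rng.normal(logit_med, cfg.nadir_frac_logit_sd, size=n)
        nadir_frac = 1.0 / (1.0 + np.exp(-logit))
    mu, sigma = cfg.regain_lognormal_params()
    regain = np.exp(rng.normal(mu, sigma, size=n))
    return nadir_time, nadir_frac, nadir_time + regain


def _birth_weight_mean(cfg: SimConfig, male, ga, first_birth, mat_age, edu,
                       multiple=None, died=None):
    mean = (
        cfg.bw_intercept
        + cfg.bw_male * male
        + cfg.bw_first_birth * first_birth
        + cfg.bw_ga_slope_below40 * np.minimum(ga - 40.0, 0.0)
        + cfg.bw_ga_slope_above40 * np.maximum(ga - 40.0, 0.0)
        + cfg.bw_maternal_age * (mat_age - cfg.maternal_age_center)
        + cfg.bw_education * (edu - cfg.education_center)
    )
    if multiple is not None:
        mean = mean + cfg.bw_multiple * multiple
    if died is not None:
        mean = mean + cfg.bw_death * died
    return mean


def _truth_categories(truth: pd.DataFrame, observed_sex, ga, standard):
    cat, severe = classify_size_for_ga(
        truth["birth_weight"].to_numpy(), ga, observed_sex, standard
    )
    lbw, vlbw = classify_lbw(truth["birth_weight"].to_numpy())
    truth["true_size_category"] = cat
    truth["true_severe_sga"] = severe
    truth["true_lbw"] = lbw
    truth["true_vlbw"] = vlbw
    return truth


# ---------------------------------------------------------------------------
# public generators


def simulate_training_cohort(
    config: SimConfig, seed: int | None = None, standard=None
) -> SimulatedCohort:
    """Longitudinal training cohort: daily weights on days 0..10.

    The day-0 weight is measured within ``day0_max_h`` hours of delivery;
    later visits fall exactly on integer days.  Multiples and neonatal deaths
    are excluded (the training sub-study followed surviving singletons only).
    Returns one observed row per baby-visit and a per-baby truth sidecar.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    standard = standard or synthetic_standard()
    n = cfg.n_babies_training

    male = (rng.uniform(size=n) < cfg.male_frac_training).astype(float)
    ga = _trunc_normal(rng, cfg.ga_mean_training, cfg.ga_sd_training,
                       cfg.ga_min, cfg.ga_max, n)
    parity = _sample_parity(rng, cfg, n)
    first_birth = (parity == 0).astype(float)
    mat_age = _trunc_normal(rng, cfg.maternal_age_mean, cfg.maternal_age_sd,
                            cfg.maternal_age_min, cfg.maternal_age_max, n)
    edu = _sample_education(rng, cfg, n)

    bw_mean = _birth_weight_mean(cfg, male, ga, first_birth, mat_age, edu)
    bw = np.maximum(bw_mean + rng.normal(0.0, cfg.bw_resid_sd, size=n), cfg.bw_floor)
    nadir_time, nadir_frac, return_time = _sample_trajectories(rng, cfg, n)

    day0_t = _trunc_lognormal_below(
        rng, cfg.day0_time_median_h, cfg.day0_time_log_sd, cfg.day0_max_h, n
    ) / 24.0
    days = np.arange(0, int(cfg.followup_window_days) + 1)
    t = np.tile(days.astype(float), (n, 1))
    t[:, 0] = day0_t

    w_true = trajectory_weight(
        t,
        bw[:, None],
        nadir_time[:, None],
        nadir_frac[:, None],
        return_time[:, None],
        cfg.postnatal_growth_rate,
    )
    w_obs = w_true + rng.normal(0.0, cfg.noise_sd, size=w_true.shape)

    baby_id = np.arange(n)
    sex = np.where(male == 1, "male", "female")
    observed = pd.DataFrame(
        {
            "baby_id": np.repeat(baby_id, len(days)),
            "visit_day": np.tile(days, n),
            "t_days": t.ravel(),
            "weight": w_obs.ravel(),
            "sex": np.repeat(sex, len(days)),
            "ga_weeks": np.repeat(ga, len(days)),
            "parity": np.repeat(parity, len(days)),
            "first_birth": np.repeat(first_birth, len(days)),
            "mat_age": np.repeat(mat_age, len(days)),
            "mat_edu": np.repeat(edu, len(days)),
        }
    )
    truth = pd.DataFrame(
        {
            "baby_id": baby_id,
            "birth_weight": bw,
            "nadir_time": nadir_time,
            "nadir_frac": nadir_frac,
            "nadir_weight": bw * (1.0 - nadir_frac),
            "return_time": return_time,
            "never_returns_in_window": return_time > cfg.followup_window_days,
        }
    )
    truth = _truth_categories(truth, sex, ga, standard)
    return SimulatedCohort(observed=observed, truth=truth, kind="training")


def simulate_lmm_training_cohort(
    config: SimConfig, seed: int | None = None
) -> SimulatedCohort:
    """Training cohort generated exactly from the linear mixed model.

    ``weight = Xβ + u0 + u1·t + e`` with ``(u0, u1) ~ N(0, lmm_G)`` and
    ``e ~ N(0, lmm_sigma²)``; covariates and visit times as in
    :func:`simulate_training_cohort`.  Used for variance-component and
    fixed-effect recovery studies, where the fitted model is correctly
    specified by construction.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = cfg.n_babies_training

    male = (rng.uniform(size=n) < cfg.male_frac_training).astype(float)
    ga = _trunc_normal(rng, cfg.ga_mean_training, cfg.ga_sd_training,
                       cfg.ga_min, cfg.ga_max, n)
    parity = _sample_parity(rng, cfg, n)
    first_birth = (parity == 0).astype(float)
    mat_age = _trunc_normal(rng, cfg.maternal_age_mean, cfg.maternal_age_sd,
                            cfg.maternal_age_min, cfg.maternal_age_max, n)
    edu = _sample_education(rng, cfg, n)

    mean_i = _birth_weight_mean(cfg, male, ga, first_birth, mat_age, edu)
    G = np.asarray(cfg.lmm_G, dtype=float)
    u = rng.multivariate_normal(np.zeros(2), G, size=n)  # svd handles PSD G

    day0_t = _trunc_lognormal_below(
        rng, cfg.day0_time_median_h, cfg.day0_time_log_sd, cfg.day0_max_h, n
    ) / 24.0
    days = np.arange(0, int(cfg.followup_window_days) + 1)
    t = np.tile(days.astype(float), (n, 1))
    t[:, 0] = day0_t

    w = (
        mean_i[:, None]
        + u[:, [0]]
        + u[:, [1]] * t
        + rng.normal(0.0, cfg.lmm_sigma, size=t.shape)
    )
    baby_id = np.arange(n)
    sex = np.where(male == 1, "male", "female")
    observed = pd.DataFrame(
        {
            "baby_id": np.repeat(baby_id, len(days)),
            "visit_day": np.tile(days, n),
            "t_days": t.ravel(),
            "weight": w.ravel(),
            "sex": np.repeat(sex, len(days)),
            "ga_weeks": np.repeat(ga, len(days)),
            "parity": np.repeat(parity, len(days)),
            "first_birth": np.repeat(first_birth, len(days)),
            "mat_age": np.repeat(mat_age, len(days)),
            "mat_edu": np.repeat(edu, len(days)),
        }
    )
    truth = pd.DataFrame(
        {
            "baby_id": baby_id,
            "mean_weight": mean_i,
            "u0": u[:, 0],
            "u1": u[:, 1],
        }
    )
    return SimulatedCohort(observed=observed, truth=truth, kind="training_lmm")


def simulate_application_cohort(
    config: SimConfig, seed: int | None = None, standard=None
) -> SimulatedCohort:
    """Application cohort: one row per live birth, at most one weight.

    Women may contribute multiple births (``woman_id``); multiples and
    neonatal deaths are present.  The probability that the weight is missing
    follows a logistic model in survival status, preterm birth, nulliparity
    and maternal education, so missingness is conditionally independent of
    the weight given covariates (MNAR behaviour downstream arises from the
    covariate–weight correlation).  A small fraction of covariate values are
    also missing, independently.
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    standard = standard or synthetic_standard()
    n = cfg.n_births_application

    # women: each contributes 1 + Poisson(extra) births
    sizes = 1 + rng.poisson(cfg.births_per_woman_extra, size=n)
    cum = np.cumsum(sizes)
    n_women = int(np.searchsorted(cum, n) + 1)
    woman_id = np.repeat(np.arange(n_women), sizes[:n_women])[:n]

    male = (rng.uniform(size=n) < cfg.male_frac_application).astype(float)
    ga = _trunc_normal(rng, cfg.ga_mean_application, cfg.ga_sd_application,
                       cfg.ga_min, cfg.ga_max, n)
    preterm = (ga < 37.0).astype(float)
    parity = _sample_parity(rng, cfg, n)
    first_birth = (parity == 0).astype(float)
    mat_age = _trunc_normal(rng, cfg.maternal_age_mean, cfg.maternal_age_sd,
                            cfg.maternal_age_min, cfg.maternal_age_max, n)
    edu = _sample_education(rng, cfg, n)
    multiple = (rng.uniform(size=n) < cfg.multiples_frac).astype(float)

    u_surv = rng.uniform(size=n)
    died = (u_surv < cfg.death_frac).astype(float)
    lost = ((u_surv >= cfg.death_frac)
            & (u_surv < cfg.death_frac + cfg.ltfu_frac)).astype(float)
    survival = np.where(died == 1, "dead", np.where(lost == 1, "lost", "alive"))
    death_day = np.full(n, np.nan)
    ndead = int(died.sum())
    if ndead:
        death_day[died == 1] = np.minimum(rng.exponential(cfg.death_day_mean, ndead), 28.0)

    bw_mean = _birth_weight_mean(cfg, male, ga, first_birth, mat_age, edu,
                                 multiple=multiple, died=died)
    bw = np.maximum(bw_mean + rng.normal(0.0, cfg.bw_resid_sd, size=n), cfg.bw_floor)
    nadir_time, nadir_frac, return_time = _sample_trajectories(rng, cfg, n)

    facility = (rng.uniform(size=n) < cfg.facility_frac).astype(float)
    log_t = np.where(
        facility == 1,
        rng.normal(np.log(cfg.visit_time_facility_median_h),
                   cfg.visit_time_facility_log_sd, size=n),
        rng.normal(np.log(cfg.visit_time_home_median_h),
                   cfg.visit_time_home_log_sd, size=n),
    )
    t_hours = np.exp(log_t)

    w_true = trajectory_weight(
        t_hours / 24.0, bw, nadir_time, nadir_frac, return_time,
        cfg.postnatal_growth_rate,
    )
    w_obs = w_true + rng.normal(0.0, cfg.noise_sd, size=n)

    # missing-weight mechanism: logistic in covariates and survival only
    lin = (
        cfg.miss_intercept
        + cfg.miss_death * died
        + cfg.miss_preterm * preterm
        + cfg.miss_nulliparous * first_birth
        + cfg.miss_education * edu
    )
    from scipy.special import expit

    p_miss = expit(lin)
    missing_weight = rng.uniform(size=n) < p_miss
    weight = np.where(missing_weight, np.nan, w_obs)
    t_hours_obs = np.where(missing_weight, np.nan, t_hours)

    sex = np.where(male == 1, "male", "female").astype(object)
    sex[rng.uniform(size=n) < cfg.miss_sex_frac] = None
    parity_obs = parity.copy()
    parity_obs[rng.uniform(size=n) < cfg.miss_parity_frac] = np.nan
    survival_obs = survival.astype(object)
    survival_obs[rng.uniform(size=n) < cfg.miss_survival_frac] = None
    edu_obs = edu.copy()
    edu_obs[rng.uniform(size=n) < cfg.miss_edu_frac] = np.nan

    baby_id = np.arange(n)
    observed = pd.DataFrame(
        {
            "baby_id": baby_id,
            "woman_id": woman_id,
            "sex": sex,
            "ga_weeks": ga,
            "preterm": preterm,
            "parity": parity_obs,
            "first_birth": np.where(np.isnan(parity_obs), np.nan, parity_obs == 0),
            "mat_age": mat_age,
            "mat_edu": edu_obs,
            "multiple": multiple,
            "survival": survival_obs,
            "facility": facility,
            "t_hours": t_hours_obs,
            "weight": weight,
        }
    )
    truth = pd.DataFrame(
        {
            "baby_id": baby_id,
            "birth_weight": bw,
            "nadir_time": nadir_time,
            "nadir_frac": nadir_frac,
            "nadir_weight": bw * (1.0 - nadir_frac),
            "return_time": return_time,
            "visit_t_hours": t_hours,
            "death_day": death_day,
            "p_missing": p_miss,
            "missing_weight": missing_weight,
        }
    )
    sex_true = np.where(male == 1, "male", "female")
    truth = _truth_categories(truth, sex_true, ga, standard)
    return SimulatedCohort(observed=observed, truth=truth, kind="application")
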