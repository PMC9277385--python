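"""Longitudinal model of early-neonatal weight and trajectory analytics.

Fits a linear mixed-effects model to repeated daily weights from the
training cohort — fixed effects for parity, maternal education and age,
infant sex and gestational age (linear spline with a knot at 40 weeks);
per-baby random intercept and random slope in days since delivery — and
exposes the variance components (the 2×2 random-effects covariance ``G``
and the residual variance ``σ²``) for transfer to the recalibration stage.

Descriptive trajectory analytics operate on a per-baby weight curve
extended from delivery (t = 0) to the last observed time on a dense grid:
the time and weight at the nadir (the grid argmin, ties broken earliest),
the first time after the nadir at which the curve regains the delivery
weight (censored at the window end if it never does), and the
product-limit (Kaplan–Meier) curve of the probability of not yet having
returned to birth weight.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline
from sklearn.base import BaseEstimator

import statsmodels.formula.api as smf
from lifelines import KaplanMeierFitter

logger = logging.getLogger(__name__)


def fit_mixedlm_robust(model, reml: bool, maxiter: int = 500):
    """Fit a MixedLM trying a sequence of optimizers.

    Profiled-likelihood surfaces with weakly identified variance components
    make gradient methods fragile; fall back to derivative-free optimizers
    before giving up.  Raises RuntimeError with the optimizer message if no
    method converges.
    """
    last_message = "no optimizer attempted"
    for method in ("lbfgs", "powell", "nm"):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                result = model.fit(reml=reml, method=method, maxiter=maxiter)
        except (np.linalg.LinAlgError, ValueError) as exc:
            last_message = f"{method}: {exc}"
            continue
        if result.converged:
            return result
        last_message = f"{method}: {getattr(result, 'convergence_message', 'did not converge')}"
    raise RuntimeError(f"mixed-model fit did not converge ({last_message})")

__all__ = [
    "MixedModelSpec",
    "NeonatalGrowthModel",
    "fit_longitudinal_model",
    "baby_trajectory",
    "find_nadir",
    "find_return_time",
    "km_return_curve",
    "summarize_growth",
    "TrajectorySummary",
    "ReturnTime",
]

#: Default grid resolution (days) for nadir / return-time searches:
#: ~15-minute precision, far below the inter-quartile ranges of interest.
GRID_RESOLUTION = 0.01


@dataclass
class MixedModelSpec:
    """Fixed/random-effect layout of the training model.

    The gestational-age spline knot is fixed at 40 weeks; time is measured
    in days since delivery and is non-negative.
    """

    fixed_effects: tuple = (
        "first_birth",
        "mat_edu",
        "mat_age",
        "male",
        "ga_below40",
        "ga_above40",
    )
    knot_weeks: float = 40.0
    reml: bool = True

    def formula(self) -> str:
        return "weight ~ " + " + ".join(self.fixed_effects)


def _prepare_training_frame(df: pd.DataFrame, spec: MixedModelSpec) -> pd.DataFrame:
    out = df.copy()
    if "male" not in out.columns and "sex" in out.columns:
        out["male"] = (out["sex"] == "male").astype(float)
    out["ga_below40"] = np.minimum(out["ga_weeks"] - spec.knot_weeks, 0.0)
    out["ga_above40"] = np.maximum(out["ga_weeks"] - spec.knot_weeks, 0.0)
    if (out["t_days"] < 0).any():
        raise ValueError("t_days must be non-negative")
    return out


class NeonatalGrowthModel(BaseEstimator):
    """Random-intercept + random-slope mixed model of repeated weights.

    Parameters
    ----------
    spec : MixedModelSpec, optional
        Fixed-effect layout and estimation method (REML by default).

    Attributes
    ----------
    beta_ : pandas.Series
        Fixed-effect coefficients (grams per unit covariate).
    G_ : ndarray, shape (2, 2)
        Covariance of the per-baby (intercept, slope) random effects;
        units g², g²/day, g²/day².
    sigma2_ : float
        Residual variance σ² (g²).
    random_effects_ : pandas.DataFrame
        Predicted (BLUP) per-baby ``u0`` (g) and ``u1`` (g/day), indexed by
        baby id.
    singular_ : bool
        True when the estimated G is (near-)singular; reported, not hidden.
    """

    def __init__(self, spec: MixedModelSpec | None = None):
        self.spec = spec

    def fit(self, cohort: pd.DataFrame) -> "NeonatalGrowthModel":
        spec = self.spec or MixedModelSpec()
        required = {"baby_id", "t_days", "weight"}
        missing_cols = required - set(cohort.columns)
        if missing_cols:
            raise ValueError(f"cohort missing columns: {sorted(missing_cols)}")
        data = _prepare_training_frame(cohort, spec)
        model_cols = ["weight", "t_days", "baby_id", *spec.fixed_effects]
        complete = data[model_cols].notna().all(axis=1)
        n_dropped = int((~complete).sum())
        if n_dropped:
            logger.info("dropping %d rows with missing covariates", n_dropped)
        self.n_dropped_ = n_dropped
        data = data.loc[complete]
        counts = data.groupby("baby_id").size()
        if (counts < 2).any():
            raise ValueError(
                "every baby needs >=2 observations to identify a slope; "
                f"{int((counts < 2).sum())} babies have fewer"
            )

        if float(np.var(data["weight"])) < 1e-10:
            # exactly constant response: variance components are all zero and
            # the likelihood surface is singular; report the degenerate fit
            # directly instead of letting the optimizer fail
            return self._fit_degenerate(data, spec)

        model = smf.mixedlm(
            spec.formula(), data, groups=data["baby_id"], re_formula="~t_days"
        )
        result = fit_mixedlm_robust(model, reml=spec.reml)

        self.spec_ = spec
        self.result_ = result
        self.beta_ = result.fe_params
        self.G_ = np.asarray(result.cov_re)
        self.sigma2_ = float(result.scale)
        re = pd.DataFrame(result.random_effects).T
        re.columns = ["u0", "u1"]
        re.index.name = "baby_id"
        self.random_effects_ = re
        self.n_babies_ = int(data["baby_id"].nunique())
        self.n_obs_ = int(len(data))
        self.n_dropped_ = n_dropped
        self.loglik_ = float(result.llf)
        self.aic_ = float(result.aic) if np.isfinite(result.aic) else np.nan
        eig = np.linalg.eigvalsh(self.G_)
        self.singular_ = bool(eig[0] < 1e-6 * max(eig[-1], 1.0))
        if self.singular_:
            logger.warning("random-effects covariance G is near-singular")
        self._baby_covariates = (
            data.drop_duplicates("baby_id").set_index("baby_id", drop=False)
            .drop(columns=["weight"])
        )
        return self

    def _fit_degenerate(self, data, spec) -> "NeonatalGrowthModel":
        const = float(data["weight"].iloc[0])
        logger.warning("response is exactly constant; degenerate singular fit")
        self.spec_ = spec
        self.result_ = None
        self.beta_ = pd.Series(
            {"Intercept": const, **{c: 0.0 for c in spec.fixed_effects}}
        )
        self.G_ = np.zeros((2, 2))
        self.sigma2_ = 0.0
        ids = data["baby_id"].unique()
        self.random_effects_ = pd.DataFrame(
            0.0, index=pd.Index(ids, name="baby_id"), columns=["u0", "u1"]
        )
        self.n_babies_ = int(len(ids))
        self.n_obs_ = int(len(data))
        self.n_dropped_ = getattr(self, "n_dropped_", 0)
        self.loglik_ = np.nan
        self.aic_ = np.nan
        self.singular_ = True
        self._baby_covariates = (
            data.drop_duplicates("baby_id").set_index("baby_id", drop=False)
            .drop(columns=["weight"])
        )
        self._constant = const
        return self

    def _check_fitted(self):
        if not hasattr(self, "beta_"):
            raise RuntimeError("model is not fitted")

    def predict_trajectory(self, baby_id, t_grid) -> np.ndarray:
        """Predicted weight(t) = fixed part + u0 + u1·t on ``t_grid`` (days)."""
        self._check_fitted()
        if baby_id not in self.random_effects_.index:
            raise KeyError(f"unknown baby id: {baby_id!r}")
        t = np.asarray(t_grid, dtype=float)
        if self.result_ is None:  # degenerate constant fit
            fixed = self._constant
        else:
            row = self._baby_covariates.loc[[baby_id]]
            fixed = float(self.result_.predict(exog=row).iloc[0])
        u0, u1 = self.random_effects_.loc[baby_id]
        return fixed + u0 + u1 * t

    def variance_components(self) -> dict:
        """G and σ² in a plain-dict transfer format."""
        self._check_fitted()
        return {
            "G11": float(self.G_[0, 0]),
            "G12": float(self.G_[0, 1]),
            "G22": float(self.G_[1, 1]),
            "sigma2": self.sigma2_,
            "singular": self.singular_,
        }

    def summary_dict(self) -> dict:
        self._check_fitted()
        return {
            "beta": {k: float(v) for k, v in self.beta_.items()},
            **self.variance_components(),
            "n_babies": self.n_babies_,
            "n_obs": self.n_obs_,
            "n_dropped_rows": self.n_dropped_,
            "loglik": self.loglik_,
            "aic": self.aic_,
        }


def fit_longitudinal_model(
    cohort: pd.DataFrame, spec: MixedModelSpec | None = None
) -> NeonatalGrowthModel:
    """Fit the training mixed model; see :class:`NeonatalGrowthModel`."""
    return NeonatalGrowthModel(spec=spec).fit(cohort)


# ---------------------------------------------------------------------------
# trajectory analytics


class ReturnTime(NamedTuple):
    time: float
    censored: bool
    closest_gap: float  # min |weight - birth_weight| after the nadir (grams)


def baby_trajectory(
    t_obs,
    w_obs,
    t_max: float = 10.0,
    resolution: float = GRID_RESOLUTION,
) -> tuple[np.ndarray, np.ndarray]:
    """Extend one baby's observed weights to a dense curve from delivery.

    A natural cubic spline through the (time, weight) observations is
    evaluated on a grid from t = 0 to the last observed time (capped at
    ``t_max`` days); the short extrapolation from the first measurement
    (taken within hours of delivery) back to t = 0 uses the spline's end
    segment.  Returns ``(grid, weights)``.
    """
    t_obs = np.asarray(t_obs, dtype=float)
    w_obs = np.asarray(w_obs, dtype=float)
    order = np.argsort(t_obs)
    t_obs, w_obs = t_obs[order], w_obs[order]
    if len(t_obs) < 2:
        raise ValueError("need at least two observations to build a trajectory")
    hi = min(float(t_obs[-1]), t_max)
    grid = np.arange(0.0, hi + resolution / 2, resolution)
    spline = CubicSpline(t_obs, w_obs, bc_type="natural")
    return grid, spline(grid)


def find_nadir(times, weights) -> tuple[float, float]:
    """Grid argmin of the trajectory; ties broken by the earliest time."""
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if times.size == 0:
        raise ValueError("empty trajectory grid")
    i = int(np.argmin(weights))  # np.argmin returns the first minimum
    return float(times[i]), float(weights[i])


def find_return_time(times, weights, birth_weight: float) -> ReturnTime:
    """First time at/after the nadir when the curve regains birth weight.

    If the curve never reaches ``birth_weight`` after its nadir within the
    grid, the event is censored at the last grid time.  The closest approach
    to birth weight after the nadir is reported alongside either way.
    """
    times = np.asarray(times, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if times.size == 0:
        raise ValueError("empty trajectory grid")
    nadir_t, _ = find_nadir(times, weights)
    after = times >= nadir_t
    t_a, w_a = times[after], weights[after]
    gap = np.abs(w_a - birth_weight)
    reached = w_a >= birth_weight
    if reached.any():
        j = int(np.argmax(reached))
        return ReturnTime(time=float(t_a[j]), censored=False,
                          closest_gap=float(gap.min()))
    return ReturnTime(time=float(times[-1]), censored=True,
                      closest_gap=float(gap.min()))


def km_return_curve(return_times, censored_flags, alpha: float = 0.05) -> pd.DataFrame:
    """Kaplan–Meier curve of P(not yet returned to birth weight).

    Censored babies contribute risk time up to their censoring day.
    Returns a step-function table with columns ``time``, ``estimate``,
    ``lower``, ``upper`` (pointwise CI, lifelines' log-log default).
    """
    times = np.asarray(return_times, dtype=float)
    censored = np.asarray(censored_flags, dtype=bool)
    if times.size == 0:
        raise ValueError("no return times supplied")
    if np.any(times < 0):
        raise ValueError("return times must be non-negative")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(times, event_observed=~censored)
    est = kmf.survival_function_
    ci = kmf.confidence_interval_
    out = pd.DataFrame(
        {
            "time": est.index.to_numpy(dtype=float),
            "estimate": est.iloc[:, 0].to_numpy(),
            "lower": ci.iloc[:, 0].to_numpy(),
            "upper": ci.iloc[:, 1].to_numpy(),
        }
    )
    return out.reset_index(drop=True)


@dataclass
class TrajectorySummary:
    """Per-baby trajectory statistics and cohort-level medians/IQRs."""

    per_baby: pd.DataFrame
    medians: dict = field(default_factory=dict)
    n_not_returned: int = 0
    n_babies: int = 0

    def table(self) -> pd.DataFrame:
        rows = []
        for name, (med, lo, hi) in self.medians.items():
            rows.append({"quantity": name, "median": med, "q1": lo, "q3": hi})
        rows.append(
            {
                "quantity": "n_not_returned_within_window",
                "median": self.n_not_returned,
                "q1": np.nan,
                "q3": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _median_iqr(x) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return (np.nan, np.nan, np.nan)
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return (float(med), float(q1), float(q3))


def summarize_growth(
    cohort: pd.DataFrame,
    t_max: float = 10.0,
    resolution: float = GRID_RESOLUTION,
) -> TrajectorySummary:
    """Cohort growth summary: birth weight, nadir, return to birth weight.

    For each baby the observed weights are extended to a dense curve with
    :func:`baby_trajectory`; the birth weight is the curve's value at
    delivery (t = 0), the nadir is the curve minimum, and the return time is
    the first post-nadir time the curve regains the delivery weight
    (censored at the window end otherwise).  Medians and IQRs are reported
    across babies; the relative loss at nadir is (birth − nadir)/birth.
    """
    records = []
    for baby_id, sub in cohort.groupby("baby_id"):
        grid, w = baby_trajectory(
            sub["t_days"].to_numpy(), sub["weight"].to_numpy(),
            t_max=t_max, resolution=resolution,
        )
        bw = float(w[0])
        nadir_t, nadir_w = find_nadir(grid, w)
        ret = find_return_time(grid, w, bw)
        records.append(
            {
                "baby_id": baby_id,
                "birth_weight": bw,
                "first_observed_weight": float(sub.sort_values("t_days")["weight"].iloc[0]),
                "nadir_time": nadir_t,
                "nadir_weight": nadir_w,
                "relative_loss": (bw - nadir_w) / bw if bw > 0 else np.nan,
                "return_time": ret.time,
                "censored": ret.censored,
                "closest_gap": ret.closest_gap,
            }
        )
    per_baby = pd.DataFrame(records)
    returned = per_baby.loc[~per_baby["censored"], "return_time"]
    medians = {
        "birth_weight_g": _median_iqr(per_baby["birth_weight"]),
        "nadir_weight_g": _median_iqr(per_baby["nadir_weight"]),
        "nadir_time_days": _median_iqr(per_baby["nadir_time"]),
        "return_time_days": _median_iqr(returned),
        "relative_loss": _median_iqr(per_baby["relative_loss"]),
    }
    return TrajectorySummary(
        per_baby=per_baby,
        medians=medians,
        n_not_returned=int(per_baby["censored"].sum()),
        n_babies=int(len(per_baby)),
    )
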