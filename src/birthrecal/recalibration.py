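"""Empirical-Bayes recalibration of a single postnatal weight to birth weight.

The application cohort records at most one weight per live birth, at a known
postnatal age t.  A population model fitted to those observed weights gives
every birth two predictions: ``w_hat_it`` at its own measurement time and
``w_hat_i0`` with the age terms set to zero (weight at delivery).  The
variance components estimated in the longitudinal training cohort — the 2×2
random-effects covariance ``G`` (intercept/slope, units g², g²/day, g²/day²)
and the residual variance ``σ²`` — are transferred, and the empirical Bayes
estimate of the birth weight shrinks the individual deviation from the
population curve:

    v_i      = G11 + G12 · t_i                      (g²)
    λ_i      = v_i / (v_i + σ²)                     (shrinkage factor)
    w̃_i0     = ŵ_i0 + λ_i · (w_it − ŵ_it)          (grams)
    Var(w̃_i0) = (G11 + σ²) − v_i² / (v_i + σ²)     (g²)

``v_i`` is Cov(b0, b0 + b1·t), the covariance between the random part of the
birth weight and the random part of the observed weight.  Note the shrinkage
denominator uses v + σ², not the full marginal variance of the observed
weight (G11 + 2·G12·t + G22·t² + σ²); :func:`oracle_conditional_normal`
implements the exact bivariate-normal conditioning for comparison.  The two
coincide exactly when t = 0 or when G12 = G22 = 0.

Multiple predictive draws from N(w̃_i0, Var(w̃_i0)) provide the imputation
datasets consumed by the reporting stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

import statsmodels.formula.api as smf

from .growth import fit_mixedlm_robust

logger = logging.getLogger(__name__)

__all__ = [
    "ApplicationModelSpec",
    "ApplicationWeightModel",
    "fit_application_model",
    "eb_recalibrate",
    "oracle_conditional_normal",
    "draw_imputations",
    "EmpiricalBayesRecalibrator",
    "RecalibratedWeight",
]

#: Imputed/recalibrated draws are truncated below at this floor (grams).
WEIGHT_FLOOR = 300.0


def _check_G(G) -> np.ndarray:
    G = np.asarray(G, dtype=float)
    if G.shape != (2, 2):
        raise ValueError("G must be 2x2")
    if not np.allclose(G, G.T, atol=1e-8):
        raise ValueError("G must be symmetric")
    if np.linalg.eigvalsh(G)[0] < -1e-8 * max(1.0, abs(G).max()):
        raise ValueError("G must be positive semi-definite")
    return G


@dataclass
class RecalibratedWeight:
    """Per-birth recalibration quantities (arrays aligned by record)."""

    w_it: np.ndarray        # measured weight (g)
    t_days: np.ndarray      # age at measurement (days)
    w_hat_it: np.ndarray    # model prediction at measurement time (g)
    w_hat_i0: np.ndarray    # model prediction at delivery (g)
    v: np.ndarray           # covariance term G11 + G12*t (g^2)
    lam: np.ndarray         # shrinkage factor v/(v+sigma2) in [0, 1]
    w_tilde_i0: np.ndarray  # empirical Bayes birth-weight estimate (g)
    var_i0: np.ndarray      # its variance (g^2)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t_days": self.t_days,
                "w_it": self.w_it,
                "w_hat_it": self.w_hat_it,
                "w_hat_i0": self.w_hat_i0,
                "v": self.v,
                "lambda": self.lam,
                "w_tilde_i0": self.w_tilde_i0,
                "var_i0": self.var_i0,
            }
        )


def eb_recalibrate(w_it, t_days, w_hat_it, w_hat_i0, G, sigma2) -> RecalibratedWeight:
    """Empirical Bayes birth-weight estimate from one weight at age t (days).

    Negative ``v`` (possible for large t when G12 < 0) clamps the shrinkage
    factor to 0 with a logged warning: the estimate degrades gracefully to
    the covariate-only prediction ``w_hat_i0`` with variance G11 + σ².
    """
    G = _check_G(G)
    sigma2 = float(sigma2)
    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    w_it = np.asarray(w_it, dtype=float)
    t = np.asarray(t_days, dtype=float)
    w_hat_it = np.asarray(w_hat_it, dtype=float)
    w_hat_i0 = np.asarray(w_hat_i0, dtype=float)
    w_it, t, w_hat_it, w_hat_i0 = np.broadcast_arrays(w_it, t, w_hat_it, w_hat_i0)

    v = G[0, 0] + G[0, 1] * t
    n_neg = int(np.sum(v < 0))
    if n_neg:
        logger.warning(
            "clamping shrinkage to 0 for %d records with negative v "
            "(G12 < 0 at large measurement age)", n_neg,
        )
    v_eff = np.maximum(v, 0.0)
    denom = v_eff + sigma2
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(denom > 0, v_eff / np.where(denom > 0, denom, 1.0), 0.0)
    w_tilde = w_hat_i0 + lam * (w_it - w_hat_it)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (G[0, 0] + sigma2) - np.where(
            denom > 0, v_eff**2 / np.where(denom > 0, denom, 1.0), 0.0
        )
    var = np.maximum(var, 0.0)
    return RecalibratedWeight(
        w_it=w_it, t_days=t, w_hat_it=w_hat_it, w_hat_i0=w_hat_i0,
        v=v, lam=lam, w_tilde_i0=w_tilde, var_i0=var,
    )


def oracle_conditional_normal(w_it, t_days, w_hat_it, w_hat_i0, G, sigma2):
    """Exact conditional mean/variance of weight(0) given weight(t).

    Under the random-intercept + random-slope model the pair
    (weight(0) − ŵ_0, weight(t) − ŵ_t) is bivariate normal with
    Cov = G11 + G12·t and Var(weight(t)) = G11 + 2·G12·t + G22·t² + σ²;
    conditioning gives

        mean = ŵ_0 + Cov/Var_t · (w_t − ŵ_t)
        var  = (G11 + σ²) − Cov²/Var_t.

    Serves as the independent check on :func:`eb_recalibrate`; the two agree
    exactly when t = 0 or G12 = G22 = 0.
    """
    G = _check_G(G)
    sigma2 = float(sigma2)
    w_it = np.asarray(w_it, dtype=float)
    t = np.asarray(t_days, dtype=float)
    w_hat_it = np.asarray(w_hat_it, dtype=float)
    w_hat_i0 = np.asarray(w_hat_i0, dtype=float)
    cov = G[0, 0] + G[0, 1] * t
    var_t = G[0, 0] + 2.0 * G[0, 1] * t + G[1, 1] * t**2 + sigma2
    if np.any(var_t <= 0):
        raise ValueError("marginal variance of the observed weight must be positive")
    mean = w_hat_i0 + cov / var_t * (w_it - w_hat_it)
    var = (G[0, 0] + sigma2) - cov**2 / var_t
    return mean, var


def draw_imputations(
    mean, var, m: int, seed=None, floor: float = WEIGHT_FLOOR
) -> np.ndarray:
    """``m`` independent normal predictive draws per record, floored.

    Returns an (n, m) array; draws below ``floor`` grams are truncated up to
    the floor, with the number of truncation events logged.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    mean = np.atleast_1d(np.asarray(mean, dtype=float))
    var = np.atleast_1d(np.asarray(var, dtype=float))
    mean, var = np.broadcast_arrays(mean, var)
    if np.any(var < 0):
        raise ValueError("variance must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    draws = rng.normal(mean[:, None], np.sqrt(var)[:, None], size=(mean.size, m))
    n_trunc = int(np.sum(draws < floor))
    if n_trunc:
        logger.info("floored %d imputation draws at %.0f g", n_trunc, floor)
    return np.maximum(draws, floor)


# ---------------------------------------------------------------------------
# application-cohort population model


@dataclass
class ApplicationModelSpec:
    """Population model of the observed weight in the application cohort.

    Fixed effects: natural cubic spline in maternal age (``age_spline_df``
    degrees of freedom), maternal education (linear), neonatal death
    indicator, infant sex, preterm and multiple-birth indicators, first-birth
    indicator, and age-at-measurement terms (linear in days plus a linear
    spline knot at ``time_knot_days`` so the extrapolation to t = 0 is
    anchored by the pre-nadir segment).  Random effect: per-woman intercept
    (women may contribute several pregnancies).
    """

    age_spline_df: int = 4
    time_knot_days: float = 3.0
    reml: bool = True

    def formula(self, data: pd.DataFrame | None = None) -> str:
        terms = ["mat_edu", "died", "male", "preterm", "multiple",
                 "first_birth", "t_days", "t_after_knot"]
        if data is not None:
            # constant columns (e.g. no multiples sampled, or all
            # measurements before the time knot) would make the design
            # singular; drop them from the fit
            dropped = [c for c in terms if data[c].nunique() < 2]
            if dropped:
                logger.info("dropping constant fixed-effect terms: %s", dropped)
            terms = [c for c in terms if c not in dropped]
        return (
            f"weight ~ cr(mat_age, df={self.age_spline_df}) + "
            + " + ".join(terms)
        )


_APP_COVARIATES = [
    "mat_age", "mat_edu", "died", "male", "preterm", "multiple", "first_birth",
]


def _prepare_application_frame(df: pd.DataFrame, spec: ApplicationModelSpec):
    out = df.copy()
    if "male" not in out.columns:
        out["male"] = np.where(
            out["sex"].isna(), np.nan, (out["sex"] == "male").astype(float)
        )
    if "died" not in out.columns:
        out["died"] = np.where(
            out["survival"].isna(), np.nan, (out["survival"] == "dead").astype(float)
        )
    if "preterm" not in out.columns:
        out["preterm"] = (out["ga_weeks"] < 37.0).astype(float)
    if "first_birth" not in out.columns:
        out["first_birth"] = np.where(
            out["parity"].isna(), np.nan, (out["parity"] == 0).astype(float)
        )
    out["t_days"] = out["t_hours"] / 24.0
    out["t_after_knot"] = np.maximum(out["t_days"] - spec.time_knot_days, 0.0)
    return out


class ApplicationWeightModel(BaseEstimator):
    """Mixed model of the single observed weight per birth.

    Only records with an observed weight and complete covariates enter the
    fit.  After fitting, :meth:`predict_pair` returns, for any record, the
    population prediction at its own measurement time and at t = 0 (all
    other covariates unchanged), both including the woman's random-intercept
    BLUP when she contributed fitted records, so two births from the same
    woman share one intercept prediction.
    """

    def __init__(self, spec: ApplicationModelSpec | None = None):
        self.spec = spec

    def fit(self, cohort: pd.DataFrame) -> "ApplicationWeightModel":
        spec = self.spec or ApplicationModelSpec()
        data = _prepare_application_frame(cohort, spec)
        has_weight = data["weight"].notna()
        if not has_weight.any():
            raise ValueError("no observed weights to fit")
        if (data.loc[has_weight, "t_hours"] <= 0).any():
            raise ValueError("age at measurement must be positive for observed weights")
        cols = ["weight", "t_days", "t_after_knot", "woman_id", *_APP_COVARIATES]
        complete = data[cols].notna().all(axis=1)
        fit_rows = has_weight & complete
        self.n_excluded_ = int((has_weight & ~complete).sum())
        if self.n_excluded_:
            logger.info(
                "excluding %d weighed records with incomplete covariates from the fit",
                self.n_excluded_,
            )
        fit_data = data.loc[fit_rows]
        model = smf.mixedlm(
            spec.formula(fit_data), fit_data, groups=fit_data["woman_id"]
        )
        result = fit_mixedlm_robust(model, reml=spec.reml)
        self.spec_ = spec
        self.result_ = result
        self.beta_ = result.fe_params
        self.woman_effects_ = {
            k: float(np.asarray(v)[0]) for k, v in result.random_effects.items()
        }
        self.n_fit_ = int(len(fit_data))
        self.n_women_ = int(fit_data["woman_id"].nunique())
        return self

    def predict_pair(self, cohort: pd.DataFrame) -> pd.DataFrame:
        """(ŵ_it, ŵ_i0) for each record with complete covariates.

        Records must carry a measurement age; t = 0 predictions zero the age
        terms only.  Unseen women get a zero random-intercept BLUP.
        """
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted")
        data = _prepare_application_frame(cohort, self.spec_)
        u = data["woman_id"].map(self.woman_effects_).fillna(0.0).to_numpy()
        w_hat_it = np.asarray(self.result_.predict(exog=data), dtype=float) + u
        data0 = data.copy()
        data0["t_days"] = 0.0
        data0["t_after_knot"] = 0.0
        w_hat_i0 = np.asarray(self.result_.predict(exog=data0), dtype=float) + u
        return pd.DataFrame(
            {"w_hat_it": w_hat_it, "w_hat_i0": w_hat_i0}, index=cohort.index
        )


def fit_application_model(
    cohort: pd.DataFrame, spec: ApplicationModelSpec | None = None
) -> ApplicationWeightModel:
    """Fit the application-cohort weight model; see the class docstring."""
    return ApplicationWeightModel(spec=spec).fit(cohort)


class EmpiricalBayesRecalibrator(BaseEstimator):
    """Transformer applying the EB recalibration to a cohort table.

    Parameters are the transferred training variance components ``G`` and
    ``sigma2``, the number of predictive draws ``m``, the truncation floor
    in grams and a seed.  :meth:`transform` expects a cohort frame carrying
    observed weights/times plus fitted ``w_hat_it``/``w_hat_i0`` columns
    (from :meth:`ApplicationWeightModel.predict_pair`) and returns the
    per-birth recalibration table with draw columns ``draw_1..draw_m``.
    """

    def __init__(self, G=None, sigma2=None, m: int = 5,
                 floor: float = WEIGHT_FLOOR, seed: int | None = None):
        self.G = G
        self.sigma2 = sigma2
        self.m = m
        self.floor = floor
        self.seed = seed

    def transform(self, cohort: pd.DataFrame) -> pd.DataFrame:
        if self.G is None or self.sigma2 is None:
            raise RuntimeError("G and sigma2 must be provided")
        observed = cohort.loc[cohort["weight"].notna()].copy()
        rw = eb_recalibrate(
            observed["weight"].to_numpy(),
            observed["t_hours"].to_numpy() / 24.0,
            observed["w_hat_it"].to_numpy(),
            observed["w_hat_i0"].to_numpy(),
            self.G,
            self.sigma2,
        )
        draws = draw_imputations(
            rw.w_tilde_i0, rw.var_i0, self.m, seed=self.seed, floor=self.floor
        )
        out = rw.to_frame()
        out.insert(0, "baby_id", observed["baby_id"].to_numpy())
        for k in range(self.m):
            out[f"draw_{k + 1}"] = draws[:, k]
        return out
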