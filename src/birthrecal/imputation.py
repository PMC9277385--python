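"""Random-forest imputation of birth weight for births with no measurement.

A regression forest learns the relationship between the recalibrated birth
weight and the covariates available for every birth (sex, gestational age,
multiple/singleton, neonatal survival, parity/first-birth, maternal
education and age).  Stochastic imputation draws add a residual sampled
with replacement from the model's out-of-bag residual pool to the forest
prediction, so draw variability reflects the forest's honest prediction
error without a distributional assumption.  Records missing any required
covariate are excluded with an exact count, and the bookkeeping identity
``imputed + excluded = missing-weight records`` always holds.

When m recalibrated datasets exist, one forest is trained per imputation
index (on recalibrated draw k), preserving between-imputation variability;
a mean-trained single-forest mode is available as an alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.ensemble import RandomForestRegressor

from .recalibration import WEIGHT_FLOOR

logger = logging.getLogger(__name__)

__all__ = [
    "MissingWeightImputer",
    "fit_imputation_model",
    "impute_missing",
    "impute_datasets",
    "IMPUTATION_COVARIATES",
]

#: Covariates the imputation forest uses; all must be non-missing.
IMPUTATION_COVARIATES = [
    "male", "ga_weeks", "multiple", "died", "first_birth", "mat_edu", "mat_age",
]


def _covariate_matrix(df: pd.DataFrame) -> pd.DataFrame:
    out = pd.DataFrame(index=df.index)
    if "male" in df.columns:
        out["male"] = df["male"]
    else:
        out["male"] = np.where(df["sex"].isna(), np.nan,
                               (df["sex"] == "male").astype(float))
    if "died" in df.columns:
        out["died"] = df["died"]
    else:
        out["died"] = np.where(df["survival"].isna(), np.nan,
                               (df["survival"] == "dead").astype(float))
    if "first_birth" in df.columns:
        out["first_birth"] = df["first_birth"]
    else:
        out["first_birth"] = np.where(df["parity"].isna(), np.nan,
                                      (df["parity"] == 0).astype(float))
    for col in ("ga_weeks", "multiple", "mat_edu", "mat_age"):
        out[col] = df[col]
    return out[IMPUTATION_COVARIATES]


class MissingWeightImputer(BaseEstimator):
    """Forest regression of recalibrated birth weight on covariates.

    Attributes (after fit): ``forest_``, ``oob_residuals_`` (observed minus
    out-of-bag prediction, one per training row with a valid OOB
    prediction), ``n_train_``, ``oob_error_`` (RMS of the OOB residuals).
    """

    def __init__(self, n_estimators: int = 500, min_train: int = 50,
                 floor: float = WEIGHT_FLOOR, random_state: int | None = None):
        self.n_estimators = n_estimators
        self.min_train = min_train
        self.floor = floor
        self.random_state = random_state

    def fit(self, covariates: pd.DataFrame, y) -> "MissingWeightImputer":
        X = _covariate_matrix(covariates)
        y = np.asarray(y, dtype=float)
        ok = X.notna().all(axis=1).to_numpy() & ~np.isnan(y)
        X, y = X.loc[ok], y[ok]
        if len(X) < self.min_train:
            raise ValueError(
                f"need at least {self.min_train} complete training rows, got {len(X)}"
            )
        forest = RandomForestRegressor(
            n_estimators=self.n_estimators,
            oob_score=True,
            bootstrap=True,
            random_state=self.random_state,
            n_jobs=1,
        )
        forest.fit(X.to_numpy(), y)
        oob_pred = forest.oob_prediction_
        # rows never out-of-bag (possible with few trees) are filled with 0
        valid = np.isfinite(oob_pred) & (oob_pred != 0.0)
        resid = y[valid] - oob_pred[valid]
        self.forest_ = forest
        self.oob_residuals_ = resid
        self.n_train_ = int(len(X))
        self.oob_error_ = float(np.sqrt(np.mean(resid**2))) if resid.size else np.nan
        return self

    def predict(self, covariates: pd.DataFrame) -> np.ndarray:
        if not hasattr(self, "forest_"):
            raise RuntimeError("imputer is not fitted")
        X = _covariate_matrix(covariates)
        if X.isna().any().any():
            raise ValueError("prediction rows must have complete covariates")
        return self.forest_.predict(X.to_numpy())

    def draw(self, covariates: pd.DataFrame, m: int, seed=None) -> np.ndarray:
        """(n, m) stochastic draws: prediction + bootstrapped OOB residual."""
        if m < 1:
            raise ValueError("m must be >= 1")
        pred = self.predict(covariates)
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        if self.oob_residuals_.size == 0:
            resid = np.zeros((len(pred), m))
        else:
            resid = rng.choice(self.oob_residuals_, size=(len(pred), m), replace=True)
        return np.maximum(pred[:, None] + resid, self.floor)


def fit_imputation_model(
    recalibrated_weights, covariates: pd.DataFrame, seed: int | None = None,
    n_estimators: int = 500, min_train: int = 50,
) -> MissingWeightImputer:
    """Train the forest on recalibrated weights with their covariates."""
    return MissingWeightImputer(
        n_estimators=n_estimators, min_train=min_train, random_state=seed
    ).fit(covariates, recalibrated_weights)


@dataclass
class ImputationResult:
    draws: pd.DataFrame          # baby_id + draw_1..draw_m for imputable records
    n_missing: int               # records lacking an observed weight
    n_imputed: int               # of those, records receiving draws
    n_excluded: int              # of those, records with incomplete covariates

    @property
    def coverage(self) -> float:
        """Fraction of missing-weight records successfully imputed."""
        return self.n_imputed / self.n_missing if self.n_missing else np.nan


def impute_missing(
    model: MissingWeightImputer, records: pd.DataFrame, m: int, seed=None
) -> ImputationResult:
    """Impute ``m`` birth-weight draws for records with no observed weight.

    Records missing any required covariate are excluded with a logged count;
    ``n_imputed + n_excluded == n_missing`` exactly.  An empty record set
    returns an empty result, not an error.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    missing = records.loc[records["weight"].isna()].copy()
    n_missing = int(len(missing))
    if n_missing == 0:
        empty = pd.DataFrame(
            columns=["baby_id"] + [f"draw_{k + 1}" for k in range(m)]
        )
        return ImputationResult(draws=empty, n_missing=0, n_imputed=0, n_excluded=0)
    X = _covariate_matrix(missing)
    complete = X.notna().all(axis=1)
    n_excluded = int((~complete).sum())
    if n_excluded:
        logger.info(
            "excluding %d missing-weight records with incomplete covariates",
            n_excluded,
        )
    usable = missing.loc[complete]
    draws = model.draw(usable, m, seed=seed)
    out = pd.DataFrame({"baby_id": usable["baby_id"].to_numpy()})
    for k in range(m):
        out[f"draw_{k + 1}"] = draws[:, k]
    return ImputationResult(
        draws=out, n_missing=n_missing, n_imputed=int(len(usable)),
        n_excluded=n_excluded,
    )


def impute_datasets(
    recal_table: pd.DataFrame,
    cohort: pd.DataFrame,
    m: int,
    seed: int | None = None,
    mode: str = "per-draw",
    n_estimators: int = 500,
    min_train: int = 50,
) -> tuple[list[pd.DataFrame], ImputationResult]:
    """Produce ``m`` completed datasets (recalibrated + imputed weights).

    ``mode='per-draw'`` trains one forest per imputation index k on
    recalibrated draw k (the default, preserving between-imputation
    variability); ``mode='mean'`` trains a single forest on the mean
    recalibrated weight and draws m times from it.  Each completed dataset
    is the cohort frame with a ``birth_weight_imputed`` column holding the
    recalibrated draw for measured births and the forest draw for imputable
    missing-weight births (NaN where covariates were incomplete).
    """
    if mode not in ("per-draw", "mean"):
        raise ValueError(f"unknown mode: {mode!r}")
    ss = np.random.SeedSequence(seed)
    child_seeds = ss.spawn(m + 1)
    measured = cohort.merge(recal_table[["baby_id"] +
                                        [f"draw_{k+1}" for k in range(m)]],
                            on="baby_id", how="left")
    covars = cohort.loc[cohort["weight"].notna()].merge(
        recal_table[["baby_id"]], on="baby_id", how="inner"
    )

    datasets: list[pd.DataFrame] = []
    result: ImputationResult | None = None
    if mode == "mean":
        mean_w = recal_table[[f"draw_{k+1}" for k in range(m)]].mean(axis=1)
        model = MissingWeightImputer(
            n_estimators=n_estimators, min_train=min_train,
            random_state=int(child_seeds[m].generate_state(1)[0] % (2**31)),
        ).fit(covars, mean_w.to_numpy())
    for k in range(m):
        seed_k = int(child_seeds[k].generate_state(1)[0] % (2**31))
        if mode == "per-draw":
            model = MissingWeightImputer(
                n_estimators=n_estimators, min_train=min_train,
                random_state=seed_k,
            ).fit(covars, recal_table[f"draw_{k+1}"].to_numpy())
        result = impute_missing(model, cohort, 1,
                                seed=np.random.default_rng(seed_k))
        completed = cohort.copy()
        completed["birth_weight_imputed"] = completed["baby_id"].map(
            recal_table.set_index("baby_id")[f"draw_{k+1}"]
        )
        if len(result.draws):
            imput = result.draws.set_index("baby_id")["draw_1"]
            fill = completed["baby_id"].map(imput)
            completed["birth_weight_imputed"] = (
                completed["birth_weight_imputed"].fillna(fill)
            )
        datasets.append(completed)
    assert result is not None
    return datasets, result
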