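"""Shared fixtures: synthetic cohorts and fitted models reused across tests.

Session scope keeps the expensive pieces (mixed-model fits, the end-to-end
recalibration) to a single computation for the whole run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from birthrecal import (
    SimConfig,
    simulate_application_cohort,
    simulate_training_cohort,
    synthetic_standard,
)
from birthrecal.growth import NeonatalGrowthModel
from birthrecal.recalibration import ApplicationWeightModel, EmpiricalBayesRecalibrator


@pytest.fixture(scope="session")
def standard():
    return synthetic_standard()


@pytest.fixture(scope="session")
def training_cohort():
    """Default-calibration training cohort (457 babies, 11 visits)."""
    return simulate_training_cohort(SimConfig(), seed=1)


@pytest.fixture(scope="session")
def application_cohort():
    """Application cohort at a reduced study size for test runtime."""
    return simulate_application_cohort(
        SimConfig(n_births_application=4000), seed=2
    )


@pytest.fixture(scope="session")
def growth_fit(training_cohort):
    return NeonatalGrowthModel().fit(training_cohort.observed)


@pytest.fixture(scope="session")
def recalibrated(growth_fit, application_cohort):
    """End-to-end recalibration table for the application cohort (m=5)."""
    obs = application_cohort.observed.loc[
        application_cohort.observed["weight"].notna()
    ].copy()
    app_model = ApplicationWeightModel().fit(application_cohort.observed)
    obs[["w_hat_it", "w_hat_i0"]] = app_model.predict_pair(obs)
    table = EmpiricalBayesRecalibrator(
        G=growth_fit.G_, sigma2=growth_fit.sigma2_, m=5, seed=3
    ).transform(obs)
    return table


@pytest.fixture()
def tiny_longitudinal():
    """Hand-built 4-baby cohort with linear per-baby weight trends."""
    rows = []
    rng = np.random.default_rng(0)
    for b in range(4):
        base = 2500.0 + 200.0 * b
        slope = -30.0 + 10.0 * b
        for d in range(6):
            t = 0.2 if d == 0 else float(d)
            rows.append(
                {
                    "baby_id": b,
                    "t_days": t,
                    "weight": base + slope * t + rng.normal(0, 1),
                    "sex": "male" if b % 2 else "female",
                    "ga_weeks": 38.0 + b,
                    "parity": float(b),
                    "first_birth": 1.0 if b == 0 else 0.0,
                    "mat_age": 20.0 + b,
                    "mat_edu": float(b),
                }
            )
    return pd.DataFrame(rows)
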