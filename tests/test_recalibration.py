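"""Empirical-Bayes recalibration: arithmetic, oracle agreement, properties."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from birthrecal.recalibration import (
    ApplicationWeightModel,
    draw_imputations,
    eb_recalibrate,
    oracle_conditional_normal,
)

G_EXAMPLE = [[40000.0, -500.0], [-500.0, 100.0]]


class TestEbArithmetic:
    def test_worked_example_exact(self):
        """v=39000, λ=39000/49000, shift −79.59..., var 18959.18... (direct
        arithmetic: v=G11+G12·t, w̃=ŵ0+λ·resid, var=(G11+σ²)−v²/(v+σ²))."""
        rw = eb_recalibrate(
            w_it=2600.0, t_days=2.0, w_hat_it=2700.0, w_hat_i0=2750.0,
            G=G_EXAMPLE, sigma2=10000.0,
        )
        assert rw.v[()] == pytest.approx(39000.0, abs=1e-9)
        assert rw.lam[()] == pytest.approx(39000.0 / 49000.0, rel=1e-12)
        assert rw.w_tilde_i0[()] == pytest.approx(
            2750.0 - 39000.0 / 49000.0 * 100.0, rel=1e-12
        )
        assert rw.var_i0[()] == pytest.approx(
            50000.0 - 39000.0**2 / 49000.0, rel=1e-12
        )

    def test_zero_v_no_borrowing(self):
        rw = eb_recalibrate(2600.0, 1.0, 2700.0, 2750.0,
                            [[0.0, 0.0], [0.0, 100.0]], 10000.0)
        assert rw.w_tilde_i0[()] == 2750.0
        assert rw.var_i0[()] == pytest.approx(10000.0)  # G11 + sigma2

    def test_noiseless_observation_fully_trusted(self):
        rw = eb_recalibrate(2600.0, 0.0, 2700.0, 2750.0,
                            [[40000.0, 0.0], [0.0, 100.0]], 0.0)
        assert rw.lam[()] == 1.0
        assert rw.w_tilde_i0[()] == pytest.approx(2750.0 - 100.0)
        assert rw.var_i0[()] == pytest.approx(0.0, abs=1e-9)

    def test_negative_v_clamped_to_prior(self):
        rw = eb_recalibrate(2600.0, 90.0, 2700.0, 2750.0, G_EXAMPLE, 10000.0)
        assert rw.v[()] < 0
        assert rw.lam[()] == 0.0
        assert rw.w_tilde_i0[()] == 2750.0
        assert rw.var_i0[()] == pytest.approx(50000.0)

    def test_non_psd_G_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            eb_recalibrate(2600.0, 1.0, 2700.0, 2750.0,
                           [[100.0, 500.0], [500.0, 100.0]], 1.0)
        with pytest.raises(ValueError, match="symmetric"):
            eb_recalibrate(2600.0, 1.0, 2700.0, 2750.0,
                           [[100.0, 5.0], [-5.0, 100.0]], 1.0)


class TestOracle:
    def test_oracle_differs_as_documented_on_example(self):
        """The exact conditional denominator uses Var(w_t), not v+σ²."""
        mean, var = oracle_conditional_normal(
            2600.0, 2.0, 2700.0, 2750.0, G_EXAMPLE, 10000.0
        )
        var_t = 40000.0 + 2 * (-500.0) * 2 + 100.0 * 4 + 10000.0  # 48400
        assert mean == pytest.approx(2750.0 - 39000.0 / var_t * 100.0, rel=1e-12)
        assert var == pytest.approx(50000.0 - 39000.0**2 / var_t, rel=1e-12)
        rw = eb_recalibrate(2600.0, 2.0, 2700.0, 2750.0, G_EXAMPLE, 10000.0)
        # quantified gap between the shrinkage formula and the exact oracle
        assert abs(rw.w_tilde_i0[()] - mean) == pytest.approx(
            abs(39000.0 / 49000.0 - 39000.0 / 48400.0) * 100.0, rel=1e-9
        )

    @given(
        g11=st.floats(1.0, 2e5),
        g22=st.floats(0.0, 1e3),
        sigma2=st.floats(1e-3, 1e5),
        t=st.floats(0.0, 40.0),
        resid=st.floats(-500.0, 500.0),
    )
    @settings(max_examples=200, deadline=None)
    def test_equivalence_when_g12_g22_zero_or_t_zero(
        self, g11, g22, sigma2, t, resid
    ):
        for G, tt in ([[g11, 0.0], [0.0, 0.0]], t), ([[g11, 0.0], [0.0, g22]], 0.0):
            rw = eb_recalibrate(2600.0 + resid, tt, 2600.0, 2700.0, G, sigma2)
            mean, var = oracle_conditional_normal(
                2600.0 + resid, tt, 2600.0, 2700.0, G, sigma2
            )
            assert rw.w_tilde_i0[()] == pytest.approx(mean, rel=1e-9, abs=1e-7)
            assert rw.var_i0[()] == pytest.approx(var, rel=1e-9, abs=1e-7)

    def test_degenerate_marginal_variance_rejected(self):
        with pytest.raises(ValueError):
            oracle_conditional_normal(
                2600.0, 1.0, 2600.0, 2700.0, [[0.0, 0.0], [0.0, 0.0]], 0.0
            )


class TestShrinkageProperties:
    @given(
        g11=st.floats(0.0, 2e5),
        rho=st.floats(-0.99, 0.99),
        g22=st.floats(0.0, 1e3),
        sigma2=st.floats(1e-6, 1e5),
        t=st.floats(0.0, 12.0),
        resid=st.floats(-600.0, 600.0),
    )
    @settings(max_examples=300, deadline=None)
    def test_estimate_between_prior_and_observation_shift(
        self, g11, rho, g22, sigma2, t, resid
    ):
        g12 = rho * np.sqrt(g11 * g22)
        G = [[g11, g12], [g12, g22]]
        rw = eb_recalibrate(2600.0 + resid, t, 2600.0, 2700.0, G, sigma2)
        lam = rw.lam[()]
        assert 0.0 <= lam <= 1.0
        lo, hi = sorted((2700.0, 2700.0 + resid))
        assert lo - 1e-6 <= rw.w_tilde_i0[()] <= hi + 1e-6
        assert -1e-6 <= rw.var_i0[()] <= g11 + sigma2 + 1e-6

    def test_monotone_in_observation_and_variance_in_v(self):
        w = np.linspace(2000, 3200, 50)
        rw = eb_recalibrate(w, 2.0, 2600.0, 2700.0,
                            [[40000.0, 0.0], [0.0, 100.0]], 10000.0)
        assert np.all(np.diff(rw.w_tilde_i0) > 0)
        # var non-increasing in v for fixed sigma2
        v = np.linspace(0, 1e5, 200)
        sigma2 = 5000.0
        var = (1e5 + sigma2) - v**2 / (v + sigma2)
        assert np.all(np.diff(var) <= 1e-9)


class TestDraws:
    def test_zero_variance_draws_collapse(self):
        d = draw_imputations([2700.0], [0.0], m=5, seed=1)
        assert np.all(d == 2700.0)

    def test_reproducible_with_seed(self):
        a = draw_imputations([2700.0, 2500.0], [100.0, 400.0], m=5, seed=42)
        b = draw_imputations([2700.0, 2500.0], [100.0, 400.0], m=5, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_moments_match_normal_theory(self):
        mean, var = 2700.0, 18959.2
        d = draw_imputations([mean], [var], m=10000, seed=7)[0]
        se_mean = np.sqrt(var / d.size)
        assert abs(d.mean() - mean) < 3 * se_mean
        se_var = var * np.sqrt(2.0 / (d.size - 1))
        assert abs(d.var(ddof=1) - var) < 3 * se_var

    def test_floor_applied(self):
        d = draw_imputations([350.0], [1e6], m=2000, seed=3, floor=300.0)
        assert d.min() >= 300.0

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            draw_imputations([2700.0], [1.0], m=0)


class TestApplicationModel:
    def test_prediction_at_time_zero_equals_birth_prediction(
        self, application_cohort, recalibrated
    ):
        obs = application_cohort.observed.loc[
            application_cohort.observed["weight"].notna()
        ].head(20).copy()
        model = ApplicationWeightModel().fit(application_cohort.observed)
        obs["t_hours"] = 0.0
        pair = model.predict_pair(obs)
        np.testing.assert_allclose(pair["w_hat_it"], pair["w_hat_i0"], atol=1e-8)

    def test_known_linear_time_effect_recovered(self):
        """Weights falling 40 g/day give ŵ0 − ŵt ≈ 40·t."""
        rng = np.random.default_rng(5)
        n = 1500
        t_days = rng.uniform(0.05, 2.8, n)
        woman = np.arange(n) // 2
        base = (2700 + rng.normal(0, 250, n // 2 + 1))[woman] + rng.normal(0, 150, n)
        df = pd.DataFrame(
            {
                "baby_id": np.arange(n),
                "woman_id": woman,  # two births per woman: identifiable intercept
                "sex": rng.choice(["male", "female"], n),
                "ga_weeks": rng.normal(39.5, 2.0, n),
                "parity": rng.integers(0, 4, n).astype(float),
                "mat_age": rng.uniform(16, 40, n),
                "mat_edu": rng.integers(0, 10, n).astype(float),
                "multiple": np.zeros(n),
                "survival": "alive",
                "t_hours": t_days * 24,
                "weight": base - 40.0 * t_days,
            }
        )
        model = ApplicationWeightModel().fit(df)
        pair = model.predict_pair(df)
        slope_hat = (pair["w_hat_i0"] - pair["w_hat_it"]) / t_days
        assert slope_hat.mean() == pytest.approx(40.0, abs=6.0)

    def test_same_woman_shares_intercept(self, application_cohort):
        obs = application_cohort.observed
        model = ApplicationWeightModel().fit(obs)
        sizes = obs.loc[obs["weight"].notna()].groupby("woman_id").size()
        woman = sizes[sizes >= 2].index[0]
        pair_rows = obs.loc[obs["woman_id"] == woman].copy()
        # zeroing the woman's BLUP shifts every one of her births equally
        u = model.woman_effects_.get(woman, 0.0)
        assert u != 0.0
        preds = model.predict_pair(pair_rows)
        model.woman_effects_[woman] = 0.0
        preds0 = model.predict_pair(pair_rows)
        model.woman_effects_[woman] = u
        shift = preds["w_hat_it"] - preds0["w_hat_it"]
        np.testing.assert_allclose(shift, u, atol=1e-9)

    def test_all_missing_weights_rejected(self, application_cohort):
        empty = application_cohort.observed.copy()
        empty["weight"] = np.nan
        with pytest.raises(ValueError, match="no observed weights"):
            ApplicationWeightModel().fit(empty)

    def test_recalibration_pulls_toward_birth_weight(
        self, application_cohort, recalibrated
    ):
        """Nadir-period weights are adjusted up, post-regain weights down."""
        rec = recalibrated.set_index("baby_id")
        adj = rec["w_tilde_i0"] - rec["w_it"]
        t = rec["t_days"]
        assert adj[(t >= 1) & (t < 3)].mean() > 0
        assert adj[t >= 10].mean() < 0
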