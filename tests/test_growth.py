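"""Mixed-model fitting and trajectory analytics."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.formula.api as smf

from birthrecal import SimConfig, simulate_lmm_training_cohort, simulate_training_cohort
from birthrecal.growth import (
    MixedModelSpec,
    NeonatalGrowthModel,
    baby_trajectory,
    find_nadir,
    find_return_time,
    km_return_curve,
    summarize_growth,
)


class TestMixedModelFit:
    def test_matches_ols_when_random_effects_absent(self):
        """With zero generating random effects the GLS fit collapses to OLS."""
        cfg = SimConfig(
            n_babies_training=150,
            lmm_G=((0.0, 0.0), (0.0, 0.0)),
            lmm_sigma=40.0,
        )
        tc = simulate_lmm_training_cohort(cfg, seed=2)
        fit = NeonatalGrowthModel().fit(tc.observed)
        data = tc.observed.copy()
        data["male"] = (data["sex"] == "male").astype(float)
        data["ga_below40"] = np.minimum(data["ga_weeks"] - 40, 0)
        data["ga_above40"] = np.maximum(data["ga_weeks"] - 40, 0)
        ols = smf.ols(MixedModelSpec().formula(), data).fit()
        for name, value in ols.params.items():
            scale = max(abs(value), 1.0)
            assert abs(fit.beta_[name] - value) / scale < 0.02

    def test_variance_components_recovered(self):
        """Estimated G11 and sigma2 land near the generating values."""
        cfg = SimConfig()
        tc = simulate_lmm_training_cohort(cfg, seed=30)
        fit = NeonatalGrowthModel().fit(tc.observed)
        G = np.asarray(cfg.lmm_G)
        assert fit.G_[0, 0] == pytest.approx(G[0, 0], rel=0.25)
        assert fit.sigma2_ == pytest.approx(cfg.lmm_sigma**2, rel=0.15)
        assert not fit.singular_

    def test_blup_residuals_vanish_without_noise(self):
        """With σ→0 the per-baby predictions interpolate the data (BLUP)."""
        cfg = SimConfig(n_babies_training=40, lmm_sigma=1e-3)
        tc = simulate_lmm_training_cohort(cfg, seed=12)
        fit = NeonatalGrowthModel().fit(tc.observed)
        for baby_id, sub in list(tc.observed.groupby("baby_id"))[:10]:
            pred = fit.predict_trajectory(baby_id, sub["t_days"].to_numpy())
            resid = sub["weight"].to_numpy() - pred
            assert abs(resid.mean()) < 0.05

    def test_constant_response_flagged_singular(self):
        rows = []
        for b in range(12):
            for d in range(5):
                rows.append(
                    {"baby_id": b, "t_days": 0.2 if d == 0 else float(d),
                     "weight": 3000.0, "sex": "male", "ga_weeks": 39.0,
                     "first_birth": 0.0, "mat_age": 25.0, "mat_edu": 3.0}
                )
        fit = NeonatalGrowthModel().fit(pd.DataFrame(rows))
        assert fit.singular_
        assert fit.sigma2_ == pytest.approx(0.0, abs=1e-9)
        assert np.allclose(fit.G_, 0.0)
        np.testing.assert_allclose(
            fit.predict_trajectory(0, [0.0, 5.0]), [3000.0, 3000.0]
        )

    def test_single_observation_babies_rejected(self, tiny_longitudinal):
        broken = pd.concat(
            [tiny_longitudinal, tiny_longitudinal.iloc[[0]].assign(baby_id=99)]
        )
        with pytest.raises(ValueError, match=">=2 observations"):
            NeonatalGrowthModel().fit(broken)

    def test_unknown_baby_raises(self, growth_fit):
        with pytest.raises(KeyError):
            growth_fit.predict_trajectory("nope", [0.0])

    def test_prediction_at_zero_is_fixed_part_plus_intercept(self, growth_fit):
        baby = growth_fit.random_effects_.index[0]
        p0 = growth_fit.predict_trajectory(baby, [0.0, 1.0])
        u0, u1 = growth_fit.random_effects_.loc[baby]
        assert p0[1] - p0[0] == pytest.approx(u1, abs=1e-9)


class TestNadirAndReturn:
    def test_monotone_increasing_nadir_at_zero(self):
        t = np.linspace(0, 10, 1001)
        assert find_nadir(t, 2500 + 30 * t) == (0.0, 2500.0)

    def test_v_shape_recovers_minimum_at_2_1(self):
        t = np.arange(0, 10.0001, 0.01)
        w = 2700 + 100 * np.abs(t - 2.1)
        nt, nw = find_nadir(t, w)
        assert nt == pytest.approx(2.1, abs=0.01)
        assert nw == pytest.approx(2700, abs=1.0)

    def test_tie_broken_earliest(self):
        t = np.array([0.0, 1.0, 2.0, 3.0])
        w = np.array([5.0, 1.0, 1.0, 2.0])
        assert find_nadir(t, w)[0] == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            find_nadir([], [])

    def test_return_at_crossing_time(self):
        t = np.arange(0, 10.0001, 0.01)
        w = np.where(t <= 2.0, 3000 - 60 * t, 3000 - 120 + 48 * (t - 2.0))
        ret = find_return_time(t, w, 3000.0)
        assert not ret.censored
        assert ret.time == pytest.approx(4.5, abs=0.011)

    def test_never_regaining_censored_at_window_end(self):
        t = np.arange(0, 10.0001, 0.01)
        w = 3000 - 50 * t / 10
        ret = find_return_time(t, w, 3000.0)
        assert ret.censored and ret.time == pytest.approx(10.0, abs=1e-9)
        assert ret.closest_gap > 0

    def test_flat_at_birth_weight_returns_immediately(self):
        t = np.arange(0, 5.0001, 0.01)
        ret = find_return_time(t, np.full_like(t, 3000.0), 3000.0)
        assert not ret.censored and ret.time == 0.0

    def test_grid_refinement_agreement(self):
        """Coarse-grid results sit within one coarse step of a 10x finer scan."""
        rng = np.random.default_rng(44)
        for _ in range(20):
            tn = rng.uniform(0.5, 4.0)
            tr = tn + rng.uniform(0.5, 8.0)
            frac = rng.uniform(0.01, 0.08)
            from birthrecal import trajectory_weight

            def curve(t):
                return trajectory_weight(t, 3000.0, tn, frac, tr, 30.0)

            g1 = np.arange(0, 10.0001, 0.01)
            g2 = np.arange(0, 10.00001, 0.001)
            n1, _ = find_nadir(g1, curve(g1))
            n2, _ = find_nadir(g2, curve(g2))
            assert abs(n1 - n2) <= 0.01 + 1e-9
            r1 = find_return_time(g1, curve(g1), 3000.0)
            r2 = find_return_time(g2, curve(g2), 3000.0)
            if not (r1.censored or r2.censored):
                assert abs(r1.time - r2.time) <= 0.01 + 1e-9

    def test_dense_grid_recovers_configured_nadir(self):
        """On the true trajectory the finder returns the generating nadir."""
        cfg = SimConfig(n_babies_training=30)
        tc = simulate_training_cohort(cfg, seed=13)
        grid = np.arange(0, 10.0001, 0.01)
        for _, row in tc.truth.head(10).iterrows():
            from birthrecal import trajectory_weight

            w = trajectory_weight(grid, row.birth_weight, row.nadir_time,
                                  row.nadir_frac, row.return_time, 30.0)
            nt, nw = find_nadir(grid, w)
            assert nt == pytest.approx(row.nadir_time, abs=0.011)
            assert nw == pytest.approx(row.nadir_weight, abs=0.5)


class TestKaplanMeier:
    def test_no_censoring_equals_ecdf_complement(self):
        km = km_return_curve([1.0, 2.0, 3.0], [False, False, False])
        steps = km.set_index("time")["estimate"]
        assert steps.loc[1.0] == pytest.approx(2 / 3)
        assert steps.loc[2.0] == pytest.approx(1 / 3)
        assert steps.loc[3.0] == pytest.approx(0.0)

    def test_hand_computed_product_limit_with_censoring(self):
        """One censored at 1, one event at 2: risk set at 2 is a single baby."""
        km = km_return_curve([1.0, 2.0], [True, False])
        steps = km.set_index("time")["estimate"]
        assert steps.loc[1.0] == pytest.approx(1.0)
        assert steps.loc[2.0] == pytest.approx(0.0)

    def test_all_censored_flat_curve(self):
        km = km_return_curve([5.0, 10.0], [True, True])
        assert (km["estimate"] == 1.0).all()

    def test_plateau_matches_never_return_fraction(self, training_cohort):
        summary = summarize_growth(training_cohort.observed)
        km = km_return_curve(summary.per_baby["return_time"],
                             summary.per_baby["censored"])
        plateau = km["estimate"].iloc[-1]
        assert plateau == pytest.approx(84 / 457, abs=0.06)


class TestGrowthSummary:
    def test_single_baby_medians_equal_its_values(self, training_cohort):
        one = training_cohort.observed.query("baby_id == 0")
        s = summarize_growth(one)
        assert s.n_babies == 1
        row = s.per_baby.iloc[0]
        assert s.medians["nadir_time_days"][0] == row["nadir_time"]
        assert s.medians["birth_weight_g"][0] == row["birth_weight"]

    def test_noiseless_summary_tracks_sidecar_truth(self):
        cfg = SimConfig(n_babies_training=60, noise_sd=0.0)
        tc = simulate_training_cohort(cfg, seed=17)
        s = summarize_growth(tc.observed)
        merged = s.per_baby.merge(tc.truth, on="baby_id",
                                  suffixes=("_est", "_true"))
        # daily sampling limits nadir-time precision to the spline's
        # placement between knots; loss fraction is much tighter
        err_t = (merged["nadir_time_est"] - merged["nadir_time_true"]).abs()
        assert err_t.median() < 0.2
        rel_true = merged["nadir_frac"]
        assert (merged["relative_loss"] - rel_true).abs().median() < 0.004
        returned = ~merged["censored"] & ~merged["never_returns_in_window"]
        err_r = (merged.loc[returned, "return_time_est"]
                 - merged.loc[returned, "return_time_true"]).abs()
        assert err_r.median() < 0.25

    def test_default_cohort_relative_loss_near_configured(self, training_cohort):
        s = summarize_growth(training_cohort.observed)
        # measurement noise deepens the apparent minimum slightly; the
        # documented bias stays well under one percentage point of loss
        assert s.medians["relative_loss"][0] == pytest.approx(0.043, abs=0.008)
        assert s.medians["birth_weight_g"][0] == pytest.approx(2726, abs=80)

    def test_trajectory_builder_needs_two_points(self):
        with pytest.raises(ValueError):
            baby_trajectory([1.0], [3000.0])
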