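"""R^2, the single-parameter least-squares fit, and the activation-energy
profile, including the brute-force grid-search oracle."""

import math

import numpy as np
import pandas as pd
import pytest

import nanotoxkin as nk


class TestRSquared:
    def test_exact_predictions(self):
        y = [0.1, 0.4, 0.7]
        assert nk.r_squared(y, y) == 1.0

    def test_mean_predictor_scores_zero(self):
        y = np.array([0.2, 0.5, 0.8])
        assert nk.r_squared(y, np.full(3, y.mean())) == pytest.approx(0.0, abs=1e-15)

    def test_hand_computed_value(self):
        # SSres = 0.0025 + 0.0025 + 0 = 0.005; SStot = 0.09 + 0 + 0.09 = 0.18
        r2 = nk.r_squared([0.2, 0.5, 0.8], [0.25, 0.45, 0.80])
        assert r2 == pytest.approx(1 - 0.005 / 0.18, rel=1e-12)
        assert r2 == pytest.approx(0.97222, abs=1e-5)

    def test_can_be_negative(self):
        assert nk.r_squared([0.1, 0.2, 0.3], [0.9, 0.9, 0.9]) < 0

    def test_errors(self):
        with pytest.raises(ValueError):
            nk.r_squared([0.1, 0.2], [0.1])
        with pytest.raises(ValueError):
            nk.r_squared([0.5, 0.5], [0.4, 0.6])  # zero SStot
        with pytest.raises(ValueError):
            nk.r_squared([0.5], [0.4])


class TestDamageTimeCourse:
    def test_counts_define_fraction(self):
        tc = nk.DamageTimeCourse.from_counts(
            [10.0, 60.0], [1500, 1600], [300, 800], 295.15, 3.98e16
        )
        assert tc.fraction == pytest.approx([0.2, 0.5])

    @pytest.mark.parametrize(
        "times, fracs",
        [
            ([10.0, 10.0], [0.1, 0.2]),  # not strictly increasing
            ([10.0, 5.0], [0.1, 0.2]),
            ([10.0, 20.0], [0.1, 1.2]),  # fraction out of range
        ],
    )
    def test_invariants(self, times, fracs):
        with pytest.raises(ValueError):
            nk.DamageTimeCourse(
                time_min=np.array(times),
                fraction=np.array(fracs),
                temperature=295.15,
                nanoparticle_density=3.98e16,
            )

    def test_damaged_cannot_exceed_counted(self):
        with pytest.raises(ValueError):
            nk.DamageTimeCourse.from_counts(
                [10.0], [100], [200], 295.15, 3.98e16
            )

    def test_from_dataframe_with_fractions(self):
        df = pd.DataFrame(
            {
                "temperature_C": [22.0, 22.0],
                "agnp_ug_per_ml": [5.0, 5.0],
                "time_min": [30.0, 150.0],
                "fraction_damaged": [0.2, 0.5],
            }
        )
        tc = nk.DamageTimeCourse.from_dataframe(df)
        assert tc.temperature == pytest.approx(295.15)
        assert tc.nanoparticle_density == pytest.approx(7.95e16, rel=5e-3)

    def test_from_dataframe_rejects_mixed_conditions(self):
        df = pd.DataFrame(
            {
                "temperature_C": [22.0, 37.0],
                "agnp_ug_per_ml": [5.0, 5.0],
                "time_min": [30.0, 150.0],
                "fraction_damaged": [0.2, 0.5],
            }
        )
        with pytest.raises(ValueError):
            nk.DamageTimeCourse.from_dataframe(df)

    def test_from_dataframe_missing_columns(self):
        with pytest.raises(ValueError):
            nk.DamageTimeCourse.from_dataframe(pd.DataFrame({"time_min": [1.0]}))


class TestFit:
    def test_noise_free_recovery(self, noise_free_timecourse, medium_22c, condition_22c_5ug):
        res = nk.fit_p2(
            noise_free_timecourse, medium=medium_22c, condition=condition_22c_5ug
        )
        assert abs(res.p2_hat - 0.106) < 1e-3
        assert res.rsquared == pytest.approx(1.0, abs=1e-10)

    def test_two_points_on_one_hyperbola_fit_exactly(self):
        # (10 min, 0.5) and (60 min, 6/7) lie on a single hyperbola
        tc = nk.DamageTimeCourse(
            time_min=np.array([10.0, 60.0]),
            fraction=np.array([0.5, 6.0 / 7.0]),
            temperature=nk.celsius_to_kelvin(37.0),
            nanoparticle_density=nk.mass_to_number_density(5.0, nk.ParticleSpec()),
        )
        res = nk.fit_p2(tc)
        assert res.rsquared == pytest.approx(1.0, abs=1e-9)
        implied = 1.0 / 600.0  # CB0 k2, s^-1
        assert tc.nanoparticle_density * res.k2_hat == pytest.approx(implied, rel=1e-5)

    def test_single_point_rejected(self):
        tc = nk.DamageTimeCourse(
            time_min=np.array([10.0]),
            fraction=np.array([0.5]),
            temperature=295.15,
            nanoparticle_density=3.98e16,
        )
        with pytest.raises(ValueError):
            nk.fit_p2(tc)

    def test_all_zero_fractions_warn_and_floor(self):
        tc = nk.DamageTimeCourse(
            time_min=np.array([10.0, 60.0, 120.0]),
            fraction=np.zeros(3),
            temperature=295.15,
            nanoparticle_density=3.98e16,
        )
        with pytest.warns(UserWarning, match="not identified"):
            res = nk.fit_p2(tc)
        assert res.at_bound
        assert res.p2_hat == nk.MembraneDamageModel.p2_bounds[0]

    def test_determinism(self, noise_free_timecourse):
        a = nk.fit_p2(noise_free_timecourse)
        b = nk.fit_p2(noise_free_timecourse)
        assert a.p2_hat == b.p2_hat  # bitwise

    def test_agrees_with_grid_search_oracle(self, medium_22c, condition_22c_5ug):
        """Brute force: dense log grid over (1e-3, 1] plus parabolic
        refinement must land on the optimiser's estimate."""
        rng = np.random.default_rng(3)
        aod = nk.AodSurvivalModel(0.08)
        times = np.array([5.0, 15.0, 45.0, 90.0, 150.0, 210.0])
        frac = nk.predict_timecourse(times * 60, condition_22c_5ug, medium_22c, aod)
        frac = np.clip(frac + rng.normal(0, 0.02, frac.size), 0, 1)
        tc = nk.DamageTimeCourse(
            time_min=times,
            fraction=frac,
            temperature=condition_22c_5ug.temperature,
            nanoparticle_density=condition_22c_5ug.nanoparticle_density,
        )
        model = nk.MembraneDamageModel(tc, medium=medium_22c, condition=condition_22c_5ug)
        res = model.fit()
        # independent oracle: 1e4-point grid + golden refinement on bracket
        grid = np.exp(np.linspace(math.log(1e-3), 0.0, 10_000))
        ssr = np.array([model._ssr(p) for p in grid])
        i = int(np.argmin(ssr))
        from scipy.optimize import minimize_scalar

        ref = minimize_scalar(
            model._ssr,
            bounds=(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)]),
            method="bounded",
            options={"xatol": 1e-12},
        )
        assert abs(res.p2_hat - ref.x) < 1e-4

    def test_time_window_excludes_points(self, noise_free_timecourse):
        res = nk.fit_p2(noise_free_timecourse, time_window=(0.0, 150.0))
        assert res.nobs == 7

    def test_inverse_variance_weighting_runs(self):
        tc = nk.DamageTimeCourse.from_counts(
            [10.0, 60.0, 150.0], [1500, 1500, 1500], [300, 700, 850],
            295.15, 7.95e16,
        )
        res = nk.fit_p2(tc, weights="inverse_variance")
        assert 1e-3 < res.p2_hat <= 1.0

    def test_results_accessors(self, noise_free_timecourse):
        res = nk.fit_p2(noise_free_timecourse)
        assert res.params.shape == (1,)
        assert res.resid.shape == (8,)
        assert res.eact2_hat == pytest.approx(
            nk.activation_energy_second(res.p2_hat, 295.15), rel=1e-12
        )
        d = res.to_dict()
        assert set(d) >= {"p2_hat", "k2_hat_m3_per_s", "eact2_hat_J", "r_squared",
                          "convention", "n_points"}
        assert "P2" in res.summary()

    def test_truncation_improves_fit_under_late_breakdown(self, medium_22c, condition_22c_5ug):
        """With hazard-doubling after 150 min the hyperbola cannot follow
        the late points; restricting the window restores the fit."""
        aod = nk.AodSurvivalModel(0.106)
        design = nk.AssayDesign(
            temperatures=(22.0,), concentrations=(5.0,),
            times=(5, 10, 30, 60, 90, 120, 150, 180, 210.0),
            baseline_damage=0.0, breakdown_time=150.0, breakdown_factor=2.0,
            seed=7,
        )
        tc = nk.simulate_assay(design, aod).to_timecourses()[0]
        r2_full = nk.fit_p2(tc).rsquared
        r2_trunc = nk.fit_p2(tc, time_window=(0.0, 150.0)).rsquared
        assert r2_trunc > r2_full


class TestSinglePointInversion:
    def test_roundtrip_through_forward_model(self, medium_22c):
        condition = nk.ExperimentCondition.from_lab_units(22.0, 5.0)
        aod = nk.AodSurvivalModel(0.12)
        f = nk.predict_timecourse(np.array([3600.0]), condition, medium_22c, aod)[0]
        p2 = nk.p2_from_fraction(f, 60.0, condition, medium_22c)
        assert p2 == pytest.approx(0.12, rel=1e-9)

    def test_printed_convention_inverse(self, medium_22c):
        condition = nk.ExperimentCondition.from_lab_units(22.0, 5.0)
        p2c = nk.p2_from_fraction(0.3, 60.0, condition, medium_22c, "corrected")
        p2p = nk.p2_from_fraction(0.3, 60.0, condition, medium_22c, "printed")
        # same |g|, opposite sign: 1/p2c + 1/p2p = 2
        assert 1 / p2c + 1 / p2p == pytest.approx(2.0, rel=1e-9)

    @pytest.mark.parametrize("bad_f", [0.0, 1.0, -0.1])
    def test_domain(self, bad_f, medium_22c):
        condition = nk.ExperimentCondition.from_lab_units(22.0, 5.0)
        with pytest.raises(ValueError):
            nk.p2_from_fraction(bad_f, 60.0, condition, medium_22c)


class TestActivationEnergyProfile:
    def test_temperature_scan_scenario(self):
        """60-min damage of 40%/10%/30% at 4/22/37 degC (2.5 ug/mL):
        the inferred death barrier peaks at 22 degC — cells are most
        protected near ambient — and is lowest at 4 degC where the
        enzymatic defence is cold-suppressed."""
        fits = []
        for t_c, frac in nk.temperature_scan_fractions().items():
            condition = nk.ExperimentCondition.from_lab_units(t_c, 2.5)
            medium = nk.MediumState.from_celsius(t_c)
            p2 = nk.p2_from_fraction(frac, 60.0, condition, medium)
            fits.append((condition.temperature, p2))
        profile = nk.activation_energy_profile(fits)
        assert profile.attrs["argmax_temperature_C"] == pytest.approx(22.0)
        assert profile.attrs["argmin_temperature_C"] == pytest.approx(4.0)
        by_t = profile.set_index(profile["temperature_C"].round(0))
        assert by_t.loc[4.0, "p2"] == pytest.approx(0.122, abs=0.002)
        assert by_t.loc[22.0, "p2"] == pytest.approx(0.102, abs=0.002)
        assert by_t.loc[37.0, "p2"] == pytest.approx(0.109, abs=0.002)
        assert by_t.loc[4.0, "eact2_J"] == pytest.approx(4.7e-20, rel=0.02)
        assert by_t.loc[22.0, "eact2_J"] == pytest.approx(6.0e-20, rel=0.02)
        assert by_t.loc[37.0, "eact2_J"] == pytest.approx(5.9e-20, rel=0.02)

    def test_shared_p2_profile_increases_with_temperature(self):
        fits = [(277.15, 0.1), (295.15, 0.1), (310.15, 0.1)]
        profile = nk.activation_energy_profile(fits)
        assert profile["eact2_J"].is_monotonic_increasing

    def test_errors(self):
        with pytest.raises(ValueError):
            nk.activation_energy_profile([(295.15, 0.1)])
        with pytest.raises(ValueError):
            nk.activation_energy_profile([(295.15, 0.1), (295.15, 0.2)])
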