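import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hydromix.errors import CalibrationError, InvalidInputError
from hydromix.mixing_power import PowerCorrelation, fit_power_correlation
from hydromix.synthetic_data import (
    DEFAULT_ANCHORS,
    HydrolysisConditions,
    SlurryComposition,
    calibrate_conversion_model,
    conversion_curve,
    conversion_from_glucose,
    dilute_slurry,
    enzyme_dose,
    glucose_from_conversion,
    sample_noisy_glucose,
    simulate_power_observations,
    wis_from_conversion,
)

# independent closed-form oracles for the default-anchor calibration:
# u = exp(-48/tau) solves (1 - u)/(1 - u^2) = 0.57/0.72  =>  u = 72/57 - 1
TAU_ORACLE = -48.0 / math.log(72.0 / 57.0 - 1.0)  # 35.955 h
P_ORACLE = math.log(0.54 / 0.72) / math.log(10.0 / 20.0)  # 0.41504


class TestEnzymeDose:
    def test_high_loading(self):
        prep, iu = enzyme_dose(20.0, 95.0, 590.0)
        assert iu == pytest.approx(124.2, abs=0.05)
        assert prep == pytest.approx(20.0 / 95.0, rel=1e-12)

    def test_low_loading(self):
        _, iu = enzyme_dose(10.0, 95.0, 590.0)
        assert iu == pytest.approx(62.1, abs=0.05)

    def test_zero_load(self):
        assert enzyme_dose(0.0, 95.0, 590.0) == (0.0, 0.0)

    def test_zero_activity_rejected(self):
        with pytest.raises(InvalidInputError):
            enzyme_dose(10.0, 0.0, 590.0)


class TestDiluteSlurry:
    def test_water_added_13_to_10(self, base_composition):
        res = dilute_slurry(base_composition, 10.0)
        assert res.water_added_per_kg == pytest.approx(0.30, abs=1e-12)

    def test_no_op_dilution(self, base_composition):
        res = dilute_slurry(base_composition, base_composition.wis0)
        assert res.water_added_per_kg == 0.0
        assert res.composition == base_composition

    def test_diluted_glucose(self, base_composition):
        # 29.8 g/L in 0.87 L -> 25.93 g in 1.17 L = 22.16 g/L
        res = dilute_slurry(base_composition, 10.0)
        assert res.composition.initial_liquid_glucose == pytest.approx(
            29.8 * 0.87 / 1.17, rel=1e-12
        )
        assert res.composition.initial_liquid_glucose == pytest.approx(22.2, abs=0.1)

    def test_target_above_current_rejected(self, base_composition):
        with pytest.raises(InvalidInputError):
            dilute_slurry(base_composition, 15.0)

    @given(wis0=st.floats(5.0, 20.0), target=st.floats(1.0, 20.0))
    @settings(max_examples=100)
    def test_mass_conservation(self, wis0, target):
        if target > wis0:
            target = wis0
        comp = SlurryComposition(wis0=wis0)
        res = dilute_slurry(comp, target)
        # solids conserved per kg slurry
        solids_before = wis0 / 100.0
        solids_after = target / 100.0 * (1.0 + res.water_added_per_kg)
        assert solids_after == pytest.approx(solids_before, rel=1e-12)
        # dissolved glucose mass conserved (liquid density 1 kg/L)
        liquid_before = 1.0 - wis0 / 100.0
        liquid_after = liquid_before + res.water_added_per_kg
        mass_before = comp.initial_liquid_glucose * liquid_before
        mass_after = res.composition.initial_liquid_glucose * liquid_after
        assert mass_after == pytest.approx(mass_before, rel=1e-12)


class TestCalibrateConversionModel:
    def test_tau_matches_oracle(self, conversion_params):
        assert conversion_params.tau == pytest.approx(TAU_ORACLE, rel=1e-6)
        assert conversion_params.tau == pytest.approx(35.96, abs=0.05)

    def test_enzyme_exponent_matches_oracle(self, conversion_params):
        assert conversion_params.p == pytest.approx(P_ORACLE, rel=1e-6)
        assert conversion_params.p == pytest.approx(0.415, abs=5e-4)

    def test_anchors_reproduced(self, conversion_params):
        for rpm, load, t, x in DEFAULT_ANCHORS:
            assert conversion_params.conversion(t, rpm, load) == pytest.approx(x, abs=5e-3)

    def test_too_few_anchors(self):
        with pytest.raises(CalibrationError):
            calibrate_conversion_model(DEFAULT_ANCHORS[:3])

    def test_non_monotone_in_time_rejected(self):
        bad = [
            (500.0, 20.0, 48.0, 0.72),
            (25.0, 20.0, 48.0, 0.26),
            (500.0, 20.0, 96.0, 0.57),  # lower conversion at later time
            (500.0, 10.0, 96.0, 0.54),
        ]
        with pytest.raises(CalibrationError):
            calibrate_conversion_model(bad)

    def test_infeasible_ratio_rejected(self):
        # ratio below t1/t2 cannot come from a shared saturating exponential
        bad = [
            (500.0, 20.0, 48.0, 0.10),
            (25.0, 20.0, 48.0, 0.05),
            (500.0, 20.0, 96.0, 0.90),
            (500.0, 10.0, 96.0, 0.54),
        ]
        with pytest.raises(CalibrationError):
            calibrate_conversion_model(bad)


class TestConversionCurve:
    def test_zero_at_time_zero(self, conversion_params):
        cond = HydrolysisConditions(500.0, 20.0)
        curve = conversion_curve(conversion_params, cond, [0.0, 48.0])
        assert curve.conversion[0] == 0.0

    @pytest.mark.parametrize(
        "rpm,load,t,expected",
        [(500.0, 20.0, 48.0, 0.57), (25.0, 20.0, 48.0, 0.26)],
    )
    def test_printed_anchors(self, conversion_params, rpm, load, t, expected):
        cond = HydrolysisConditions(rpm, load)
        curve = conversion_curve(conversion_params, cond, [t])
        assert curve.conversion[0] == pytest.approx(expected, abs=1e-3)

    def test_extrapolation_warns_but_evaluates(self, conversion_params, caplog):
        cond = HydrolysisConditions(700.0, 20.0)
        with caplog.at_level("WARNING", logger="hydromix.synthetic_data"):
            curve = conversion_curve(conversion_params, cond, [48.0])
        assert "extrapolating" in caplog.text
        assert 0.0 < curve.conversion[0] <= 1.0

    def test_unsorted_grid_rejected(self, conversion_params):
        with pytest.raises(InvalidInputError):
            conversion_curve(conversion_params, HydrolysisConditions(500.0, 20.0), [48.0, 24.0])

    def test_monotone_in_time_speed_and_load(self, conversion_params):
        t = np.linspace(0.0, 96.0, 49)
        speeds = np.linspace(25.0, 500.0, 8)
        loads = np.linspace(10.0, 20.0, 5)
        for n in speeds:
            for e in loads:
                x = conversion_params.conversion(t, n, e)
                assert np.all(np.diff(x) >= 0)
                assert np.all((x >= 0) & (x <= 1))
        for tt in (12.0, 48.0, 96.0):
            xs = [conversion_params.conversion(tt, n, 20.0) for n in speeds]
            assert np.all(np.diff(xs) >= 0)
            xe = [conversion_params.conversion(tt, 500.0, e) for e in loads]
            assert np.all(np.diff(xe) >= 0)


class TestStoichiometry:
    def test_wis_identity_at_zero(self, diluted_composition):
        assert wis_from_conversion(0.0, diluted_composition) == 10.0

    def test_wis_at_072(self, diluted_composition):
        assert wis_from_conversion(0.72, diluted_composition) == pytest.approx(6.544, abs=1e-3)

    def test_wis_at_full_conversion(self, diluted_composition):
        assert wis_from_conversion(1.0, diluted_composition) == pytest.approx(5.2, abs=1e-12)

    def test_wis_out_of_range_rejected(self, diluted_composition):
        for x in (-0.1, 1.1):
            with pytest.raises(InvalidInputError):
                wis_from_conversion(x, diluted_composition)

    def test_glucose_baseline(self, diluted_composition):
        assert glucose_from_conversion(0.0, diluted_composition) == pytest.approx(22.16, abs=0.05)

    def test_glucose_full_release(self, diluted_composition):
        released = glucose_from_conversion(1.0, diluted_composition) - glucose_from_conversion(
            0.0, diluted_composition
        )
        assert released == pytest.approx(48.0 * 180.0 / 162.0, rel=1e-12)
        assert released == pytest.approx(53.3, abs=0.05)

    @given(x=st.floats(0.0, 1.0))
    @settings(max_examples=200)
    def test_round_trip(self, x, diluted_composition):
        conc = glucose_from_conversion(x, diluted_composition)
        assert conversion_from_glucose(conc, diluted_composition) == pytest.approx(
            x, abs=1e-12
        )


class TestNoisySampling:
    @pytest.fixture()
    def curve(self, conversion_params):
        cond = HydrolysisConditions(500.0, 20.0)
        return conversion_curve(conversion_params, cond, np.linspace(0.0, 96.0, 25))

    def test_zero_cv_identity(self, curve, diluted_composition):
        clean = glucose_from_conversion(curve.conversion, diluted_composition)
        noisy = sample_noisy_glucose(curve, diluted_composition, cv=0.0, seed=1)
        assert np.array_equal(noisy, clean)

    def test_seed_reproducibility(self, curve, diluted_composition):
        a = sample_noisy_glucose(curve, diluted_composition, cv=0.04, seed=123)
        b = sample_noisy_glucose(curve, diluted_composition, cv=0.04, seed=123)
        assert np.array_equal(a, b)
        c = sample_noisy_glucose(curve, diluted_composition, cv=0.04, seed=124)
        assert not np.array_equal(a, c)

    def test_empirical_cv(self, curve, diluted_composition):
        clean = glucose_from_conversion(curve.conversion, diluted_composition)
        ratios = []
        for seed in range(1000 // curve.times.size + 1):
            noisy = sample_noisy_glucose(curve, diluted_composition, cv=0.04, seed=seed)
            ratios.extend(noisy / clean - 1.0)
        assert 0.035 <= np.std(ratios) <= 0.045


class TestSimulatePowerObservations:
    def test_zero_noise_exact(self, printed_correlation):
        re = np.logspace(0, 3, 50)
        obs = simulate_power_observations(printed_correlation, re, 0.0)
        assert np.allclose(obs[:, 1], 346.7 / re + 1.27, rtol=1e-14)

    def test_round_trip_fit(self, printed_correlation):
        re = np.logspace(0, 3, 50)
        obs = simulate_power_observations(printed_correlation, re, 0.0, seed=0)
        fit = fit_power_correlation(obs)
        assert fit.k1 == pytest.approx(346.7, rel=1e-8)
        assert fit.k2 == pytest.approx(1.27, rel=1e-8)

    def test_noisy_recovery_seed42(self, printed_correlation):
        re = np.logspace(-0.3, 3.7, 200)
        obs = simulate_power_observations(printed_correlation, re, 0.05, seed=42)
        fit = fit_power_correlation(obs)
        assert fit.k1 == pytest.approx(346.7, rel=0.05)

    def test_seeded_determinism(self, printed_correlation):
        re = np.logspace(0, 3, 20)
        a = simulate_power_observations(printed_correlation, re, 0.05, seed=9)
        b = simulate_power_observations(printed_correlation, re, 0.05, seed=9)
        assert np.array_equal(a, b)
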