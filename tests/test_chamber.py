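"""Chamber dose chain, saturation-curve analysis and recombination estimators."""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flashcal.chamber import (
    ChamberReading,
    ChamberSpec,
    SaturationCurve,
    air_density_correction,
    dose_from_chamber,
    jaffe_classify,
    k_ion_three_voltage,
    k_ion_two_voltage_continuous,
    k_ion_two_voltage_from_curve,
    k_polarity,
    k_tp,
    load_chamber_registry,
    normalize_saturation,
    ratio_summary,
    ratio_to_calorimeter,
)
from flashcal.errors import (
    ConfigurationError,
    InsufficientDataError,
    NonPhysicalValueError,
)
from flashcal.synthetic import CurveRecipe, curve_recipe_for_k_ion, gen_saturation_curve


def spec_with(**kw):
    base = dict(
        name="test",
        geometry="plane-parallel",
        volume_cm3=0.35,
        electrode_spacing_mm=2.0,
        n_dw_gy_per_c=1e9,
        k_q=1.0,
    )
    base.update(kw)
    return ChamberSpec(**base)


class TestAirDensityCorrection:
    def test_reference_conditions_give_unity(self):
        assert air_density_correction(293.2, 1013.3, 293.2) == 1.0

    def test_nist_conditions_against_npl_reference(self):
        assert air_density_correction(295.2, 1013.3, 293.2) == pytest.approx(1.00682, abs=1e-5)

    def test_halving_pressure_doubles_factor(self):
        base = air_density_correction(295.0, 1000.0, 293.2)
        assert air_density_correction(295.0, 500.0, 293.2) == pytest.approx(2 * base)

    def test_k_tp_uses_chamber_reference(self):
        reading = ChamberReading(-1e-9, -400.0, 295.2, 1013.3)
        assert k_tp(reading, spec_with(ref_temperature_K=295.2)) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(NonPhysicalValueError):
            air_density_correction(-1.0, 1000.0, 293.2)


class TestPolarity:
    def test_symmetric_response_is_unity(self):
        assert k_polarity(1.0, -1.0, -1.0) == 1.0

    def test_roos_like_magnitude(self):
        assert k_polarity(1.004, 1.000, 1.000) == pytest.approx(1.002)

    def test_farmer_like_magnitude(self):
        assert k_polarity(0.936, 1.000, 1.000) == pytest.approx(0.968)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(m=st.floats(0.1, 10.0))
    def test_sign_insensitive(self, m):
        assert k_polarity(m, -m, m) == pytest.approx(1.0)

    def test_zero_operating_reading_raises(self):
        with pytest.raises(NonPhysicalValueError):
            k_polarity(1.0, 1.0, 0.0)


class TestSaturationCurve:
    def test_normalisation_example(self):
        c = SaturationCurve([200.0, 400.0], [0.95, 1.90])
        n = normalize_saturation(c)
        assert n.readings == pytest.approx([0.5, 1.0])
        assert n.normalized

    def test_single_point_maps_to_one(self):
        n = normalize_saturation(SaturationCurve([400.0], [2.7]))
        assert n.readings[0] == 1.0

    def test_idempotent(self):
        c = SaturationCurve([100.0, 200.0, 400.0], [0.8, 0.95, 1.9])
        once = normalize_saturation(c)
        twice = normalize_saturation(once)
        assert twice.readings == pytest.approx(once.readings)

    def test_duplicate_voltages_rejected(self):
        with pytest.raises(NonPhysicalValueError):
            SaturationCurve([200.0, 200.0], [1.0, 1.0])


class TestJaffeClassification:
    def test_quadratic_model_classified_continuous(self):
        v = np.array([100.0, 150.0, 200.0, 250.0, 300.0, 400.0])
        m = 1.0 / (1.0 + 8000.0 / v**2)
        res = jaffe_classify(SaturationCurve(v, m))
        assert res.beam_class == "continuous"
        assert res.quadratic.coefficients[2] > 0

    def test_linear_model_classified_pulsed(self):
        v = np.array([100.0, 150.0, 200.0, 250.0, 300.0, 400.0])
        m = 1.0 / (1.0 + 20.0 / v)
        res = jaffe_classify(SaturationCurve(v, m))
        assert res.beam_class == "pulsed"

    def test_noisy_continuous_data_classified_reliably(self):
        # 0.1% reading noise, 6 voltages, >= 95% correct over 200 seeds
        v = (100.0, 150.0, 200.0, 250.0, 300.0, 400.0)
        recipe = curve_recipe_for_k_ion(1.05, 400.0, voltages=v, rel_noise_sd=1e-3)
        hits = 0
        for seed in range(200):
            curve, _ = gen_saturation_curve(recipe, seed=seed)
            if jaffe_classify(curve).beam_class == "continuous":
                hits += 1
        assert hits >= 190

    def test_too_few_points_raises(self):
        with pytest.raises(InsufficientDataError):
            jaffe_classify(SaturationCurve([100.0, 200.0, 400.0], [0.9, 0.95, 1.0]))


class TestTwoVoltage:
    def test_saturated_readings_give_unity(self):
        est = k_ion_two_voltage_continuous(1.0, 400.0, 1.0, 200.0)
        assert est.k_ion == pytest.approx(1.0)
        assert est.method == "two-voltage"

    def test_exact_under_general_recombination_model(self):
        # true k_ion(400 V) = 1.039 (a Roos-like magnitude)
        xi2 = 0.039 * 400.0**2
        m = lambda v: 1.0 / (1.0 + xi2 / v**2)
        est = k_ion_two_voltage_continuous(m(400.0), 400.0, m(200.0), 200.0)
        assert est.k_ion == pytest.approx(1.039, abs=1e-12)

    def test_analytically_exact_for_random_parameters(self):
        # exactness of the quadratic expression under its own model, V1/V2 = 2
        rng = np.random.default_rng(123)
        for _ in range(100):
            v1 = rng.uniform(100.0, 1000.0)
            k_true = rng.uniform(1.0005, 1.3)
            xi2 = (k_true - 1.0) * v1**2
            m = lambda v: 1.0 / (1.0 + xi2 / v**2)
            est = k_ion_two_voltage_continuous(m(v1), v1, m(v1 / 2), v1 / 2)
            assert abs(est.k_ion / k_true - 1.0) < 1e-10

    def test_near_pole_is_flagged(self):
        r2 = 4.0
        est = k_ion_two_voltage_continuous(1.0, 400.0, 1.0 / (r2 * (1 - 1e-6)), 200.0)
        assert est.flagged and est.k_ion > 2.0

    def test_beyond_pole_raises(self):
        with pytest.raises(NonPhysicalValueError):
            k_ion_two_voltage_continuous(4.1, 400.0, 1.0, 200.0)

    def test_equal_voltages_raise(self):
        with pytest.raises(NonPhysicalValueError):
            k_ion_two_voltage_continuous(1.0, 400.0, 1.0, 400.0)


class TestThreeVoltage:
    def test_model_in_model_recovery(self):
        xi2 = 5000.0
        v = np.array([200.0, 300.0, 400.0])
        m = 1.0 / (1.0 + xi2 / v**2)
        est = k_ion_three_voltage(SaturationCurve(v, m), v_op=400.0)
        a, b, c = est.coefficients
        assert abs(b) < 1e-9
        assert est.k_ion == pytest.approx(1.0 + xi2 / 400.0**2, rel=1e-10)
        assert est.m_sat == pytest.approx(1.0, rel=1e-10)

    def test_combined_model_accuracy_below_half_percent(self):
        # small initial-recombination share; fit at 400/300/200 V
        for k_true in (1.02, 1.05, 1.10, 1.25):
            recipe = curve_recipe_for_k_ion(
                k_true, 400.0, initial_fraction=0.03,
                voltages=(200.0, 300.0, 400.0), rel_noise_sd=0.0,
            )
            curve, truth = gen_saturation_curve(recipe)
            est = k_ion_three_voltage(curve, v_op=400.0)
            assert abs(est.k_ion / truth.k_ion(400.0) - 1.0) < 5e-3

    def test_saturated_curve_gives_unity(self):
        v = np.array([200.0, 300.0, 400.0])
        est = k_ion_three_voltage(SaturationCurve(v, np.full(3, 2.5)), v_op=400.0)
        assert est.k_ion == pytest.approx(1.0)

    def test_estimated_correction_nonincreasing_in_voltage(self):
        recipe = curve_recipe_for_k_ion(
            1.15, 400.0, initial_fraction=0.2,
            voltages=(150.0, 200.0, 300.0, 400.0, 500.0, 600.0), rel_noise_sd=0.0,
        )
        curve, _ = gen_saturation_curve(recipe)
        ks = [k_ion_three_voltage(curve, v_op=v, n_points=6).k_ion for v in (200.0, 300.0, 400.0, 600.0)]
        assert all(k1 >= k2 - 1e-12 for k1, k2 in zip(ks, ks[1:]))

    def test_nonphysical_intercept_raises(self):
        # 1/M = 400/V - 0.5 exactly: the fitted intercept is -0.5
        v = np.array([200.0, 300.0, 400.0])
        m = 1.0 / (400.0 / v - 0.5)
        with pytest.raises(NonPhysicalValueError):
            k_ion_three_voltage(SaturationCurve(v, m), v_op=400.0)

    def test_insufficient_points_raise(self):
        with pytest.raises(InsufficientDataError):
            k_ion_three_voltage(SaturationCurve([300.0, 400.0], [0.9, 1.0]), v_op=400.0)


class TestMethodDivergence:
    def test_three_voltage_beats_two_voltage_at_high_recombination(self):
        """At >= 5% recombination the high-voltage-fit estimator is closer to
        truth than the two-voltage formula, which leans on near-saturation
        linearity that no longer holds."""
        rng = np.random.default_rng(2024)
        wins = 0
        n = 50
        for _ in range(n):
            k_true = rng.uniform(1.05, 1.25)
            recipe = curve_recipe_for_k_ion(
                k_true, 400.0, initial_fraction=0.3,
                voltages=(200.0, 300.0, 400.0, 500.0, 600.0),
            )
            curve, truth = gen_saturation_curve(recipe, seed=int(rng.integers(2**31)))
            two = k_ion_two_voltage_from_curve(curve, v_op=400.0)
            three = k_ion_three_voltage(curve, v_op=400.0, n_points=3)
            kt = truth.k_ion(400.0)
            if abs(three.k_ion - kt) < abs(two.k_ion - kt):
                wins += 1
        assert wins >= int(0.9 * n)


class TestDoseChain:
    def test_unit_chain(self):
        reading = ChamberReading(1e-9, -400.0, 293.2, 1013.3)
        spec = spec_with()
        assert dose_from_chamber(reading, spec, 1.0, 1.0) == pytest.approx(1.0)

    def test_linear_in_each_correction(self):
        reading = ChamberReading(1e-9, -400.0, 293.2, 1013.3)
        spec = spec_with()
        assert dose_from_chamber(reading, spec, 1.039, 1.0) == pytest.approx(1.039)
        assert dose_from_chamber(reading, spec, 1.039, 1.002) == pytest.approx(1.039 * 1.002)

    def test_negative_charge_magnitude_used(self):
        pos = ChamberReading(1e-9, 400.0, 293.2, 1013.3)
        neg = ChamberReading(-1e-9, -400.0, 293.2, 1013.3)
        spec = spec_with()
        assert dose_from_chamber(pos, spec, 1.0, 1.0) == dose_from_chamber(neg, spec, 1.0, 1.0)

    def test_nonpositive_correction_rejected(self):
        reading = ChamberReading(1e-9, -400.0, 293.2, 1013.3)
        with pytest.raises(NonPhysicalValueError):
            dose_from_chamber(reading, spec_with(), 0.0, 1.0)


class TestRatios:
    def test_values(self):
        assert ratio_to_calorimeter(7.8, 7.8) == 1.0
        assert ratio_to_calorimeter(7.8, 7.746) == pytest.approx(1.007, abs=5e-4)
        assert ratio_to_calorimeter(7.8, 8.150) == pytest.approx(0.957, abs=5e-4)

    def test_summary(self):
        mean, se = ratio_summary([1.0, 1.0, 1.0])
        assert mean == 1.0 and se == 0.0
        mean, se = ratio_summary([0.98])
        assert mean == 0.98 and se is None

    def test_zero_denominator_raises(self):
        with pytest.raises(NonPhysicalValueError):
            ratio_to_calorimeter(7.8, 0.0)


class TestRegistry:
    def test_shipped_registry(self):
        reg = load_chamber_registry()
        assert len(reg) == 5
        roos = reg["PTW-34001 Roos"]
        assert roos.geometry == "plane-parallel"
        assert roos.ref_temperature_K == 293.2
        markus = reg["PTW-34045 Advanced Markus"]
        assert markus.ref_temperature_K == 295.2  # NIST-calibrated
        farmer = reg["PTW-30013 Farmer"]
        assert farmer.geometry == "cylindrical"

    def test_bad_geometry_rejected(self):
        with pytest.raises(ConfigurationError):
            spec_with(geometry="spherical")
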