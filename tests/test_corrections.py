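"""Correction factors, |F_h|, contrast-variation phasing, absolute scale."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sandlam import corrections, synthetic
from sandlam.models import BilayerModel, CompositionConfig, ContrastSpec, InstrumentConfig


class TestLorentzFactor:
    def test_known_values(self):
        assert corrections.lorentz_factor(math.radians(45)) == pytest.approx(1.0)
        assert corrections.lorentz_factor(math.radians(15)) == pytest.approx(2.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(1.0, 89.0))
    def test_matches_reciprocal_sine(self, theta_deg):
        th = math.radians(theta_deg)
        assert corrections.lorentz_factor(th) == pytest.approx(1 / math.sin(2 * th))

    def test_singular_angles_rejected(self):
        for th in (0.0, math.pi / 2):
            with pytest.raises(ValueError):
                corrections.lorentz_factor(th)


class TestAbsorptionFactor:
    def test_no_absorption_limit(self):
        assert corrections.absorption_factor(0.3, 0.0, 0.1) == pytest.approx(1.0)
        # series branch: tiny mu agrees with 1 to better than 1e-8 relative
        assert abs(corrections.absorption_factor(0.3, 1e-9, 0.001) - 1.0) < 1e-8

    def test_closed_form_at_unit_argument(self):
        # choose mu, t, theta with 2*mu*t/sin(theta) = 1
        theta = math.asin(0.5)
        val = corrections.absorption_factor(theta, 1.0, 0.25)
        assert val == pytest.approx(1 - math.exp(-1), rel=1e-12)

    def test_series_branch_matches_exact_form(self):
        # just below the series threshold the Taylor branch agrees with the
        # closed form to float precision
        theta = 0.4
        for frac in (0.999, 0.5, 0.1):
            mu = frac * corrections._SERIES_THRESHOLD * math.sin(theta) / 2
            x = 2 * mu / math.sin(theta)
            exact = (1 - math.exp(-x)) / x
            assert corrections.absorption_factor(theta, mu, 1.0) == pytest.approx(
                exact, rel=1e-12)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(0.05, 1.4))
    def test_monotone_decreasing_in_mu(self, theta):
        mus = np.linspace(0.0, 50.0, 40)
        vals = [corrections.absorption_factor(theta, mu, 0.01) for mu in mus]
        assert all(a >= b for a, b in zip(vals, vals[1:]))
        assert all(0 < v <= 1 for v in vals)


class TestFluxFactor:
    def test_full_illumination_limit(self):
        assert corrections.flux_factor(1.0, 1e5, 1.0) == pytest.approx(1.0)

    def test_zero_argument(self):
        assert corrections.flux_factor(1e-12, 65.0, 1.25) == pytest.approx(0.0, abs=1e-10)

    def test_matches_series_evaluation(self):
        """Independent erf oracle: Taylor series of the error function."""
        def erf_series(x, terms=40):
            return 2 / math.sqrt(math.pi) * sum(
                (-1) ** n * x ** (2 * n + 1) / (math.factorial(n) * (2 * n + 1))
                for n in range(terms))
        for theta in (0.02, 0.1, 0.5):
            got = corrections.flux_factor(theta, 65.0, 10.0)
            assert got == pytest.approx(erf_series(65.0 * math.sin(theta) / 80.0),
                                        rel=1e-9)

    def test_monotone_in_l_sin_theta(self):
        thetas = np.linspace(0.01, 0.5, 50)  # unsaturated range
        vals = [corrections.flux_factor(t, 65.0, 1.25) for t in thetas]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_sqrt8_variant(self):
        a = corrections.flux_factor(0.1, 65.0, 1.25, "8sigma")
        b = corrections.flux_factor(0.1, 65.0, 1.25, "sqrt8_sigma")
        assert b > a  # smaller denominator, larger argument


class TestStructureFactorMagnitude:
    def test_simple_arithmetic(self):
        f, _ = corrections.structure_factor_magnitude(4.0, 1.0, 1.0, 1.0)
        assert f == 2.0

    def test_zero_intensity_flagged_infinite_uncertainty(self):
        f, sig = corrections.structure_factor_magnitude(0.0, 1.0, 1.0, 1.0, 1.0)
        assert f == 0.0 and math.isinf(sig)

    def test_zero_corrections_rejected(self):
        with pytest.raises(ValueError):
            corrections.structure_factor_magnitude(1.0, 0.0, 1.0, 1.0)


class TestForwardScattering:
    def test_contrast_match_gives_zero(self):
        comp = CompositionConfig(mole_ratio_x=0.0)
        rho_match = 10.0 * comp.b_total / comp.v_total
        c = ContrastSpec(0.5, rho_match)
        assert corrections.forward_scattering(comp, 60.0, c) == pytest.approx(0.0)

    def test_arithmetic_identity(self):
        comp = CompositionConfig(b_lipid=10.0, v_lipid=40.0, mole_ratio_x=0.0)
        c = ContrastSpec(0.5, 1.0)  # rho_w * V_l = 40
        # (10*10 - 1*40)/60 = 1
        assert corrections.forward_scattering(comp, 60.0, c) == pytest.approx(1.0)

    def test_doubling_area_halves_f0(self):
        comp = CompositionConfig()
        c = ContrastSpec.from_d2o_fraction(0.5)
        assert corrections.forward_scattering(comp, 120.0, c) == pytest.approx(
            corrections.forward_scattering(comp, 60.0, c) / 2)


def _reduced(model, contrasts, instrument, noise, seed, hmax=5):
    table = synthetic.simulate_peak_table(model, contrasts, hmax, instrument,
                                          noise, seed)
    red = corrections.magnitudes_from_table(table, instrument)
    f0 = np.array([synthetic.true_f0abs(model, c) for c in contrasts])
    return red, f0


def _true_signs(model, contrasts, hmax=5):
    F = np.array([synthetic.theoretical_structure_factors(
        synthetic.model_profile(model, c), hmax)[1:] for c in contrasts])
    return np.where(F >= 0, 1, -1), F


class TestAssignSigns:
    def test_recovers_forward_model_signs(self, default_model, contrasts,
                                          instrument):
        red, f0 = _reduced(default_model, contrasts, instrument, 0.0, 1)
        a = corrections.assign_signs(red["magnitudes"], red["water_nslds"],
                                     default_model.lattice_D, f0abs=f0)
        truth, _ = _true_signs(default_model, contrasts)
        np.testing.assert_array_equal(a.signs, truth)

    def test_null_order_flagged_indeterminate(self, contrasts):
        mags = np.array([[10.0, 0.0], [20.0, 0.0], [50.0, 0.0]])
        x = np.array([c.water_nsld for c in contrasts])
        a = corrections.assign_signs(mags, x, 55.0)
        assert 2 in a.indeterminate_orders

    def test_invariant_under_contrast_relabeling_and_rescaling(
            self, default_model, contrasts, instrument):
        red, f0 = _reduced(default_model, contrasts, instrument, 0.0, 1)
        a = corrections.assign_signs(red["magnitudes"], red["water_nslds"],
                                     default_model.lattice_D, f0abs=f0)
        perm = [2, 0, 1]
        b = corrections.assign_signs(3.7 * red["magnitudes"][perm],
                                     red["water_nslds"][perm],
                                     default_model.lattice_D, f0abs=f0[perm])
        np.testing.assert_array_equal(a.signs[perm], b.signs)

    def test_water_positive_at_edge_convention(self, default_model, contrasts,
                                               instrument):
        """The resolved slopes describe water increasing towards the edge."""
        red, f0 = _reduced(default_model, contrasts, instrument, 0.0, 1)
        a = corrections.assign_signs(red["magnitudes"], red["water_nslds"],
                                     default_model.lattice_D, f0abs=f0)
        D = default_model.lattice_D
        z = np.linspace(-D / 2, D / 2, 401)
        h = np.arange(1, 6)
        s = a.slopes @ np.cos(2 * np.pi * np.outer(h, z) / D)
        assert s[np.abs(z) > 0.45 * D].mean() > s[np.abs(z) < 0.05 * D].mean()

    def test_requires_two_contrasts(self):
        with pytest.raises(ValueError):
            corrections.assign_signs(np.ones((1, 3)), np.array([1.0]), 55.0)


class TestAbsoluteScale:
    def test_noiseless_round_trip_within_one_percent(self, default_model,
                                                     contrasts, instrument):
        red, f0 = _reduced(default_model, contrasts, instrument, 0.0, 1)
        truth, F = _true_signs(default_model, contrasts)
        signed = truth * red["magnitudes"]
        k = corrections.absolute_scale(signed, red["water_nslds"], f0,
                                       default_model.lattice_D)
        assert k == pytest.approx(synthetic.true_scale_k(), rel=0.01)

    def test_scale_covariance(self, default_model, contrasts, instrument):
        red, f0 = _reduced(default_model, contrasts, instrument, 0.0, 1)
        truth, _ = _true_signs(default_model, contrasts)
        signed = truth * red["magnitudes"]
        x = red["water_nslds"]
        D = default_model.lattice_D
        k1 = corrections.absolute_scale(signed, x, f0, D)
        k2 = corrections.absolute_scale(2 * signed, x, f0, D)
        assert k2 == pytest.approx(2 * k1, rel=1e-6)

    def test_identical_contrasts_no_leverage(self):
        F = np.random.default_rng(0).normal(size=(2, 5))
        with pytest.raises(ValueError, match="leverage"):
            corrections.absolute_scale(F, np.array([1.0, 1.0]),
                                       np.zeros(2), 55.0)

    def test_single_order_insufficient(self):
        with pytest.raises(ValueError, match="too few"):
            corrections.absolute_scale(np.ones((2, 1)), np.array([0.0, 2.0]),
                                       np.zeros(2), 55.0)


class TestSignRecoveryRegression:
    @pytest.mark.parametrize("noise,min_rate", [(0.0, 1.0), (0.01, 1.0),
                                                (0.05, 0.8)])
    def test_recovery_rate_across_noise(self, contrasts, instrument, noise,
                                        min_rate):
        """Documented regression: sign recovery on a standard 5-order model."""
        model = BilayerModel()
        f0 = np.array([synthetic.true_f0abs(model, c) for c in contrasts])
        truth, _ = _true_signs(model, contrasts)
        ok = 0
        n = 20
        for s in range(n):
            table = synthetic.simulate_peak_table(model, contrasts, 5,
                                                  instrument, noise, seed=s)
            red = corrections.magnitudes_from_table(table, instrument)
            a = corrections.assign_signs(red["magnitudes"], red["water_nslds"],
                                         model.lattice_D, f0abs=f0)
            ok += int(np.array_equal(a.signs, truth))
        assert ok >= min_rate * n
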