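"""Forward-model generator: profiles, structure factors, peak tables, frames."""

import numpy as np
import pytest

from sandlam import constants, synthetic
from sandlam.models import BilayerModel, ContrastSpec, InstrumentConfig


class TestWaterNSLD:
    def test_monotone_in_d2o_fraction(self):
        fracs = np.linspace(0, 1, 11)
        vals = [constants.water_nsld(f) for f in fracs]
        assert np.all(np.diff(vals) > 0)

    def test_match_point_nulls_water(self):
        assert constants.water_nsld(constants.D2O_MATCH_FRACTION) == pytest.approx(0.0, abs=1e-12)
        # the paper's 8% D2O water-nulling contrast is the match point
        assert constants.D2O_MATCH_FRACTION == pytest.approx(0.08, abs=0.005)

    def test_endpoints_from_scattering_lengths(self):
        # pure H2O / D2O NSLDs follow from b and V directly
        assert constants.water_nsld(0.0) == pytest.approx(10 * constants.B_H2O / 30.0)
        assert constants.water_nsld(1.0) == pytest.approx(10 * constants.B_D2O / 30.0)


class TestModelProfile:
    def test_null_model_is_flat_zero(self):
        m = BilayerModel(headgroup_amplitude=0.0, methyl_amplitude=0.0,
                         chain_plateau=0.0)
        p = synthetic.model_profile(m, ContrastSpec(0.08, 0.0))
        assert np.allclose(p.rho, 0.0)

    def test_centrosymmetric_by_construction(self, default_model, contrasts):
        for c in contrasts:
            p = synthetic.model_profile(default_model, c)
            assert np.array_equal(p.rho, p.rho[::-1])

    def test_contrast_differences_proportional_to_water_term(self, default_model):
        """Profiles at several contrasts differ exactly by Δρ_w·w(z)."""
        cs = [ContrastSpec.from_d2o_fraction(f) for f in (0.08, 0.20, 0.50)]
        ps = [synthetic.model_profile(default_model, c) for c in cs]
        w_oracle = synthetic.water_fraction(ps[0].z, default_model)
        for a, b in ((0, 1), (0, 2), (1, 2)):
            dn = cs[a].water_nsld - cs[b].water_nsld
            np.testing.assert_allclose(ps[a].rho - ps[b].rho, dn * w_oracle,
                                       rtol=0, atol=1e-12)

    def test_water_term_integrates_to_geometric_volume(self, default_model):
        m = default_model
        p = synthetic.model_profile(m, ContrastSpec(0.5, 1.0), 0.05)
        w = synthetic.water_fraction(p.z, m)
        # exact up to the (sub-1e-4) unterminated erf tail at the cell edge
        assert np.trapezoid(w, p.z) == pytest.approx(
            m.lattice_D - 2 * m.interface_position, abs=1e-3)

    def test_nonphysical_model_rejected(self):
        with pytest.raises(ValueError):
            BilayerModel(headgroup_sigma=-1.0)
        with pytest.raises(ValueError):
            BilayerModel(interface_position=40.0, lattice_D=55.0)


class TestTheoreticalStructureFactors:
    def test_flat_profile(self):
        m = BilayerModel(headgroup_amplitude=0.0, methyl_amplitude=0.0,
                         chain_plateau=0.0)
        c = ContrastSpec(0.5, 0.0)
        p = synthetic.model_profile(m, c)
        p.rho = np.full_like(p.rho, 3.0)
        F = synthetic.theoretical_structure_factors(p, 5)
        assert F[0] == pytest.approx(3.0 * p.D, rel=1e-12)
        assert np.allclose(F[1:], 0.0, atol=1e-9)

    def test_single_cosine_mode(self):
        m = BilayerModel()
        p = synthetic.model_profile(m, ContrastSpec(0.5, 0.0))
        p.rho = 2.5 * np.cos(2 * np.pi * p.z / p.D)
        F = synthetic.theoretical_structure_factors(p, 4)
        assert F[1] == pytest.approx(2.5 * p.D / 2, rel=1e-9)
        mask = np.ones(5, bool)
        mask[1] = False
        assert np.allclose(F[mask], 0.0, atol=1e-8 * abs(F[1]))

    def test_refinement_oracle(self):
        """Trapezoid refinement at half the spacing changes nothing to 1e-6."""
        # model whose features decay inside the cell, so the quadrature is
        # resolution-limited, not boundary-limited
        m = BilayerModel(headgroup_position=15.0, headgroup_sigma=2.5,
                         interface_position=17.5, interface_width=2.0,
                         lattice_D=60.0)
        c = ContrastSpec.from_d2o_fraction(0.08)
        F = synthetic.theoretical_structure_factors(
            synthetic.model_profile(m, c, 0.5), 6)
        z_fine = synthetic.unit_cell_grid(m.lattice_D, 0.25)
        p_fine = synthetic.model_profile(m, c, 0.25)
        h = np.arange(0, 7)
        oracle = np.trapezoid(
            np.cos(2 * np.pi * np.outer(h, z_fine) / m.lattice_D)
            * p_fine.rho[None, :], z_fine, axis=1)
        np.testing.assert_allclose(F, oracle, rtol=0,
                                   atol=1e-6 * np.max(np.abs(oracle)))


class TestSimulatePeakTable:
    def test_deterministic_from_seed(self, default_model, contrasts, instrument):
        t1 = synthetic.simulate_peak_table(default_model, contrasts, 5,
                                           instrument, 0.05, seed=42)
        t2 = synthetic.simulate_peak_table(default_model, contrasts, 5,
                                           instrument, 0.05, seed=42)
        assert t1.equals(t2)

    def test_bragg_angles_closed_form(self, instrument):
        lam = instrument.wavelength
        m = BilayerModel(lattice_D=50.0, interface_position=19.5,
                         headgroup_position=18.2)
        table = synthetic.simulate_peak_table(
            m, [ContrastSpec.from_d2o_fraction(0.5)], 5, instrument, 0.0, 0)
        for h in range(1, 6):
            expected = 2.0 * np.degrees(np.arcsin(h * lam / (2 * 50.0)))
            got = table.loc[table.order_h == h, "two_theta_deg"].iloc[0]
            assert got == pytest.approx(expected, rel=1e-12)
            # inverse map: Bragg equation returns D = 50
            theta = np.radians(got / 2)
            assert h * lam / (2 * np.sin(theta)) == pytest.approx(50.0, rel=1e-12)

    def test_undefined_reflection_dropped_with_warning(self, instrument):
        m = BilayerModel(lattice_D=52.0, interface_position=20)
        # order 23: h*lambda/2D > 1 at lambda=4.5707, D=52
        with pytest.warns(UserWarning, match="Bragg angle undefined"):
            t = synthetic.simulate_peak_table(
                m, [ContrastSpec.from_d2o_fraction(0.5)], 23, instrument, 0.0, 0)
        assert t.order_h.max() == 22

    def test_noiseless_magnitude_round_trip(self, default_model, contrasts, instrument):
        """Reduction recovers k·|F_h| exactly from a noiseless table."""
        from sandlam import corrections
        table = synthetic.simulate_peak_table(default_model, contrasts, 5,
                                              instrument, 0.0, 0)
        red = corrections.magnitudes_from_table(table, instrument)
        k = synthetic.true_scale_k()
        for i, c in enumerate(contrasts):
            F = synthetic.theoretical_structure_factors(
                synthetic.model_profile(default_model, c), 5)
            np.testing.assert_allclose(red["magnitudes"][i], k * np.abs(F[1:]),
                                       rtol=1e-9)


class TestSyntheticFrames:
    def test_aligned_endpoint(self):
        frames = synthetic.synthetic_frames(2000, (100, 100, 100), 1.0, seed=1)
        from sandlam.order import order_parameter
        res = order_parameter(frames, [("C1A", "C2A")])[("C1A", "C2A")]
        assert res.p2 == pytest.approx(1.0, abs=1e-12)

    def test_perpendicular_endpoint(self):
        frames = synthetic.synthetic_frames(2000, (100, 100, 100), -0.5, seed=1)
        from sandlam.order import order_parameter
        res = order_parameter(frames, [("C1A", "C2A")])[("C1A", "C2A")]
        assert res.p2 == pytest.approx(-0.5, abs=1e-12)

    def test_isotropic_within_sampling_error(self):
        n_bonds = 20000
        frames = synthetic.synthetic_frames(2 * n_bonds, (200, 200, 200), 0.0,
                                            seed=3)
        from sandlam.order import order_parameter
        res = order_parameter(frames, [("C1A", "C2A")])[("C1A", "C2A")]
        # Var(P2) for an isotropic bond is 1/5 (Monte-Carlo-verified closed form)
        se = np.sqrt(0.2 / n_bonds)
        assert abs(res.p2) < 3 * se

    def test_impossible_target_rejected(self):
        with pytest.raises(ValueError):
            synthetic.synthetic_frames(100, (50, 50, 50), 1.2)
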