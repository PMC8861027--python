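"""Hand-checked values and closure properties of the biophysical inversions."""

import numpy as np
import pytest

from fluxdry import biophysics as bp
from fluxdry.errors import GeometryError
from fluxdry.lightresponse import fit_light_response, fit_light_response_windows, lrc_nee


class TestAerodynamicResistance:
    def test_hand_value(self):
        # ln((30 - 6.7)/1)^2 / (3 * 0.16)
        assert bp.aerodynamic_resistance(3.0, 30.0, 10.0) == pytest.approx(20.6516, abs=1e-3)

    def test_inverse_wind_proportionality(self):
        assert bp.aerodynamic_resistance(6.0, 30.0, 10.0) == pytest.approx(
            bp.aerodynamic_resistance(3.0, 30.0, 10.0) / 2.0)

    def test_tower_below_roughness_height_rejected(self):
        with pytest.raises(GeometryError):
            bp.aerodynamic_resistance(3.0, 7.7, 10.0)  # zm == zd + z0

    def test_array_input_degrades_to_nan(self):
        ra = bp.aerodynamic_resistance(np.array([3.0, -1.0]), 30.0, 10.0)
        assert np.isfinite(ra[0]) and np.isnan(ra[1])


class TestCanopyHeight:
    def test_hand_value(self):
        # 30 / (0.6 + 0.1 * e^4)
        assert bp.canopy_height(5.0, 0.5, 30.0) == pytest.approx(4.9506, abs=1e-3)

    def test_calm_limit(self):
        assert bp.canopy_height(1e-9, 0.5, 30.0) == pytest.approx(30.0 / 0.7, rel=1e-6)

    def test_height_scales_with_tower(self):
        h1 = bp.canopy_height(5.0, 0.5, 30.0)
        h2 = bp.canopy_height(5.0, 0.5, 60.0)
        assert h2 == pytest.approx(2 * h1)

    def test_zero_ustar_rejected(self):
        with pytest.raises(GeometryError):
            bp.canopy_height(5.0, 0.0, 30.0)

    def test_large_exponent_overflow_guarded(self):
        assert np.isnan(bp.canopy_height(np.array([200.0]), np.array([1.0]), 30.0))[0] or \
            np.isnan(bp.canopy_height(np.array([200.0]), np.array([1.0]), 30.0)[0])


class TestPenmanMonteith:
    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        n = 200
        gc = rng.uniform(1e-3, 0.05, n)
        ra = rng.uniform(5, 120, n)
        avail = rng.uniform(50, 600, n)
        ta = rng.uniform(5, 35, n)
        vpd = rng.uniform(0.2, 4.0, n)
        le = bp.penman_monteith_forward(gc, ra, avail, ta, vpd)
        back = bp.invert_penman_monteith(le, avail, 0.0, ta, vpd, ra)
        np.testing.assert_allclose(back, gc, rtol=1e-10)

    def test_specific_round_trip_case(self):
        le = bp.penman_monteith_forward(0.01, 20.0, 400.0, 25.0, 1.5)
        gc = bp.invert_penman_monteith(le, 400.0, 0.0, 25.0, 1.5, 20.0)
        assert gc == pytest.approx(0.01, rel=1e-8)

    def test_lower_evaporation_means_lower_conductance(self):
        ta, ra, avail, vpd = 25.0, 20.0, 450.0, 1.5
        delta = bp.svp_slope(ta)
        gamma = bp.psychrometric_constant(ta)
        rho = bp.air_density(ta)
        le_max = (delta * avail + rho * bp.CONST.cp * vpd / ra) / (delta + gamma)
        les = np.linspace(50, 0.95 * le_max, 20)
        gcs = bp.invert_penman_monteith(les, avail, 0.0, ta, vpd, ra)
        assert np.all(np.isfinite(gcs)) and np.all(np.diff(gcs) > 0)

    def test_equilibrium_evaporation_with_no_demand_is_degenerate(self):
        # le equal to the radiative term alone as vpd -> 0: implied gc <= 0
        ta, ra, avail = 25.0, 20.0, 400.0
        delta = bp.svp_slope(ta)
        gamma = bp.psychrometric_constant(ta)
        le_eq = delta * avail / (delta + gamma)
        assert np.isnan(bp.invert_penman_monteith(le_eq, avail, 0.0, ta, 0.0, ra))

    def test_nonpositive_le_flagged_missing(self):
        assert np.isnan(bp.invert_penman_monteith(-5.0, 400.0, 0.0, 25.0, 1.5, 20.0))


class TestUnits:
    def test_molar_density_hand_value(self):
        assert bp.molar_density(25.0, 101.325) == pytest.approx(40.87, abs=0.01)

    def test_conversion_consistency(self):
        gc_ms = 0.01
        gc_mol = bp.gc_ms_to_mol(gc_ms, 25.0)
        assert gc_mol == pytest.approx(0.4088, abs=1e-3)


class TestFicksLaw:
    def test_no_uptake_means_ambient(self):
        assert bp.leaf_internal_co2(0.0, 0.4) == pytest.approx(400.0)

    def test_hand_value(self):
        assert bp.leaf_internal_co2(20.0, 0.4, 0.0) == pytest.approx(320.0)

    def test_infinite_conductance_limit(self):
        assert bp.leaf_internal_co2(20.0, 1e9, 0.0) == pytest.approx(400.0, abs=1e-4)

    def test_closed_stomata_flagged(self):
        assert np.isnan(bp.leaf_internal_co2(20.0, 0.0))


class TestFarquhar:
    def test_hand_value_at_25C(self):
        vcmax, vcmax25 = bp.invert_vcmax(20.0, 320.0, 25.0)
        k = 404.9 * (1 + 210.0 / 278.4)
        expect = 20.0 * (320.0 + k) / (320.0 - 42.75)
        assert vcmax == pytest.approx(expect, rel=1e-12)
        assert vcmax == pytest.approx(74.32, abs=0.01)

    def test_zero_assimilation(self):
        vcmax, _ = bp.invert_vcmax(0.0, 320.0, 25.0)
        assert vcmax == 0.0

    def test_reference_temperature_identity(self):
        vcmax, vcmax25 = bp.invert_vcmax(20.0, 320.0, 25.0)
        assert vcmax25 == pytest.approx(vcmax, rel=1e-14)

    def test_forward_inverse_closure_over_grid(self):
        vc, ci, ta = np.meshgrid(np.linspace(5, 150, 7), np.linspace(120, 390, 7),
                                 np.linspace(2, 38, 7))
        amax = bp.forward_amax(vc, ci, ta)
        back, _ = bp.invert_vcmax(amax, ci, ta)
        np.testing.assert_allclose(back, vc, rtol=1e-12)

    def test_sub_compensation_ci_flagged(self):
        vcmax, _ = bp.invert_vcmax(10.0, 30.0, 25.0)  # ci < Gamma*(25) = 42.75
        assert np.isnan(vcmax)


class TestIwue:
    def test_ratio(self):
        assert bp.iwue(20.0, 0.4) == pytest.approx(50.0)

    def test_zero_gpp(self):
        assert bp.iwue(0.0, 0.4) == 0.0

    def test_homogeneity(self):
        assert bp.iwue(40.0, 0.8) == pytest.approx(bp.iwue(20.0, 0.4))

    def test_closed_stomata_missing(self):
        assert np.isnan(bp.iwue(20.0, 0.0))


class TestLightResponse:
    def test_noise_free_parameters_recovered(self):
        rng = np.random.default_rng(2)
        rg = np.tile(np.linspace(0, 1000, 60), 5)
        vpd = rng.uniform(0.5, 3.0, 300)
        nee = lrc_nee(rg, vpd, 0.04, 25.0, 0.2, 5.0)
        fit = fit_light_response(nee, rg, vpd)
        assert fit.alpha == pytest.approx(0.04, abs=1e-6)
        assert fit.beta0 == pytest.approx(25.0, abs=1e-5)
        assert fit.k_vpd == pytest.approx(0.2, abs=1e-6)
        assert fit.gamma_resp == pytest.approx(5.0, abs=1e-6)

    def test_low_vpd_window_fixes_decay_at_zero(self):
        rng = np.random.default_rng(3)
        rg = rng.uniform(0, 1000, 200)
        vpd = rng.uniform(0.2, 0.9, 200)
        nee = lrc_nee(rg, vpd, 0.04, 25.0, 0.0, 5.0)
        fit = fit_light_response(nee, rg, vpd)
        assert fit.k_unidentified and fit.k_vpd == 0.0
        assert fit.beta0 == pytest.approx(25.0, rel=1e-4)

    def test_noisy_recovery_median_error_under_ten_percent(self):
        rng = np.random.default_rng(4)
        errs = []
        for _ in range(40):
            rg = rng.uniform(0, 1000, 240)
            vpd = rng.uniform(0.5, 3.0, 240)
            nee = lrc_nee(rg, vpd, 0.04, 25.0, 0.2, 5.0)
            noisy = nee + 0.1 * np.abs(nee) * rng.standard_normal(240)
            fit = fit_light_response(noisy, rg, vpd)
            if fit is not None:
                errs.append(abs(fit.beta0 - 25.0) / 25.0)
        assert np.median(errs) < 0.1

    def test_windows_share_one_amax_per_window(self, clean_site):
        daily, fits = fit_light_response_windows(clean_site)
        assert len(fits) >= 1
        per_window = daily.groupby("window")["amax"].nunique()
        assert (per_window == 1).all()
        assert daily["amax"].between(0.05, 500).all()
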