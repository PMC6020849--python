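"""Grating solver: staircase geometry, diffraction, resonance, near field."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import promscope as p
from promscope.gmr_forward import trapezoid_fill_fractions

from oracles import tmm_reflectance


# ---------------------------------------------------------------------------
# staircase geometry
# ---------------------------------------------------------------------------

class TestStaircase:
    def test_vertical_sidewalls_give_uniform_fills(self):
        fills = trapezoid_fill_fractions(0.416, 120.0, 90.0, 13, 400.0)
        assert np.allclose(fills, 0.416)

    def test_stated_geometry_fills_monotonic_with_mid_height_mean(self):
        # 85 deg sidewall over 120 nm: linear width profile, wider at the base
        fills = trapezoid_fill_fractions(0.416, 120.0, 85.0, 10, 400.0)
        assert np.all(np.diff(fills) > 0)          # top slab first, narrowest
        assert abs(fills.mean() - 0.416) < 1e-12

    def test_single_layer_sits_at_mid_height(self):
        fills = trapezoid_fill_fractions(0.37, 100.0, 80.0, 1, 400.0)
        assert fills.shape == (1,)
        assert abs(fills[0] - 0.37) < 1e-12

    def test_extreme_sidewall_raises_geometry_error(self):
        # 45 deg walls over 120 nm push the base width past the period
        stack = p.GratingStack(grating_sidewall_deg=45.0, grating_duty=0.8)
        with pytest.raises(p.GeometryError):
            p.build_staircase(stack, p.Medium())

    def test_thicknesses_preserved_exactly(self, stack, water):
        slabs = p.build_staircase(stack, water)
        cap = sum(s.thickness_nm for s in slabs if s.region == "tio2_cap")
        grat = sum(s.thickness_nm for s in slabs if s.region == "grating")
        assert cap == pytest.approx(stack.tio2_thickness_nm, abs=1e-12)
        assert grat == pytest.approx(stack.grating_depth_nm, abs=1e-12)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(duty=st.floats(0.1, 0.9), sidewall=st.floats(60.0, 90.0),
           layers=st.integers(1, 12))
    def test_mean_fill_equals_duty_whenever_geometry_valid(self, duty,
                                                           sidewall, layers):
        fills = trapezoid_fill_fractions(duty, 120.0, sidewall, layers, 400.0)
        if np.all((fills > 0) & (fills < 1)):
            assert abs(fills.mean() - duty) < 1e-10


# ---------------------------------------------------------------------------
# diffraction: oracles and invariants
# ---------------------------------------------------------------------------

class TestDiffraction:
    @pytest.mark.parametrize("pol", ["TE", "TM"])
    def test_planar_limit_matches_transfer_matrix(self, pol, water):
        """Both duty cycles at 1: an unpatterned TiO2 film on polymer."""
        stack = p.GratingStack(grating_duty=1.0, tio2_duty=1.0,
                               grating_sidewall_deg=90.0,
                               tio2_sidewall_deg=90.0)
        slabs = p.build_staircase(stack, water)
        for lam in (605.0, 620.0, 633.0, 648.0):
            res = p.solve_wavelength(slabs, 1.333, 1.52, lam, 400.0, pol)
            ref = tmm_reflectance([s.strips[0].index for s in slabs],
                                  [s.thickness_nm for s in slabs],
                                  1.333, 1.52, lam)
            assert abs(res.efficiencies_r.sum() - ref) < 1e-6

    @pytest.mark.parametrize("pol", ["TE", "TM"])
    def test_zero_duty_limit_matches_transfer_matrix(self, pol, water):
        """Both duty cycles at 0 (vertical walls): conformal film only."""
        stack = p.GratingStack(grating_duty=0.0, tio2_duty=0.0,
                               grating_sidewall_deg=90.0,
                               tio2_sidewall_deg=90.0)
        slabs = p.build_staircase(stack, water)
        assert all(len(s.strips) == 0 for s in slabs)
        for lam in (610.0, 640.0):
            res = p.solve_wavelength(slabs, 1.333, 1.52, lam, 400.0, pol)
            ref = tmm_reflectance([s.background_index for s in slabs],
                                  [s.thickness_nm for s in slabs],
                                  1.333, 1.52, lam)
            assert abs(res.efficiencies_r.sum() - ref) < 1e-6

    @pytest.mark.parametrize("pol", ["TE", "TM"])
    def test_energy_conservation_lossless(self, pol, stack, water):
        slabs = p.build_staircase(stack, water)
        for lam in (605.0, 627.6, 645.0):  # off, on and off resonance
            res = p.solve_wavelength(slabs, 1.333, 1.52, lam, 400.0, pol)
            assert abs(res.total_efficiency - 1.0) < 1e-6

    def test_spectrum_metadata_reports_energy_residual(self, design_spectrum):
        assert design_spectrum.metadata["max_energy_residual"] < 1e-6

    def test_harmonic_truncation_converged(self, stack, water, design_fit):
        """Doubling 2M+1 from the default moves the PWV by < 0.1 nm."""
        from promscope.gmr_forward import DEFAULT_HARMONICS
        grid = np.arange(design_fit.pwv_nm - 2.0,
                         design_fit.pwv_nm + 2.0001, 0.05)
        fit_2m = p.locate_resonance(
            p.simulate_spectrum(stack, water, grid,
                                harmonics=2 * DEFAULT_HARMONICS))
        assert abs(fit_2m.pwv_nm - design_fit.pwv_nm) < 0.1


# ---------------------------------------------------------------------------
# resonance
# ---------------------------------------------------------------------------

class TestResonance:
    def test_stated_geometry_resonates_near_626(self, design_fit):
        assert design_fit.pwv_nm == pytest.approx(626.0, abs=5.0)

    def test_lossless_resonance_reaches_near_unity_reflection(self, design_fit):
        assert design_fit.piv >= 0.9

    def test_locate_resonance_inverts_synthetic_lorentzian(self):
        w = np.arange(615.0, 640.0001, 0.2)
        r = 0.8 * (2.0 ** 2) / ((w - 628.0) ** 2 + 2.0 ** 2)
        fit = p.locate_resonance(p.ReflectionSpectrum(w, r),
                                 method="parabolic_vertex")
        assert fit.pwv_nm == pytest.approx(628.0, abs=1e-9)

    def test_flat_spectrum_raises(self):
        w = np.arange(615.0, 640.0001, 0.2)
        with pytest.raises(p.ResonanceLocationError):
            p.locate_resonance(p.ReflectionSpectrum(w, np.full_like(w, 0.5)))

    def test_boundary_peak_raises(self):
        w = np.arange(615.0, 640.0001, 0.2)
        with pytest.raises(p.ResonanceLocationError):
            p.locate_resonance(p.ReflectionSpectrum(w, np.linspace(0, 1, w.size)))


@pytest.fixture(scope="module")
def sweep(stack):
    grid = np.arange(624.0, 636.0001, 0.1)
    return p.resonance_vs_index(stack, [1.333, 1.343, 1.353, 1.363, 1.373],
                                wavelengths_nm=grid)


class TestIndexSweep:
    def test_pwv_strictly_increasing_in_index(self, sweep):
        assert np.all(np.diff(sweep["pwv_nm"]) > 0)

    def test_piv_constant_within_one_percent(self, sweep):
        piv = sweep["piv"].to_numpy()
        assert np.all(np.abs(piv - piv[0]) / piv[0] < 0.01)

    def test_pws_referenced_to_first_index(self, sweep):
        assert sweep["pws_nm"].iloc[0] == 0.0
        assert np.all(np.diff(sweep["pws_nm"]) > 0)

    def test_single_index_gives_zero_shift(self, stack):
        grid = np.arange(624.0, 632.0001, 0.1)
        t = p.resonance_vs_index(stack, [1.333], wavelengths_nm=grid)
        assert len(t) == 1 and t["pws_nm"].iloc[0] == 0.0

    def test_pwv_nondecreasing_over_wider_index_range(self, stack):
        grid = np.arange(618.0, 640.0001, 0.2)
        t = p.resonance_vs_index(stack, [1.30, 1.35, 1.40],
                                 wavelengths_nm=grid)
        assert np.all(np.diff(t["pwv_nm"]) >= 0)


# ---------------------------------------------------------------------------
# near field
# ---------------------------------------------------------------------------

class TestFieldProfile:
    def test_resonant_surface_enhancement_at_least_tenfold(self, design_profile):
        assert design_profile.intensity_enhancement[0] >= 10.0

    def test_off_resonance_enhancement_small(self, stack, water, design_fit):
        prof = p.field_profile(stack, water, design_fit.pwv_nm - 20.0)
        assert prof.intensity_enhancement[0] < 3.0

    def test_tail_is_exponential(self, design_profile):
        _, r2 = p.evanescent_decay_constant(design_profile)
        assert r2 >= 0.99

    def test_decay_constant_matches_analytic_kappa(self, design_profile):
        kappa, _ = p.evanescent_decay_constant(design_profile)
        lam = design_profile.wavelength_nm
        n_eff = lam / 400.0
        kappa_an = (2 * np.pi / lam) * np.sqrt(n_eff ** 2 - 1.333 ** 2)
        assert kappa == pytest.approx(kappa_an, rel=0.25)

    def test_tail_monotone_beyond_near_field(self, design_profile):
        z, s = design_profile.z_nm, design_profile.intensity_enhancement
        tail = s[z >= 50.0]
        assert np.all(np.diff(tail) <= 0)
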