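"""Forward-model unit tests: power-law scattering, blood absorption,
effective path length, absorption-free reflectance and their composition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mdsfr import (
    AbsorptionParams,
    ScatteringParams,
    SFRModelConstants,
    Spectrum,
    absorption_coefficient,
    forward_reflectance,
    path_length,
    reduced_scattering,
    rsf0,
)

K = SFRModelConstants()


class TestReducedScattering:
    @pytest.mark.parametrize(
        "lam, a800, b, expected",
        [
            (800.0, 2.0, 1.3, 2.0),  # anchor wavelength: ratio is 1
            (400.0, 2.0, 1.0, 4.0),  # halving wavelength with b=1 doubles mu_s'
            (600.0, 2.0, 1.3, 2.0 * 0.75 ** (-1.3)),  # log-space check: ~2.906
        ],
    )
    def test_power_law_values(self, lam, a800, b, expected):
        assert reduced_scattering(lam, ScatteringParams(a800, b)) == pytest.approx(
            expected, rel=1e-12
        )

    def test_rejects_nonpositive_wavelength(self):
        with pytest.raises(ValueError):
            reduced_scattering(-5.0, ScatteringParams(2.0, 1.3))

    def test_vectorised_over_grid(self, grid):
        out = reduced_scattering(grid, ScatteringParams(2.0, 1.3))
        assert out.shape == grid.shape
        assert np.all(np.diff(out) < 0)  # decreasing with wavelength for b>0


class TestAbsorption:
    def test_no_blood_no_absorption(self, lib):
        ab = AbsorptionParams(bvf=0.0, sto2=0.5)
        assert absorption_coefficient(650.0, ab, lib) == 0.0

    def test_pure_oxygenated_blood_returns_table_value(self, lib):
        lam = float(lib.wavelengths_nm[40])
        ab = AbsorptionParams(bvf=1.0, sto2=1.0)
        assert absorption_coefficient(lam, ab, lib) == pytest.approx(
            lib.mu_a_hbo2[40], rel=1e-12
        )

    def test_mixture_expansion(self, lib):
        lam = float(lib.wavelengths_nm[100])
        expected = 0.02 * (0.6 * lib.mu_a_hbo2[100] + 0.4 * lib.mu_a_hb[100])
        ab = AbsorptionParams(bvf=0.02, sto2=0.6)
        assert absorption_coefficient(lam, ab, lib) == pytest.approx(expected, rel=1e-12)

    def test_outside_coverage_raises(self, lib):
        with pytest.raises(ValueError):
            absorption_coefficient(9999.0, AbsorptionParams(0.1, 0.5), lib)

    def test_parameter_domains_enforced(self):
        with pytest.raises(ValueError):
            AbsorptionParams(bvf=1.2, sto2=0.5)
        with pytest.raises(ValueError):
            AbsorptionParams(bvf=0.1, sto2=-0.01)


class TestPathLength:
    def test_hand_value_at_zero_absorption(self):
        # mu_a=0, mu_s'*d_f=1, d_f=1: L = C_PF*p1/p3 = 0.944*1.54/0.64
        assert path_length(0.0, 1.0, 1.0, K) == pytest.approx(
            0.944 * 1.54 / 0.64, rel=1e-12
        )

    def test_independent_reevaluation_small_fiber(self):
        # second, explicit evaluation of the closed form
        mu_s, d_f = 2.0, 0.470
        expected = d_f * 0.944 * 1.54 * (mu_s * d_f) ** (-0.18) / (0.64 + 0.0)
        assert path_length(0.0, mu_s, d_f, K) == pytest.approx(expected, rel=1e-12)

    def test_strictly_decreasing_in_absorption_and_scattering(self):
        mu_a_grid = np.linspace(0.0, 2.0, 15)
        mu_s_grid = np.linspace(0.5, 6.0, 15)
        for mu_s in (0.8, 2.0, 5.0):
            vals = path_length(mu_a_grid, mu_s, 0.47, K)
            assert np.all(np.diff(vals) < 0)
        for mu_a in (0.0, 0.3, 1.5):
            vals = path_length(mu_a, mu_s_grid, 0.47, K)
            assert np.all(np.diff(vals) < 0)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            path_length(0.1, -1.0, 0.47, K)
        with pytest.raises(ValueError):
            path_length(0.1, 1.0, 0.0, K)


class TestRsf0:
    def test_diffusion_limit_is_eta_lim(self):
        assert abs(rsf0(1e6, 1.0, K) - 0.027) < 1e-6

    def test_zero_scattering_gives_zero(self):
        assert rsf0(0.0, 1.0, K) == 0.0

    def test_hand_value_at_unit_dimensionless_scattering(self):
        expected = 0.027 * (1.0 + 1.55 * np.exp(-6.82)) * (1.0 / 7.82)
        assert rsf0(1.0, 1.0, K) == pytest.approx(expected, rel=1e-12)

    def test_nondecreasing_on_dense_grid(self):
        x = np.linspace(0.0, 50.0, 4000)
        vals = rsf0(x, 1.0, K)
        assert np.all(np.diff(vals) >= -1e-15)

    def test_bounded_by_eta_lim_times_one_plus_p6(self):
        x = np.logspace(-3, 3, 500)
        vals = rsf0(x, 1.0, K)
        assert np.all(vals > 0)
        assert np.all(vals <= K.rsf0_max)

    def test_negative_scattering_rejected(self):
        with pytest.raises(ValueError):
            rsf0(-0.1, 1.0, K)


class TestForwardReflectance:
    def test_no_absorption_reduces_to_rsf0(self, grid, lib):
        sc = ScatteringParams(2.0, 1.3)
        spec = forward_reflectance(grid, sc, AbsorptionParams(0.0, 0.5), 0.47, K, lib)
        mu_s = reduced_scattering(grid, sc)
        np.testing.assert_allclose(spec.values, rsf0(mu_s, 0.47, K), rtol=1e-14)

    def test_absorption_only_attenuates(self, grid, lib):
        sc = ScatteringParams(2.0, 1.3)
        r0 = forward_reflectance(grid, sc, AbsorptionParams(0.0, 0.5), 0.47, K, lib)
        r = forward_reflectance(grid, sc, AbsorptionParams(0.1, 0.5), 0.47, K, lib)
        assert np.all(r.values <= r0.values)
        assert np.all(r.values > 0)

    def test_matches_scalar_composition_oracle(self, grid, lib):
        """Full spectrum equals a naive wavelength-by-wavelength loop over
        the scalar sub-operations."""
        sc = ScatteringParams(2.0, 1.3)
        ab = AbsorptionParams(0.02, 0.7)
        spec = forward_reflectance(grid, sc, ab, 0.470, K, lib)
        for i in range(0, grid.size, 17):
            lam = float(grid[i])
            mu_s = reduced_scattering(lam, sc)
            mu_a = absorption_coefficient(lam, ab, lib)
            expected = rsf0(mu_s, 0.470, K) * np.exp(
                -mu_a * path_length(mu_a, mu_s, 0.470, K)
            )
            assert spec.values[i] == pytest.approx(expected, rel=1e-12)

    def test_pointwise_model_is_grid_invariant(self, grid, lib):
        """Evaluating on a subsampled grid equals subsampling the full
        evaluation (the model is pointwise in wavelength)."""
        sc, ab = ScatteringParams(1.6, 1.1), AbsorptionParams(0.03, 0.6)
        full = forward_reflectance(grid, sc, ab, 1.1, K, lib)
        sub = forward_reflectance(grid[::5], sc, ab, 1.1, K, lib)
        np.testing.assert_allclose(sub.values, full.values[::5], rtol=1e-14)

    @settings(max_examples=30, derandomize=True)
    @given(
        a800=st.floats(0.5, 5.0),
        b=st.floats(0.0, 3.0),
        bvf=st.floats(0.0, 0.3),
        sto2=st.floats(0.0, 1.0),
    )
    def test_reflectance_within_physical_bounds(self, a800, b, bvf, sto2, lib, grid):
        spec = forward_reflectance(
            grid, ScatteringParams(a800, b), AbsorptionParams(bvf, sto2), 0.47, K, lib
        )
        assert np.all(spec.values >= 0)
        assert np.all(spec.values <= K.rsf0_max)


class TestSpectrumContainer:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            Spectrum([500, 499, 600], [1, 2, 3])
        with pytest.raises(ValueError):
            Spectrum([500, 600], [1, 2, 3])
        with pytest.raises(ValueError):
            Spectrum([500, 600], [1, 2], units="volts")

    def test_resample_refuses_extrapolation(self):
        s = Spectrum([500.0, 600.0, 700.0], [1.0, 2.0, 3.0])
        with pytest.raises(ValueError):
            s.resample(np.array([400.0, 500.0]))

    def test_resample_is_linear_interpolation(self):
        s = Spectrum([500.0, 600.0], [1.0, 3.0])
        out = s.resample(np.array([550.0, 575.0]))
        assert out.values == pytest.approx([2.0, 2.5])
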