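"""Calibration-stage tests: sphere channel correction, the two-phantom
transform identities, the model-based reference reflectance, and the
replicate SNR quality statistic."""

import numpy as np
import pytest

from mdsfr import (
    AbsorptionParams,
    CalibrationSet,
    ScatteringParams,
    ScenarioConfig,
    Spectrum,
    apply_calibration,
    make_calibration_set,
    reference_reflectance,
    rsf0,
    reduced_scattering,
    snr_quality,
    sphere_correction,
)
from mdsfr.calibration import (
    DegenerateReplicatesError,
    IncompatibleGridsError,
    InsufficientReplicatesError,
    UnusableCalibrationError,
)


def _flat(grid, value, **meta):
    return Spectrum(grid, np.full(grid.size, float(value)), meta=meta)


class TestSphereCorrection:
    def test_identical_channels_give_unit_corrections(self, grid):
        chans = {"a": _flat(grid, 100.0), "b": _flat(grid, 100.0)}
        corr = sphere_correction(chans, reference="a")
        for c in corr.values():
            np.testing.assert_allclose(c.values, 1.0)

    def test_doubled_channel_gets_half_correction(self, grid):
        chans = {"a": _flat(grid, 100.0), "b": _flat(grid, 200.0)}
        corr = sphere_correction(chans, reference="a")
        np.testing.assert_allclose(corr["b"].values, 0.5)
        np.testing.assert_allclose(corr["a"].values, 1.0)

    def test_known_sensitivity_curves_are_inverted(self, grid):
        """Channels built as reference x known smooth curve: the correction
        must be the curve's reciprocal, and corrected spectra must agree
        with the reference."""
        rng = np.random.default_rng(42)
        ref = 1000.0 + 200.0 * np.sin(grid / 120.0)
        chans = {"ref": Spectrum(grid, ref)}
        curves = {}
        for name in ("b", "c"):
            poly = np.polynomial.polynomial.polyval(
                (grid - 675) / 225, rng.uniform(0.5, 1.5, 3)
            )
            curves[name] = poly
            chans[name] = Spectrum(grid, ref * poly)
        corr = sphere_correction(chans, reference="ref")
        for name, poly in curves.items():
            np.testing.assert_allclose(corr[name].values, 1.0 / poly, rtol=1e-10)
            corrected = chans[name].values * corr[name].values
            np.testing.assert_allclose(corrected, ref, rtol=1e-10)

    def test_disjoint_grids_raise(self):
        a = Spectrum([400.0, 500.0], [1.0, 1.0])
        b = Spectrum([600.0, 700.0], [1.0, 1.0])
        with pytest.raises(IncompatibleGridsError):
            sphere_correction({"a": a, "b": b})


class TestApplyCalibration:
    def test_intralipid_maps_to_reference(self, clean_noiseless_cal):
        cal = clean_noiseless_cal
        for label in ("small", "large"):
            out = apply_calibration(cal.intralipid[label][0], cal, label)
            ok = np.isfinite(out.values)
            np.testing.assert_allclose(
                out.values[ok], cal.r_cal_sim[label].resample(out.wavelengths_nm).values[ok],
                rtol=1e-12,
            )

    def test_water_maps_to_zero(self, clean_noiseless_cal):
        cal = clean_noiseless_cal
        out = apply_calibration(cal.water["small"], cal, "small")
        ok = np.isfinite(out.values)
        np.testing.assert_allclose(out.values[ok], 0.0, atol=1e-15)

    @pytest.mark.parametrize("f", [0.0, 0.37, 1.0])
    def test_affine_interpolant_maps_to_same_fraction(self, clean_noiseless_cal, f):
        """Eq-linearity: water + f*(intralipid - water) calibrates to
        exactly f * r_cal_sim."""
        cal = clean_noiseless_cal
        il = cal.intralipid["small"][0]
        w = cal.water["small"].resample(il.wavelengths_nm)
        mix = il.with_values(w.values + f * (il.values - w.values))
        out = apply_calibration(mix, cal, "small")
        expected = f * cal.r_cal_sim["small"].resample(out.wavelengths_nm).values
        ok = np.isfinite(out.values)
        np.testing.assert_allclose(out.values[ok], expected[ok], rtol=1e-12, atol=1e-15)

    def test_denominator_floor_masks_not_clips(self, grid):
        il_vals = np.full(grid.size, 1000.0)
        il_vals[:5] = 0.1  # edge wavelengths with no usable signal
        cal = CalibrationSet(
            intralipid={"small": [Spectrum(grid, il_vals)]},
            water={"small": _flat(grid, 0.1)},
            r_cal_sim={"small": Spectrum(grid, np.full(grid.size, 0.01), units="reflectance")},
        )
        out = apply_calibration(_flat(grid, 500.0), cal, "small", floor_fraction=1e-6)
        assert np.isnan(out.values[:5]).all()
        assert np.isfinite(out.values[5:]).all()

    def test_all_masked_is_an_error(self, grid):
        cal = CalibrationSet(
            intralipid={"small": [_flat(grid, 1.0)]},
            water={"small": _flat(grid, 1.0)},
            r_cal_sim={"small": Spectrum(grid, np.full(grid.size, 0.01), units="reflectance")},
        )
        with pytest.raises(UnusableCalibrationError):
            apply_calibration(_flat(grid, 500.0), cal, "small")

    def test_defective_set_detected(self, grid):
        cal = CalibrationSet(
            intralipid={"small": [_flat(grid, 5.0)]},
            water={"small": _flat(grid, 50.0)},
            r_cal_sim={"small": Spectrum(grid, np.full(grid.size, 0.01), units="reflectance")},
        )
        assert cal.is_defective("small")


class TestReferenceReflectance:
    def test_absorption_free_reference_equals_rsf0(self, geom, grid, lib):
        sc = ScatteringParams(3.0, 2.4)
        ref = reference_reflectance("small", geom, sc, grid_nm=grid, lib=lib)
        mu_s = reduced_scattering(grid, sc)
        np.testing.assert_allclose(ref.values, rsf0(mu_s, geom.d_small), rtol=1e-14)

    def test_large_diameter_reference_exceeds_small(self, geom, grid, lib):
        sc = ScatteringParams(3.0, 2.4)
        small = reference_reflectance("small", geom, sc, grid_nm=grid, lib=lib)
        large = reference_reflectance("large", geom, sc, grid_nm=grid, lib=lib)
        assert np.all(large.values > small.values)

    def test_deterministic(self, geom, grid, lib):
        sc = ScatteringParams(3.0, 2.4)
        a = reference_reflectance("small", geom, sc, grid_nm=grid, lib=lib)
        b = reference_reflectance("small", geom, sc, grid_nm=grid, lib=lib)
        np.testing.assert_array_equal(a.values, b.values)


class TestSnrQuality:
    def test_hand_arithmetic_flat_replicates(self, grid):
        """Replicates s, 1.01 s, 0.99 s of a flat 1000-count spectrum:
        per-wavelength mean 1000, sample SD 10, SNR exactly 100."""
        reps = [_flat(grid, 1000.0 * f) for f in (1.0, 1.01, 0.99)]
        q = snr_quality(reps)
        assert q.snr == pytest.approx(100.0, rel=1e-12)
        assert q.n_replicates == 3
        assert q.band_nm == (675.0, 725.0)

    def test_identical_replicates_are_degenerate(self, grid):
        with pytest.raises(DegenerateReplicatesError):
            snr_quality([_flat(grid, 1000.0)] * 3)

    def test_fewer_than_three_replicates_refused(self, grid):
        with pytest.raises(InsufficientReplicatesError):
            snr_quality([_flat(grid, 1000.0), _flat(grid, 1010.0)])

    def test_scale_invariance(self, grid):
        rng = np.random.default_rng(3)
        base = 1000.0 * (1.0 + rng.normal(0, 0.02, (5, grid.size)))
        reps = [Spectrum(grid, row) for row in base]
        scaled = [Spectrum(grid, 7.3 * row) for row in base]
        assert snr_quality(scaled).snr == pytest.approx(snr_quality(reps).snr, rel=1e-12)

    def test_snr_estimates_inverse_noise_at_many_replicates(self):
        """i.i.d. multiplicative noise of relative sigma: SNR ~ 1/sigma."""
        cfg = ScenarioConfig(seed=5, noise_rel=0.02, n_replicates=200)
        cal = make_calibration_set(cfg)
        q = snr_quality(cal.intralipid["small"])
        assert 45.0 < q.snr < 55.0

    def test_report_carries_grouping_keys(self, grid):
        reps = [
            Spectrum(grid, np.full(grid.size, 1000.0 * f), meta={"probe_id": "P1"})
            for f in (1.0, 1.01, 0.99)
        ]
        q = snr_quality(reps)
        assert q.meta["probe_id"] == "P1"
        assert q.row()["snr"] == pytest.approx(100.0)
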