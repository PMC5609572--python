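"""Film netOD, cubic calibration and dose-map conversion."""

import numpy as np
import pytest

from braggkit import beam, qa
from braggkit.film import (
    CalibrationCurve,
    FilmScan,
    dose_map,
    fit_calibration,
    net_od,
    read_scan_file,
    synthetic_scan,
    write_dose_map,
)


class TestNetOD:
    def test_equal_intensities_give_zero(self):
        assert net_od(30000.0, 30000.0) == 0.0

    def test_tenfold_attenuation_is_unit_od(self):
        assert net_od(3000.0, 30000.0) == pytest.approx(1.0)

    def test_elementwise_matrix_matches_scalar(self):
        rng = np.random.default_rng(1)
        exposed = rng.integers(1000, 40000, (3, 3)).astype(float)
        mat = net_od(exposed, 40000.0)
        for i in range(3):
            for j in range(3):
                assert mat[i, j] == net_od(exposed[i, j], 40000.0)

    def test_rejects_nonpositive_intensity(self):
        with pytest.raises(ValueError):
            net_od(0.0, 30000.0)

    def test_invariant_under_global_intensity_rescale(self):
        assert net_od(2.0 * 12000.0, 2.0 * 30000.0) == pytest.approx(
            net_od(12000.0, 30000.0))


class TestFitCalibration:
    def test_recovers_exact_cubic_coefficients(self):
        true = np.array([0.05, 8.0, 3.5, 12.0])
        x = np.linspace(0.02, 0.5, 9)
        y = true[0] + x * (true[1] + x * (true[2] + x * true[3]))
        curve = fit_calibration(x, y)
        np.testing.assert_allclose(curve.coefficients, true, rtol=1e-9)
        assert curve.fit_residual_rms < 1e-12

    def test_origin_constraint_pins_zero(self):
        x = np.linspace(0.02, 0.5, 9)
        y = 8.0 * x + 3.0 * x**2 + 10.0 * x**3
        curve = fit_calibration(x, y, constrain_origin=True)
        assert curve.coefficients[0] == 0.0
        assert curve.dose(0.0) == 0.0

    def test_duplicate_points_match_normal_equations_oracle(self):
        rng = np.random.default_rng(5)
        x = np.linspace(0.05, 0.5, 8)
        y = 9.0 * x + 4.0 * x**2 + 11.0 * x**3 + 0.01 * rng.standard_normal(8)
        x2 = np.concatenate([x, x])
        y2 = np.concatenate([y, y])
        curve = fit_calibration(x2, y2)
        # independent solve of the normal equations A'A c = A'y
        A = np.column_stack([np.ones_like(x2), x2, x2**2, x2**3])
        oracle = np.linalg.solve(A.T @ A, A.T @ y2)
        np.testing.assert_allclose(curve.coefficients, oracle, rtol=1e-8)
        # duplication leaves the fit unchanged
        single = fit_calibration(x, y)
        np.testing.assert_allclose(curve.coefficients, single.coefficients,
                                   rtol=1e-8)

    def test_non_monotone_fit_rejected(self):
        x = np.array([0.05, 0.1, 0.2, 0.3, 0.4, 0.5])
        y = np.array([1.0, 0.2, 1.5, 0.1, 2.0, 0.3])  # wildly oscillating
        with pytest.raises(ValueError, match="increasing"):
            fit_calibration(x, y)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="5"):
            fit_calibration([0.1, 0.2, 0.3], [1.0, 2.0, 3.0])


class TestDoseMap:
    def test_uniform_exposure_round_trips(self, cubic_curve):
        field = np.full((40, 40), 2.0)
        scan = synthetic_scan(field, cubic_curve, noise_sigma_fraction=0.0)
        dmap = dose_map(scan, cubic_curve)
        np.testing.assert_allclose(dmap.dose_gy, 2.0, atol=5e-3)

    def test_background_scan_maps_to_zero(self, cubic_curve):
        scan = FilmScan(np.full((10, 10), 40000, dtype=np.uint16),
                        dpi=254.0, background_value=40000.0)
        dmap = dose_map(scan, cubic_curve)
        np.testing.assert_allclose(dmap.dose_gy, 0.0, atol=1e-12)

    def test_round_trip_within_residual_plus_digitization(self, cubic_curve):
        doses = np.linspace(0.25, 4.0, 12)
        field = np.tile(doses, (4, 1))
        scan = synthetic_scan(field, cubic_curve, noise_sigma_fraction=0.0)
        dmap = dose_map(scan, cubic_curve)
        # one 16-bit digitization step maps to a small dose increment
        od = net_od(scan.pixel_matrix.astype(float), scan.background_value)
        step = np.max(np.abs(
            cubic_curve.dose(od + 1.0 / (np.log(10) * scan.pixel_matrix))
            - cubic_curve.dose(od)))
        tol = cubic_curve.fit_residual_rms + step + 1e-9
        assert np.max(np.abs(dmap.dose_gy - field)) <= tol

    def test_pixel_pitch_from_dpi(self, cubic_curve):
        scan = synthetic_scan(np.full((20, 30), 1.0), cubic_curve,
                              dpi=127.0, noise_sigma_fraction=0.0)
        dmap = dose_map(scan, cubic_curve)
        assert scan.pixel_pitch_mm == pytest.approx(0.2)
        assert dmap.x_mm.size == 30
        assert np.diff(dmap.x_mm)[0] == pytest.approx(0.2)

    def test_out_of_range_flagged_with_warning(self, cubic_curve):
        field = np.full((20, 20), 3.0)
        field[5:15, 5:15] = 5.5  # beyond the 4 Gy calibration ceiling
        scan = synthetic_scan(field, cubic_curve, noise_sigma_fraction=0.0)
        with pytest.warns(UserWarning, match="valid dose range"):
            dmap = dose_map(scan, cubic_curve)
        assert dmap.out_of_range.sum() == 100

    def test_circular_field_w50_via_qa_metrics(self, cubic_curve):
        # 25 mm field from the lateral generator, through film and back
        pitch_dpi = 254.0  # 0.1 mm pixels
        n = 351
        x = (np.arange(n) - (n - 1) / 2) * 0.1
        profile = beam.lateral_profile(
            x, beam.LateralProfileModel(field_radius=12.5, penumbra_sigma=1.0))
        field = 2.0 * np.tile(profile, (21, 1))
        field[field < 0.01] = 0.0
        scan = synthetic_scan(field, cubic_curve, dpi=pitch_dpi, seed=11)
        dmap = dose_map(scan, cubic_curve)
        xs, prof = dmap.profile_x(0.0)
        metrics = qa.extract_lateral_metrics((xs, prof))
        assert metrics.field_size_w50 == pytest.approx(25.0, abs=0.2)


class TestScanFiles:
    def test_matrix_text_round_trip(self, tmp_path, cubic_curve):
        scan = synthetic_scan(np.full((8, 8), 1.5), cubic_curve,
                              noise_sigma_fraction=0.0)
        path = tmp_path / "scan.txt"
        with open(path, "w") as fh:
            fh.write(f"# dpi: {scan.dpi}\n# background: {scan.background_value}\n")
            np.savetxt(fh, scan.pixel_matrix, fmt="%d")
        back = read_scan_file(path)
        np.testing.assert_array_equal(back.pixel_matrix, scan.pixel_matrix)
        assert back.dpi == scan.dpi

    def test_tiff_red_channel(self, tmp_path, cubic_curve):
        import tifffile

        scan = synthetic_scan(np.full((6, 6), 1.0), cubic_curve,
                              noise_sigma_fraction=0.0)
        path = tmp_path / "scan.tif"
        tifffile.imwrite(path, scan.pixel_matrix)
        back = read_scan_file(path, dpi=254.0,
                              background_value=scan.background_value)
        np.testing.assert_array_equal(back.pixel_matrix, scan.pixel_matrix)

    def test_dose_map_export(self, tmp_path, cubic_curve):
        scan = synthetic_scan(np.full((5, 5), 1.0), cubic_curve,
                              noise_sigma_fraction=0.0)
        dmap = dose_map(scan, cubic_curve)
        path = tmp_path / "dose.txt"
        write_dose_map(path, dmap, scan.dpi, curve_id="test")
        data = np.loadtxt(path)
        np.testing.assert_allclose(data, dmap.dose_gy, rtol=1e-6)
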