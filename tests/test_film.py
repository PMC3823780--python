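"""Film scans, netOD, calibration fitting, dose conversion, registration."""

import numpy as np
import pytest
import tifffile

from spiralfilm import (
    FilmScan,
    PlanarDoseMap,
    fit_calibration,
    net_od,
    od_to_dose,
    read_scan,
    register_film,
    write_scan,
)
from spiralfilm.film import read_calibration_table
from spiralfilm.synthetic import CALIBRATION_DOSES_CGY


def make_scan(values, dpi=72.0):
    return FilmScan(red_channel=np.asarray(values, dtype=np.uint16), dpi=dpi)


class TestScanIO:
    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(11)
        scan = make_scan(rng.integers(0, 65535, (40, 60)))
        write_scan(scan, tmp_path / "scan.tif")
        back = read_scan(tmp_path / "scan.tif")
        np.testing.assert_array_equal(back.red_channel, scan.red_channel)
        assert back.dpi == pytest.approx(72.0)

    def test_pixel_pitch_from_dpi(self):
        assert make_scan(np.zeros((2, 2))).pitch_cm * 10 == pytest.approx(
            0.35278, abs=1e-5
        )

    def test_grayscale_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "gray.tif", np.zeros((10, 10), np.uint16))
        with pytest.raises(ValueError, match="3 channels"):
            read_scan(tmp_path / "gray.tif", dpi=72)

    def test_8bit_upscaled_with_warning(self, tmp_path, caplog):
        tifffile.imwrite(tmp_path / "eight.tif",
                         np.full((5, 5, 3), 100, np.uint8), photometric="rgb")
        with caplog.at_level("WARNING"):
            scan = read_scan(tmp_path / "eight.tif", dpi=72)
        assert np.all(scan.red_channel == 100 * 257)
        assert any("16 bit" in r.message for r in caplog.records)

    def test_missing_dpi_rejected(self, tmp_path):
        tifffile.imwrite(tmp_path / "nodpi.tif",
                         np.zeros((5, 5, 3), np.uint16), photometric="rgb")
        with pytest.raises(ValueError, match="dpi"):
            read_scan(tmp_path / "nodpi.tif")


class TestNetOD:
    def test_identity_zero(self):
        s = make_scan(np.full((4, 4), 30000))
        assert np.all(net_od(s, s) == 0.0)

    def test_decade(self):
        assert net_od(make_scan([[4000]]), make_scan([[40000]]))[0, 0] == (
            pytest.approx(1.0, abs=1e-12)
        )

    def test_half_intensity(self):
        assert net_od(make_scan([[20000]]), 40000.0)[0, 0] == pytest.approx(
            np.log10(2.0), abs=1e-9
        )

    def test_clipped_below_zero(self):
        # exposed brighter than reference cannot give negative netOD
        assert net_od(make_scan([[50000]]), 40000.0)[0, 0] == 0.0

    def test_zero_intensity_half_lsb(self, caplog):
        with caplog.at_level("WARNING"):
            od = net_od(make_scan([[0]]), 40000.0)
        assert od[0, 0] == pytest.approx(np.log10(40000 / 0.5), abs=1e-9)

    def test_raster_mismatch_rejected(self):
        with pytest.raises(ValueError):
            net_od(make_scan(np.zeros((3, 3))), make_scan(np.zeros((4, 4))))


class TestCalibration:
    def test_exact_recovery_at_standard_doses(self, curve):
        """Noiseless points at the ten-level calibration series recover the
        generating (b, c, n) to 1e-6 relative."""
        fit = fit_calibration(curve.control_points)
        assert fit.b == pytest.approx(300.0, rel=1e-6)
        assert fit.c == pytest.approx(500.0, rel=1e-6)
        assert fit.n == pytest.approx(2.5, rel=1e-6)
        assert fit.fit_residual < 1e-9

    def test_zero_netod_zero_dose(self, curve):
        fit = fit_calibration(curve.control_points)
        assert fit.dose(0.0) == 0.0

    def test_monotone_on_valid_range(self, curve):
        fit = fit_calibration(curve.control_points)
        od = np.linspace(*fit.valid_range, 2000)
        assert np.all(np.diff(fit.dose(od)) > 0)

    def test_noise_robustness_monte_carlo(self, curve):
        """0.5% multiplicative netOD noise, 20 seeds: median dose error
        below 2% at all control doses >= 19.9 cGy."""
        doses = np.array(CALIBRATION_DOSES_CGY)
        ods = np.array([od for _, od in curve.control_points])
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = ods * (1 + 0.005 * rng.standard_normal(ods.shape))
            noisy[0] = 0.0
            fit = fit_calibration(list(zip(doses, noisy)))
            errors.append(np.abs(fit.dose(ods) - doses))
        med = np.median(np.array(errors), axis=0)
        check = doses >= 19.9
        assert np.all(med[check] < 0.02 * doses[check])

    def test_non_monotone_rejected(self, curve):
        pts = [list(p) for p in curve.control_points]
        pts[4][1], pts[5][1] = pts[5][1], pts[4][1]
        with pytest.raises(ValueError, match="offending"):
            fit_calibration([tuple(p) for p in pts])

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            fit_calibration([(0, 0), (10, 0.1), (20, 0.2)])

    def test_missing_zero_dose(self):
        with pytest.raises(ValueError):
            fit_calibration([(1, 0.01), (10, 0.1), (20, 0.18), (40, 0.3)])

    def test_table_red_value_conversion(self, tmp_path, curve):
        rows = ["dose_cGy,red_value"]
        for d, od in curve.control_points:
            rows.append(f"{d},{curve.unexposed_value * 10 ** -od:.6f}")
        (tmp_path / "cal.csv").write_text("\n".join(rows) + "\n")
        pts = read_calibration_table(tmp_path / "cal.csv")
        fit = fit_calibration(pts)
        assert fit.b == pytest.approx(300.0, rel=1e-4)


class TestOdToDose:
    def test_zero_map(self, curve):
        m = od_to_dose(np.zeros((5, 5)), curve, 0.1)
        assert np.all(m.values == 0.0)

    def test_control_points_recovered(self, curve):
        ods = np.array([[od for _, od in curve.control_points]])
        m = od_to_dose(ods, curve, 0.1)
        expect = [d for d, _ in curve.control_points]
        np.testing.assert_allclose(m.values[0], expect, atol=1e-6)

    def test_inverse_round_trip(self, curve):
        """dose -> netOD (inverse evaluation oracle) -> dose is identity."""
        rng = np.random.default_rng(12)
        doses = rng.uniform(0, 318.3, (20, 20))
        od = curve.net_od_from_dose(doses)
        m = od_to_dose(od, curve, 0.1)
        np.testing.assert_allclose(m.values, doses, atol=1e-6)

    def test_above_range_clipped(self, curve, caplog):
        with caplog.at_level("WARNING"):
            m = od_to_dose(np.array([[curve.valid_range[1] + 0.5]]), curve, 0.1)
        assert m.values[0, 0] == pytest.approx(
            curve.dose(curve.valid_range[1]), rel=1e-12
        )


class TestRegistration:
    def test_identity(self):
        m = PlanarDoseMap(np.arange(12.0).reshape(3, 4), pitch=(0.1, 0.1))
        out = register_film(m)
        np.testing.assert_array_equal(out.values, m.values)

    def test_double_flip_identity(self):
        m = PlanarDoseMap(np.arange(12.0).reshape(3, 4), pitch=(0.1, 0.1))
        once = register_film(m, flips=(True, True))
        twice = register_film(once, flips=(True, True))
        np.testing.assert_array_equal(twice.values, m.values)

    def test_shift_unshift_within_interpolation_error(self):
        rng = np.random.default_rng(13)
        smooth = rng.uniform(50, 150, (8, 8))
        big = np.kron(smooth, np.ones((8, 8)))  # piecewise-constant, smooth-ish
        m = PlanarDoseMap(big, pitch=(0.1, 0.1))
        out = register_film(register_film(m, offset=(0.3, 0.0)),
                            offset=(-0.3, 0.0))
        core = np.s_[8:-8, 8:-8]
        assert np.nanmax(np.abs(out.values[core] - m.values[core])) < 1e-9

    def test_fractional_shift_moves_content(self):
        vals = np.zeros((9, 9))
        vals[4, 4] = 100.0
        m = PlanarDoseMap(vals, pitch=(0.1, 0.1))
        out = register_film(m, offset=(0.1, 0.0))
        assert np.nanargmax(out.values) == np.ravel_multi_index((4, 5), (9, 9))
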