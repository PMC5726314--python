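"""Spectral collapsing, double-Lorentzian fitting and energy calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twocolor_sfx.spectro import (
    CalibrationFunction,
    CalibrationPoint,
    SpectrumFit,
    assign_two_color_energies,
    build_calibration_points,
    collapse_spectrum,
    double_lorentzian,
    fit_calibration,
    fit_double_lorentzian,
)
from twocolor_sfx.synth import NoiseModel, simulate_spectrum_image

X = np.arange(1024, dtype=float)
TRUTH = SpectrumFit(900.0, 400.0, 50.0, 200.0, 700.0, 12.0, 18.0)


def _truth_profile():
    return double_lorentzian(X, TRUTH.Amp1, TRUTH.Amp2, TRUTH.Const,
                             TRUTH.Peak1, TRUTH.Peak2, TRUTH.Width1,
                             TRUTH.Width2)


class TestCollapse:
    def test_all_ones(self):
        prof = collapse_spectrum(np.ones((1024, 512)))
        np.testing.assert_array_equal(prof.values, np.full(1024, 512.0))

    def test_single_nonzero_row(self):
        img = np.zeros((1024, 512))
        img[137, :] = 2.0
        prof = collapse_spectrum(img)
        assert prof.values[137] == 1024.0 and np.count_nonzero(prof.values) == 1

    def test_wrong_shape_rejected(self):
        with pytest.raises(ValueError):
            collapse_spectrum(np.zeros((512, 1024)))

    def test_collapse_of_simulated_image_is_512x_profile(self):
        cam = simulate_spectrum_image(TRUTH, noise_model=NoiseModel.none())
        prof = collapse_spectrum(cam)
        np.testing.assert_allclose(prof.values, 512.0 * _truth_profile(),
                                   rtol=1e-12)


class TestDoubleLorentzianFit:
    def test_exact_recovery_without_noise(self):
        fit = fit_double_lorentzian(_truth_profile())
        assert fit.converged
        for name in ("Amp1", "Amp2", "Const", "Peak1", "Peak2",
                     "Width1", "Width2"):
            assert getattr(fit, name) == pytest.approx(
                getattr(TRUTH, name), rel=1e-6)

    def test_peak_ordering_convention(self):
        flipped = double_lorentzian(X, 400.0, 900.0, 50.0, 700.0, 200.0,
                                    18.0, 12.0)
        fit = fit_double_lorentzian(flipped)
        assert fit.Peak1 < fit.Peak2

    def test_noisy_position_recovery(self):
        """Median position error over seeded noisy replicates stays sub-pixel."""
        rng = np.random.default_rng(42)
        errs = []
        for _ in range(100):
            noisy = _truth_profile() + rng.normal(0.0, 10.0, size=1024)
            fit = fit_double_lorentzian(noisy)
            errs.append(max(abs(fit.Peak1 - TRUTH.Peak1),
                            abs(fit.Peak2 - TRUTH.Peak2)))
        assert np.median(errs) < 0.5

    def test_flat_profile_fallback(self):
        fit = fit_double_lorentzian(np.full(1024, 7.0))
        assert not fit.converged
        assert fit.Amp2 == 0.0

    def test_single_line_fallback(self):
        prof = double_lorentzian(X, 800.0, 0.0, 30.0, 400.0, 900.0, 15.0, 1.0)
        fit = fit_double_lorentzian(prof)
        assert not fit.converged
        assert fit.Peak1 == pytest.approx(400.0, abs=1.0)

    def test_residual_decreases_with_noise(self):
        rng = np.random.default_rng(1)
        med = []
        for sigma in (20.0, 5.0, 1.0):
            r = [fit_double_lorentzian(
                    _truth_profile() + rng.normal(0, sigma, 1024)
                 ).residual_norm for _ in range(10)]
            med.append(np.median(r))
        assert med[0] > med[1] > med[2]


class TestCalibrationPoints:
    def test_median_grouping_example(self):
        pts = build_calibration_points([7.000, 7.000, 7.002], [137, 139, 140])
        assert [(p.wide_position, p.narrow_energy) for p in pts] == \
            [(138.0, 7.000), (140.0, 7.002)]

    def test_single_pair(self):
        pts = build_calibration_points([7.1], [250.0])
        assert pts == [CalibrationPoint(250.0, 7.1)]

    def test_empty_input(self):
        assert build_calibration_points([], []) == []

    @given(st.integers(min_value=0, max_value=2 ** 31 - 1))
    @settings(max_examples=30, derandomize=True, deadline=None)
    def test_matches_group_then_median_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 1000))
        narrow = np.round(rng.uniform(6.9, 7.1, n), 3)  # already on 1 eV grid
        wide = rng.uniform(0, 1024, n)
        pts = build_calibration_points(narrow, wide)
        # Independent dictionary-based oracle.
        groups: dict[float, list[float]] = {}
        for e, x in zip(narrow, wide):
            groups.setdefault(float(e), []).append(float(x))
        expected = sorted((float(np.median(v)), e) for e, v in groups.items())
        got = sorted((p.wide_position, p.narrow_energy) for p in pts)
        assert len(got) == len(expected)
        for (gw, ge), (ew, ee) in zip(got, expected):
            assert gw == pytest.approx(ew) and ge == pytest.approx(ee)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        narrow = np.round(rng.uniform(6.9, 7.1, 200), 3)
        wide = rng.uniform(0, 1024, 200)
        a = build_calibration_points(narrow, wide)
        perm = rng.permutation(200)
        b = build_calibration_points(narrow[perm], wide[perm])
        assert a == b


class TestCalibrationFit:
    def test_recovers_canonical_coefficients_exactly(self):
        # Points generated exactly on the deposited 7 keV branch line.
        xs = np.linspace(50, 450, 20)
        pts = [CalibrationPoint(x, 6.58984 + 0.00298 * x) for x in xs]
        cal = fit_calibration(pts)
        assert cal.c0 == pytest.approx(6.58984, abs=1e-9)
        assert cal.c1 == pytest.approx(0.00298, abs=1e-9)

    def test_two_points_exact_interpolation(self):
        cal = fit_calibration([CalibrationPoint(0.0, 6.0),
                               CalibrationPoint(100.0, 7.0)])
        assert cal(50.0) == pytest.approx(6.5)

    def test_degenerate_positions_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([CalibrationPoint(5.0, 6.0),
                             CalibrationPoint(5.0, 7.0)])

    def test_noisy_slope_recovery(self):
        rng = np.random.default_rng(0)
        rel_errs = []
        for _ in range(100):
            xs = rng.uniform(0, 500, 50)
            ys = 6.58984 + 0.00298 * xs + rng.normal(0, 0.002, 50)
            cal = fit_calibration([CalibrationPoint(x, y)
                                   for x, y in zip(xs, ys)])
            rel_errs.append(abs(cal.c1 - 0.00298) / 0.00298)
        assert np.median(rel_errs) < 0.05


class TestAssignEnergies:
    CAL1 = CalibrationFunction(6.58984, 0.00298, (0.0, 512.0))
    CAL2 = CalibrationFunction(5.72503, 0.00381, (512.0, 1024.0))

    def _fit(self, p1, p2):
        return SpectrumFit(100.0, 100.0, 5.0, p1, p2, 10.0, 10.0)

    def test_intercept_at_zero(self):
        e1, e2, wl1, wl2 = assign_two_color_energies(
            self._fit(0.0, 859.0), self.CAL1, self.CAL2)
        assert e1 == pytest.approx(6.58984)

    def test_linear_evaluation(self):
        cal1 = CalibrationFunction(6.58984, 0.00298, (0.0, 1000.0))
        cal2 = CalibrationFunction(8.0, 0.004, (1500.0, 2000.0))
        e1, e2, _, _ = assign_two_color_energies(
            self._fit(1000.0, 1600.0), cal1, cal2)
        assert e1 == pytest.approx(6.58984 + 2.98)

    def test_branch_ordering(self):
        e1, e2, wl1, wl2 = assign_two_color_energies(
            self._fit(137.0, 859.0), self.CAL1, self.CAL2)
        assert e1 < e2 and wl1 > wl2

    def test_out_of_range_peak_rejected(self):
        cal1 = CalibrationFunction(6.58984, 0.00298, (0.0, 100.0))
        with pytest.raises(ValueError, match="outside both"):
            assign_two_color_energies(self._fit(200.0, 859.0), cal1, self.CAL2)

    def test_unconverged_fit_rejected(self):
        bad = SpectrumFit(1.0, 0.0, 5.0, 100.0, 101.0, 10.0, 10.0,
                          converged=False)
        with pytest.raises(ValueError):
            assign_two_color_energies(bad, self.CAL1, self.CAL2)
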