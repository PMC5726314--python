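"""Two-colour photon-energy recovery from wide-range spectrometer images.

A split-undulator double pulse produces two spectral lines far enough apart
that the narrow-range inline spectrometer sees only one of them.  Both photon
energies are therefore recovered from the wide-range spectrometer camera:

1. the 1024 x 512 camera frame is collapsed along the non-dispersive axis
   into a 1024-sample profile;
2. a double-Lorentzian-plus-offset model is fitted, giving two line positions
   (``Peak1 < Peak2``), amplitudes, widths (FWHM) and a constant offset;
3. a linear pixel-to-keV calibration per colour branch — estimated from
   calibration shots by grouping wide-range line positions that share the
   same (coarser) narrow-range reading and taking the group median — converts
   the two positions into the two photon energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal
from scipy.optimize import curve_fit
from scipy.stats import linregress

from .core import energy_to_wavelength

__all__ = [
    "SpectrumProfile",
    "SpectrumFit",
    "CalibrationPoint",
    "CalibrationFunction",
    "collapse_spectrum",
    "double_lorentzian",
    "fit_double_lorentzian",
    "build_calibration_points",
    "fit_calibration",
    "assign_two_color_energies",
]

#: Dispersive axis length of the wide-range spectrometer camera.
PROFILE_LENGTH = 1024


@dataclass(frozen=True)
class SpectrumProfile:
    """Collapsed 1-D spectral profile (1024 samples) with its event tag."""

    values: np.ndarray
    tag: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or len(v) != PROFILE_LENGTH:
            raise ValueError(f"profile must have exactly {PROFILE_LENGTH} samples")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class SpectrumFit:
    """Parameters of the double-Lorentzian-plus-offset spectral model.

    Widths are FWHM in pixels.  ``Peak1 < Peak2`` by convention; a failed or
    single-line fit carries ``converged=False`` (with ``Amp2 = 0`` for the
    single-peak fallback).
    """

    Amp1: float
    Amp2: float
    Const: float
    Peak1: float
    Peak2: float
    Width1: float
    Width2: float
    converged: bool = True
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.Width1 <= 0 or self.Width2 <= 0:
            raise ValueError("Lorentzian widths must be positive")


@dataclass(frozen=True)
class CalibrationPoint:
    """One (wide-range position, narrow-range energy) calibration pair."""

    wide_position: float  # pixel (median over a narrow-reading group)
    narrow_energy: float  # keV

    def __post_init__(self) -> None:
        if not (math.isfinite(self.wide_position) and math.isfinite(self.narrow_energy)):
            raise ValueError("calibration point values must be finite")


@dataclass(frozen=True)
class CalibrationFunction:
    """Linear pixel-to-energy map, energy = c0 + c1 * x (keV)."""

    c0: float
    c1: float
    valid_range: tuple[float, float] = (0.0, float(PROFILE_LENGTH))

    def __post_init__(self) -> None:
        if self.c1 == 0:
            raise ValueError("calibration slope must be nonzero")

    def __call__(self, x: float) -> float:
        return self.c0 + self.c1 * x

    def contains(self, x: float) -> bool:
        lo, hi = self.valid_range
        return lo <= x <= hi

    @classmethod
    def color1_default(cls) -> "CalibrationFunction":
        """Canonical 7 keV branch calibration, (6.58984 + 0.00298 x) keV."""
        return cls(6.58984, 0.00298, (0.0, 512.0))

    @classmethod
    def color2_default(cls) -> "CalibrationFunction":
        """Canonical 9 keV branch calibration, (5.72503 + 0.00381 x) keV."""
        return cls(5.72503, 0.00381, (512.0, 1024.0))


def collapse_spectrum(camera_image: np.ndarray, tag: str = "") -> SpectrumProfile:
    """Sum a 1024 x 512 camera frame along the non-dispersive axis.

    ``profile[i]`` is the sum over the 512 pixels at dispersive position
    ``i``; summation (not averaging) is used, any linear scale being absorbed
    by the fitted amplitudes and offset.
    """
    img = np.asarray(camera_image, dtype=float)
    if img.ndim != 2 or img.shape[0] != PROFILE_LENGTH:
        raise ValueError(
            f"expected a ({PROFILE_LENGTH}, n) camera image, got {img.shape}")
    return SpectrumProfile(img.sum(axis=1), tag=tag)


def double_lorentzian(x: np.ndarray, amp1: float, amp2: float, const: float,
                      peak1: float, peak2: float, width1: float, width2: float
                      ) -> np.ndarray:
    """Const + sum of two Lorentzians; widths are FWHM."""
    g1 = (width1 / 2.0) ** 2
    g2 = (width2 / 2.0) ** 2
    return (const
            + amp1 * g1 / ((x - peak1) ** 2 + g1)
            + amp2 * g2 / ((x - peak2) ** 2 + g2))


def _initial_maxima(values: np.ndarray, min_separation: int = 30
                    ) -> list[tuple[int, float]]:
    base = float(np.percentile(values, 10))
    spread = float(values.max() - base)
    if spread <= 0:
        return []
    idx, props = _signal.find_peaks(values, distance=min_separation,
                                    prominence=0.05 * spread)
    ranked = sorted(zip(idx, values[idx]), key=lambda t: -t[1])
    return [(int(i), float(v)) for i, v in ranked]


def fit_double_lorentzian(profile: SpectrumProfile | np.ndarray) -> SpectrumFit:
    """Least-squares fit of the double-Lorentzian-plus-offset model.

    Initialised from the two highest well-separated local maxima.  When fewer
    than two resolvable maxima exist, a single-Lorentzian fallback is fitted
    and reported with ``Amp2 = 0`` and ``converged = False``.  ``Peak1 <
    Peak2`` on output; ``residual_norm`` is the RMS residual.
    """
    values = profile.values if isinstance(profile, SpectrumProfile) else \
        np.asarray(profile, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("profile contains non-finite values")
    x = np.arange(len(values), dtype=float)
    maxima = _initial_maxima(values)
    base = float(np.percentile(values, 10))

    if len(maxima) >= 2:
        (p1, v1), (p2, v2) = maxima[0], maxima[1]
        if p1 > p2:
            (p1, v1), (p2, v2) = (p2, v2), (p1, v1)
        guess = [v1 - base, v2 - base, base, float(p1), float(p2), 10.0, 10.0]
        lo = [0.0, 0.0, -np.inf, 0.0, 0.0, 0.1, 0.1]
        hi = [np.inf] * 5 + [len(values) / 2.0] * 2
        try:
            popt, _ = curve_fit(double_lorentzian, x, values, p0=guess,
                                bounds=(lo, hi), maxfev=20000)
            converged = True
        except RuntimeError:
            popt, converged = guess, False
        a1, a2, c, pk1, pk2, w1, w2 = (float(v) for v in popt)
        if pk1 > pk2:
            a1, a2, pk1, pk2, w1, w2 = a2, a1, pk2, pk1, w2, w1
        resid = values - double_lorentzian(x, a1, a2, c, pk1, pk2, w1, w2)
        return SpectrumFit(a1, a2, c, pk1, pk2, w1, w2, converged=converged,
                           residual_norm=float(np.sqrt(np.mean(resid ** 2))))

    # Fallback: zero or one resolvable line.
    def single(xv, amp, const, peak, width):
        g = (width / 2.0) ** 2
        return const + amp * g / ((xv - peak) ** 2 + g)

    if len(maxima) == 1:
        p1, v1 = maxima[0]
        guess1 = [v1 - base, base, float(p1), 10.0]
        try:
            popt, _ = curve_fit(single, x, values, p0=guess1,
                                bounds=([0, -np.inf, 0, 0.1],
                                        [np.inf, np.inf, len(values), len(values) / 2]),
                                maxfev=20000)
        except RuntimeError:
            popt = guess1
        amp, const, peak, width = (float(v) for v in popt)
    else:
        amp, const, peak, width = 0.0, float(np.median(values)), len(values) / 2.0, 1.0
    resid = values - single(x, amp, const, peak, width)
    return SpectrumFit(amp, 0.0, const, peak, peak + 1.0, width, width,
                       converged=False,
                       residual_norm=float(np.sqrt(np.mean(resid ** 2))))


def build_calibration_points(narrow_readings: np.ndarray, wide_positions: np.ndarray,
                             quantum_kev: float = 0.001) -> list[CalibrationPoint]:
    """Group wide-range positions by identical narrow-range reading.

    The narrow spectrometer resolves more coarsely than the wide one, so many
    wide readings share one narrow value; each group contributes a single
    calibration point (median of the group's wide positions, the group's
    narrow energy).  "Identical" means equal after rounding the narrow reading
    to ``quantum_kev`` (default 1 eV).  Singleton groups are retained.  Output
    is sorted by narrow energy, making it invariant under permutation of the
    input pairs.
    """
    narrow = np.asarray(narrow_readings, dtype=float)
    wide = np.asarray(wide_positions, dtype=float)
    if narrow.shape != wide.shape:
        raise ValueError("narrow and wide reading lists must have equal length")
    if len(narrow) == 0:
        return []
    keys = np.round(narrow / quantum_kev).astype(np.int64)
    points = []
    for key in np.unique(keys):
        sel = keys == key
        points.append(CalibrationPoint(float(np.median(wide[sel])),
                                       float(np.median(narrow[sel]))))
    points.sort(key=lambda p: p.narrow_energy)
    return points


def fit_calibration(points: list[CalibrationPoint]) -> CalibrationFunction:
    """Ordinary least-squares line through the calibration points.

    Returns ``energy = c0 + c1 * x`` with ``valid_range`` the span of the
    input wide positions.  Requires at least two distinct positions.
    """
    xs = np.array([p.wide_position for p in points], dtype=float)
    ys = np.array([p.narrow_energy for p in points], dtype=float)
    if len(np.unique(xs)) < 2:
        raise ValueError("need at least two distinct wide positions to fit a line")
    if len(xs) == 2:
        c1 = (ys[1] - ys[0]) / (xs[1] - xs[0])
        c0 = ys[0] - c1 * xs[0]
    else:
        res = linregress(xs, ys)
        c0, c1 = float(res.intercept), float(res.slope)
    return CalibrationFunction(c0, c1, (float(xs.min()), float(xs.max())))


def assign_two_color_energies(fit: SpectrumFit,
                              cal_color1: CalibrationFunction,
                              cal_color2: CalibrationFunction
                              ) -> tuple[float, float, float, float]:
    """Convert fitted line positions into the two photon energies.

    Each Lorentzian position is evaluated with the calibration branch whose
    valid range contains it; colour 1 is the lower-energy (~7 keV) branch and
    colour 2 the higher-energy (~9 keV) branch, so ``energy1 < energy2``.
    Returns ``(energy1, energy2, wavelength1, wavelength2)`` in keV / Angstrom.
    """
    if not fit.converged:
        raise ValueError("cannot assign energies from an unconverged spectral fit")
    energies: dict[int, float] = {}
    for pk in (fit.Peak1, fit.Peak2):
        if cal_color1.contains(pk) and not cal_color2.contains(pk):
            branch = 1
        elif cal_color2.contains(pk) and not cal_color1.contains(pk):
            branch = 2
        elif cal_color1.contains(pk) and cal_color2.contains(pk):
            # Overlapping ranges: pick the branch already unassigned.
            branch = 1 if 1 not in energies else 2
        else:
            raise ValueError(
                f"fitted line at pixel {pk:.2f} lies outside both calibration ranges")
        if branch in energies:
            raise ValueError(
                f"both fitted lines fall in the colour-{branch} calibration range")
        cal = cal_color1 if branch == 1 else cal_color2
        energies[branch] = cal(pk)
    e1, e2 = energies[1], energies[2]
    if not e1 < e2:
        raise ValueError(
            f"branch convention violated: colour-1 energy {e1:.4f} keV is not "
            f"below colour-2 energy {e2:.4f} keV")
    return e1, e2, energy_to_wavelength(e1), energy_to_wavelength(e2)
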