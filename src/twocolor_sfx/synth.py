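"""Synthetic two-colour SFX data with known ground truth.

Generates every input the pipeline consumes — two-colour crystal diffraction
events, silicon powder frames, spectrometer camera images and multi-event
containers — so that all processing stages are testable without the deposited
dataset.  The defaults emulate the deposited study: a tetragonal lysozyme
cell (a = b = 78.3, c = 39.1 Angstrom), 7 and 9 keV double pulses with
anti-correlated amplitudes, an 8-panel detector at 51.03 mm read out as one
stacked frame, silicon powder rings and double-Lorentzian spectral profiles
on a 1024 x 512 spectrometer camera.

The intensity model is deliberately simple: per-reflection intensities are
Wilson-like exponential draws, fixed per (h, k, l) per event through a
hash-seeded generator; spots are isotropic Gaussians; the background is
Poisson.  All randomness flows through a single seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from .core import (
    DetectorGeometry,
    Orientation,
    Peak,
    PeakList,
    PhotonBeam,
    UnitCell,
)
from .indexing import IndexParams, predict_reflections
from .powder import ring_radius
from .spectro import CalibrationFunction, SpectrumFit, double_lorentzian

__all__ = [
    "NoiseModel",
    "TwoColorEventTruth",
    "PowderTruth",
    "SyntheticRunConfig",
    "tetragonal_lysozyme_cell",
    "reduced_geometry",
    "draw_anticorrelated_amplitudes",
    "simulate_crystal_pattern",
    "simulate_two_color_event",
    "simulate_powder_image",
    "simulate_spectrum_image",
    "write_synthetic_run",
]


def tetragonal_lysozyme_cell() -> UnitCell:
    """The tetragonal lysozyme cell of the study, a = b = 78.3, c = 39.1 A."""
    return UnitCell(78.3, 78.3, 39.1, 90.0, 90.0, 90.0, "tetragonal")


def reduced_geometry(n_panels: int = 2) -> DetectorGeometry:
    """Desk-scale detector: a centred ``n_panels``-panel subset of the stack."""
    return DetectorGeometry(
        n_panels=n_panels,
        beam_center=(n_panels * 1024 / 2.0, 256.0),
    )


@dataclass(frozen=True)
class NoiseModel:
    """Background and readout noise: Poisson mean plus Gaussian sigma per pixel."""

    background_mean: float = 5.0
    readout_sigma: float = 0.0

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(0.0, 0.0)

    @property
    def enabled(self) -> bool:
        return self.background_mean > 0 or self.readout_sigma > 0


@dataclass(frozen=True)
class TwoColorEventTruth:
    """Ground truth of one simulated two-colour event."""

    orientation: Orientation
    energies: tuple[float, float]  # keV, actual per-event values
    amplitudes: tuple[float, float]
    true_peaks_color1: PeakList
    true_peaks_color2: PeakList
    tag: str = ""

    def __post_init__(self) -> None:
        e1, e2 = self.energies
        if e1 <= 0 or e2 <= 0 or e1 == e2:
            raise ValueError("event energies must be positive and distinct")
        if min(self.amplitudes) < 0:
            raise ValueError("amplitudes must be non-negative")


@dataclass(frozen=True)
class PowderTruth:
    """Ground truth of a simulated powder frame.

    ``true_radii`` holds NaN for spacings whose ring cannot exist at the
    simulation wavelength (d <= lambda/2 or 2theta >= 90 deg).
    """

    d_spacings: tuple[float, ...]
    true_radii: tuple[float, ...]  # mm; NaN marks an absent ring
    distance: float  # mm

    def __post_init__(self) -> None:
        present = [r for r in self.true_radii if np.isfinite(r)]
        if any(present[i] >= present[i + 1] for i in range(len(present) - 1)):
            raise ValueError("radii must strictly increase as d decreases")


# ---------------------------------------------------------------------------
# hash-seeded per-reflection intensities
# ---------------------------------------------------------------------------

def _hash_uniform(event_key: int, hkl: np.ndarray) -> np.ndarray:
    """Deterministic uniform (0, 1) draw per (event, h, k, l), splitmix-style."""
    h = hkl.astype(np.int64)
    x = ((h[:, 0] + 2048).astype(np.uint64)
         ^ ((h[:, 1] + 2048).astype(np.uint64) << np.uint64(13))
         ^ ((h[:, 2] + 2048).astype(np.uint64) << np.uint64(26))
         ^ (np.uint64(event_key) << np.uint64(39)))
    with np.errstate(over="ignore"):
        z = x + np.uint64(0x9E3779B97F4A7C15)
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        z = z ^ (z >> np.uint64(31))
    return (z.astype(np.float64) + 0.5) / 2.0 ** 64


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _stamp_spots(image: np.ndarray, positions: np.ndarray,
                 intensities: np.ndarray, sigma: float) -> None:
    """Add Gaussian spots (integrated counts = intensity) in place."""
    ns, nf = image.shape
    r = int(np.ceil(4.0 * sigma)) + 1
    norm = 1.0 / (2.0 * np.pi * sigma * sigma)
    for (cs, cf), inten in zip(positions, intensities):
        s0 = int(round(cs))
        f0 = int(round(cf))
        slo, shi = max(s0 - r, 0), min(s0 + r + 1, ns)
        flo, fhi = max(f0 - r, 0), min(f0 + r + 1, nf)
        if slo >= shi or flo >= fhi:
            continue
        ss = np.arange(slo, shi)[:, None]
        ff = np.arange(flo, fhi)[None, :]
        g = np.exp(-((ss - cs) ** 2 + (ff - cf) ** 2) / (2.0 * sigma * sigma))
        image[slo:shi, flo:fhi] += inten * norm * g


def _render_pattern(cell: UnitCell, orientation: Orientation,
                    geometry: DetectorGeometry, beam: PhotonBeam,
                    amplitude: float, event_key: int, spot_sigma: float,
                    resolution_cutoff: float) -> tuple[np.ndarray, PeakList]:
    """Noise-free single-colour render plus its exact truth peak list."""
    params = IndexParams(bandwidth_tolerance=beam.bandwidth_fraction,
                         resolution_cutoff=resolution_cutoff)
    preds = predict_reflections(cell, orientation, beam, geometry, params)
    image = np.zeros(geometry.assembled_shape, dtype=float)
    if len(preds) == 0:
        return image, PeakList([], meta={"no_reflections": True})
    u = _hash_uniform(event_key, preds.hkl)
    intensities = amplitude * (-np.log1p(-u))
    _stamp_spots(image, preds.pos, intensities, spot_sigma)
    truth = PeakList(
        [Peak((float(s), float(f)), float(i), geometry.panel_of(s))
         for (s, f), i in zip(preds.pos, intensities)],
        meta={"hkl": preds.hkl.copy(), "spot_sigma": spot_sigma},
    )
    return image, truth


def _apply_noise(image: np.ndarray, noise: NoiseModel,
                 rng: np.random.Generator) -> np.ndarray:
    if not noise.enabled:
        return image
    out = rng.poisson(image + noise.background_mean).astype(float)
    if noise.readout_sigma > 0:
        out = out + rng.normal(0.0, noise.readout_sigma, size=image.shape)
    return out


def simulate_crystal_pattern(cell: UnitCell, orientation: Orientation,
                             geometry: DetectorGeometry, beam: PhotonBeam,
                             amplitude: float,
                             noise_model: NoiseModel | None = None,
                             seed: int | np.random.Generator = 0,
                             spot_sigma: float = 1.2,
                             resolution_cutoff: float = 1.9
                             ) -> tuple[np.ndarray, PeakList]:
    """Single-colour diffraction image of one crystal in one orientation.

    Spots are Gaussians (sigma ``spot_sigma`` pixels) at the detector
    positions of every reflection excited within the beam bandwidth, with
    integrated counts ``amplitude`` times a Wilson-like exponential draw fixed
    per (h, k, l); Poisson background is added per ``noise_model``.  The truth
    list carries the exact sub-pixel positions and integrated intensities.
    A geometry that excites no reflection yields an empty truth flagged
    ``meta['no_reflections']``, not an error.
    """
    if amplitude <= 0:
        raise ValueError("amplitude must be positive")
    noise_model = noise_model if noise_model is not None else NoiseModel()
    rng = _as_rng(seed)
    event_key = int(rng.integers(0, 2 ** 24))
    image, truth = _render_pattern(cell, orientation, geometry, beam,
                                   amplitude, event_key, spot_sigma,
                                   resolution_cutoff)
    return _apply_noise(image, noise_model, rng), truth


def draw_anticorrelated_amplitudes(rng: np.random.Generator,
                                   total: float = 12000.0,
                                   jitter: float = 0.05,
                                   split_range: tuple[float, float] = (0.3, 0.7)
                                   ) -> tuple[float, float]:
    """Amplitude pair with ``a1 + a2 = total`` up to fractional ``jitter``.

    Models the anti-correlation of the double-pulse intensities: the pulse
    energies compete for a near-constant budget, the per-event split fraction
    being uniform on ``split_range``.  With ``jitter = 0`` the sum is exact.
    """
    t = total * (1.0 + jitter * rng.uniform(-1.0, 1.0))
    f = rng.uniform(*split_range)
    return f * t, (1.0 - f) * t


def simulate_two_color_event(cell: UnitCell, geometry: DetectorGeometry,
                             energies: tuple[float, float] = (7.0, 9.0),
                             anticorrelation_total: float = 12000.0,
                             jitter: float = 0.05,
                             split_range: tuple[float, float] = (0.3, 0.7),
                             noise_model: NoiseModel | None = None,
                             seed: int | np.random.Generator = 0,
                             spot_sigma: float = 1.2,
                             resolution_cutoff: float = 1.9,
                             bandwidth_fraction: float = 0.003,
                             energy_jitter_fraction: float = 5e-4,
                             tag: str = "") -> tuple[np.ndarray, TwoColorEventTruth]:
    """One two-colour image: two patterns of one crystal, superimposed.

    Both colours share a single random orientation (the same crystal); their
    amplitudes are drawn anti-correlated (see
    :func:`draw_anticorrelated_amplitudes`); per-event photon energies jitter
    around the nominals by ``energy_jitter_fraction`` (SASE shot-to-shot
    drift).  Noise is applied once to the summed image.
    """
    e_lo, e_hi = sorted(energies)
    if not e_lo < e_hi:
        raise ValueError("the two photon energies must be distinct")
    noise_model = noise_model if noise_model is not None else NoiseModel()
    rng = _as_rng(seed)
    orientation = Orientation.random(rng)
    a1, a2 = draw_anticorrelated_amplitudes(rng, anticorrelation_total,
                                            jitter, split_range)
    e1 = e_lo * (1.0 + energy_jitter_fraction * rng.uniform(-1.0, 1.0))
    e2 = e_hi * (1.0 + energy_jitter_fraction * rng.uniform(-1.0, 1.0))
    keys = rng.integers(0, 2 ** 24, size=2)
    img1, truth1 = _render_pattern(cell, orientation, geometry,
                                   PhotonBeam.from_energy(e1, bandwidth_fraction),
                                   a1, int(keys[0]), spot_sigma, resolution_cutoff)
    img2, truth2 = _render_pattern(cell, orientation, geometry,
                                   PhotonBeam.from_energy(e2, bandwidth_fraction),
                                   a2, int(keys[1]), spot_sigma, resolution_cutoff)
    image = _apply_noise(img1 + img2, noise_model, rng)
    truth = TwoColorEventTruth(orientation, (e1, e2), (a1, a2),
                               truth1, truth2, tag=tag)
    return image, truth


def simulate_powder_image(d_spacings, geometry: DetectorGeometry,
                          wavelength: float, ring_intensity: float = 50.0,
                          noise_model: NoiseModel | None = None,
                          seed: int | np.random.Generator = 0,
                          ring_sigma_px: float = 1.5
                          ) -> tuple[np.ndarray, PowderTruth]:
    """Azimuthally uniform Debye-Scherrer rings with Poisson background.

    Rings sit at ``r = distance * tan(2 asin(lambda / 2d))``; spacings that
    cannot diffract at this wavelength (or scatter beyond 90 degrees) are
    omitted and recorded as NaN in the truth.
    """
    noise_model = noise_model if noise_model is not None else NoiseModel()
    rng = _as_rng(seed)
    radii = []
    for d in d_spacings:
        try:
            radii.append(ring_radius(float(d), wavelength, geometry.distance))
        except ValueError:
            radii.append(float("nan"))
    shape = geometry.assembled_shape
    idx = np.indices(shape).reshape(2, -1).T.astype(float)
    xy = geometry.pixel_to_mm(idx)
    r_mm = np.hypot(xy[:, 0], xy[:, 1]).reshape(shape)
    sigma_mm = ring_sigma_px * geometry.pixel_size
    image = np.zeros(shape, dtype=float)
    for r in radii:
        if np.isfinite(r):
            image += ring_intensity * np.exp(-(r_mm - r) ** 2 / (2.0 * sigma_mm ** 2))
    image = _apply_noise(image, noise_model, rng)
    truth = PowderTruth(tuple(float(d) for d in d_spacings),
                        tuple(radii), geometry.distance)
    return image, truth


def simulate_spectrum_image(fit_truth: SpectrumFit,
                            camera_shape: tuple[int, int] = (1024, 512),
                            noise_model: NoiseModel | None = None,
                            seed: int | np.random.Generator = 0) -> np.ndarray:
    """Wide-range spectrometer camera frame for a known spectral model.

    Every one of the ``camera_shape[1]`` non-dispersive columns carries the
    double-Lorentzian profile evaluated on the dispersive axis, so collapsing
    recovers ``camera_shape[1]`` times the generating profile; Gaussian
    readout noise is added per ``noise_model.readout_sigma``.
    """
    if fit_truth.Peak1 == fit_truth.Peak2:
        raise ValueError("spectral model must have two distinct line positions")
    noise_model = noise_model if noise_model is not None else NoiseModel(0.0, 5.0)
    rng = _as_rng(seed)
    x = np.arange(camera_shape[0], dtype=float)
    profile = double_lorentzian(x, fit_truth.Amp1, fit_truth.Amp2,
                                fit_truth.Const, fit_truth.Peak1,
                                fit_truth.Peak2, fit_truth.Width1,
                                fit_truth.Width2)
    image = np.tile(profile[:, None], (1, camera_shape[1]))
    if noise_model.readout_sigma > 0:
        image = image + rng.normal(0.0, noise_model.readout_sigma,
                                   size=image.shape)
    return image


# ---------------------------------------------------------------------------
# multi-event synthetic runs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticRunConfig:
    """Study conditions of a synthetic two-colour run.

    Defaults mirror the emulated experiment: tetragonal lysozyme cell,
    7 / 9 keV colours with anti-correlated amplitudes, SASE bandwidth 0.3%,
    1.9 Angstrom resolution limit, Poisson background of 5 counts/pixel, and
    the canonical spectrometer calibration branches used to place the
    spectral lines on the camera.
    """

    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    cell: UnitCell = field(default_factory=tetragonal_lysozyme_cell)
    energies: tuple[float, float] = (7.0, 9.0)
    anticorrelation_total: float = 12000.0
    jitter: float = 0.05
    split_range: tuple[float, float] = (0.3, 0.7)
    noise: NoiseModel = field(default_factory=NoiseModel)
    spot_sigma: float = 1.2
    resolution_cutoff: float = 1.9
    bandwidth_fraction: float = 0.003
    energy_jitter_fraction: float = 5e-4
    cal_color1: CalibrationFunction = field(
        default_factory=CalibrationFunction.color1_default)
    cal_color2: CalibrationFunction = field(
        default_factory=CalibrationFunction.color2_default)
    camera_shape: tuple[int, int] = (1024, 512)
    spectrum_noise_sigma: float = 5.0
    spectrum_const: float = 10.0
    spectrum_widths: tuple[float, float] = (8.0, 10.0)

    def spectrum_truth(self, energies: tuple[float, float],
                       amplitudes: tuple[float, float]) -> SpectrumFit:
        """Spectral model placing the event's lines via the inverse calibrations."""
        x1 = (energies[0] - self.cal_color1.c0) / self.cal_color1.c1
        x2 = (energies[1] - self.cal_color2.c0) / self.cal_color2.c1
        # Camera amplitudes scale with the pulse amplitudes.
        a1 = max(amplitudes[0] / 20.0, 1.0)
        a2 = max(amplitudes[1] / 20.0, 1.0)
        return SpectrumFit(a1, a2, self.spectrum_const, x1, x2,
                           self.spectrum_widths[0], self.spectrum_widths[1])


def write_synthetic_run(path: str | Path, n_events: int,
                        config: SyntheticRunConfig | None = None,
                        seed: int = 0) -> tuple[Path, Path]:
    """Write a multi-event container plus a ground-truth sidecar.

    The container holds one ``/events/<tag>`` group per event with the
    assembled diffraction frame, the spectrometer camera frame and the
    nominal colour-1 energy/wavelength scalars; every ground-truth record
    lives in a separate ``<path>.truth.h5`` sidecar keyed by tag, never mixed
    into the emulated event schema.  Identical (config, seed) give identical
    files.  Returns ``(container_path, truth_path)``.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    config = config or SyntheticRunConfig()
    path = Path(path)
    truth_path = path.with_suffix(path.suffix + ".truth.h5")
    rng = np.random.default_rng(seed)
    from .core import energy_to_wavelength
    with h5py.File(path, "w") as fh, h5py.File(truth_path, "w") as th:
        ev_grp = fh.create_group("events")
        tr_grp = th.create_group("truth")
        for i in range(n_events):
            tag = f"{i:06d}"
            image, truth = simulate_two_color_event(
                config.cell, config.geometry, config.energies,
                config.anticorrelation_total, config.jitter,
                config.split_range, config.noise, rng,
                config.spot_sigma, config.resolution_cutoff,
                config.bandwidth_fraction, config.energy_jitter_fraction,
                tag=tag)
            spec_truth = config.spectrum_truth(truth.energies, truth.amplitudes)
            camera = simulate_spectrum_image(
                spec_truth, config.camera_shape,
                NoiseModel(0.0, config.spectrum_noise_sigma), rng)
            g = ev_grp.create_group(tag)
            g.create_dataset("data", data=image.astype(np.float32))
            g.create_dataset("spectro_camera", data=camera.astype(np.float32))
            g.create_dataset("photon_energy_ev",
                             data=float(config.energies[0]) * 1000.0)
            g.create_dataset(
                "photon_wavelength_A",
                data=energy_to_wavelength(float(config.energies[0])))
            t = tr_grp.create_group(tag)
            t.create_dataset("orientation", data=truth.orientation.rotation)
            t.create_dataset("energies_kev", data=np.array(truth.energies))
            t.create_dataset("amplitudes", data=np.array(truth.amplitudes))
            t.create_dataset("peaks_color1", data=truth.true_peaks_color1.to_array())
            t.create_dataset("peaks_color2", data=truth.true_peaks_color2.to_array())
            t.create_dataset("spectrum_params", data=np.array([
                spec_truth.Amp1, spec_truth.Amp2, spec_truth.Const,
                spec_truth.Peak1, spec_truth.Peak2, spec_truth.Width1,
                spec_truth.Width2]))
    return path, truth_path


def read_truth_sidecar(truth_path: str | Path) -> dict[str, TwoColorEventTruth]:
    """Load the ground-truth records of a synthetic run, keyed by tag."""
    out: dict[str, TwoColorEventTruth] = {}
    with h5py.File(truth_path, "r") as th:
        for tag, g in th["truth"].items():
            out[tag] = TwoColorEventTruth(
                Orientation(g["orientation"][()]),
                tuple(g["energies_kev"][()]),
                tuple(g["amplitudes"][()]),
                PeakList.from_array(g["peaks_color1"][()]),
                PeakList.from_array(g["peaks_color2"][()]),
                tag=tag,
            )
    return out
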