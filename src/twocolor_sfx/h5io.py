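"""Readers and writers for the deposited HDF5 event schema, and the pipeline.

Event files follow the deposited field inventory: an assembled ``data`` frame
per event plus scalar ``photon_energy_ev`` / ``photon_wavelength_A`` fields,
per-colour variants ``photon_energy_ev_color1/2`` and
``photon_wavelength_A_color1/2`` (colour 1 is the 7 keV branch), interest
points under ``poi`` / ``pca_peaks/<n>`` and weak-pattern residual peaks
under ``residual_points_7keV`` / ``residual_points_9keV`` as ``{n, 3}``
arrays of (slow, fast, intensity).  Spectra files carry ``spectrum`` {n,
1024}, the seven fit-parameter datasets ``Amp1`` ... ``Width2`` and ``tags``.

Multi-event containers are split into per-event files before processing;
every event-file write is atomic (temp file + rename), so an interrupted
pipeline never corrupts an event file.
"""

from __future__ import annotations

import logging
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .core import DetectorGeometry, PeakList, UnitCell, energy_to_wavelength
from .indexing import IndexParams, process_two_color_event
from .peaks import PeakFindParams, find_peaks, is_hit
from .report import RunSummary
from .spectro import (
    CalibrationFunction,
    SpectrumFit,
    assign_two_color_energies,
    collapse_spectrum,
    fit_double_lorentzian,
    PROFILE_LENGTH,
)

logger = logging.getLogger(__name__)

__all__ = [
    "EventRecord",
    "split_events",
    "read_event_file",
    "write_event_file",
    "write_color_energies",
    "write_spectra_file",
    "read_spectra_file",
    "write_residual_points",
    "PipelineConfig",
    "run_pipeline",
]

_FIT_FIELDS = ("Amp1", "Amp2", "Const", "Peak1", "Peak2", "Width1", "Width2")


@dataclass
class EventRecord:
    """One diffraction event: tag, assembled image, named metadata fields."""

    tag: str
    image: np.ndarray
    metadata: dict[str, np.ndarray | float | str] = field(default_factory=dict)


def _atomic_h5(path: Path):
    """Context-manager-ish helper: returns (tmp_path, finalize)."""
    fd, tmp = tempfile.mkstemp(dir=path.parent, suffix=".h5.tmp")
    os.close(fd)
    return Path(tmp)


def write_event_file(path: str | Path, record: EventRecord) -> Path:
    """Write a single-event file atomically (temp file, then rename)."""
    path = Path(path)
    tmp = _atomic_h5(path)
    try:
        with h5py.File(tmp, "w") as fh:
            fh.create_dataset("data", data=record.image)
            fh.create_dataset("tag", data=record.tag)
            for name, value in record.metadata.items():
                fh.create_dataset(name, data=value)
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()
    return path


def read_event_file(path: str | Path) -> EventRecord:
    with h5py.File(path, "r") as fh:
        if "data" not in fh:
            raise ValueError(f"{path}: not an event file (no 'data' dataset)")
        image = fh["data"][()]
        tag = fh["tag"][()].decode() if "tag" in fh else Path(path).stem
        metadata = {}
        for name in fh:
            if name in ("data", "tag"):
                continue
            obj = fh[name]
            if isinstance(obj, h5py.Group):
                for sub in obj:
                    metadata[f"{name}/{sub}"] = obj[sub][()]
            else:
                metadata[name] = obj[()]
    return EventRecord(tag, image, metadata)


def split_events(container_path: str | Path, out_dir: str | Path) -> list[Path]:
    """Split a multi-event container into per-event files.

    The container groups events under ``/events/<tag>``; each output file
    carries the event's ``data`` frame and all present metadata.  A
    single-event file passes straight through (copied into ``out_dir``), so
    re-splitting split output is a no-op.  An empty container yields an empty
    list with a warning.  The source container is never modified.
    """
    container_path = Path(container_path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out: list[Path] = []
    with h5py.File(container_path, "r") as fh:
        if "data" in fh:  # already a single-event file
            rec = read_event_file(container_path)
            target = out_dir / f"{rec.tag}.h5"
            if target.resolve() != container_path.resolve():
                write_event_file(target, rec)
            else:
                target = container_path
            return [target]
        if "events" not in fh or len(fh["events"]) == 0:
            warnings.warn(f"{container_path}: container holds no events")
            return []
        for i, tag in enumerate(sorted(fh["events"])):
            grp = fh["events"][tag]
            if "data" not in grp:
                raise ValueError(
                    f"{container_path}: event index {i} (tag {tag!r}) has no 'data'")
            metadata = {name: grp[name][()] for name in grp if name != "data"}
            rec = EventRecord(tag, grp["data"][()], metadata)
            out.append(write_event_file(out_dir / f"{tag}.h5", rec))
    return out


def write_color_energies(event_path: str | Path, energy1_kev: float,
                         energy2_kev: float, wavelength1_a: float,
                         wavelength2_a: float, overwrite: bool = False) -> None:
    """Write the four per-colour energy/wavelength scalars into an event file.

    Colour 1 is the 7 keV branch, so ``energy1 < energy2`` is required; each
    energy/wavelength pair must be mutually consistent through ``hc``.
    Pre-existing fields raise unless ``overwrite`` is set.
    """
    if not energy1_kev < energy2_kev:
        raise ValueError(
            f"colour-1 energy ({energy1_kev}) must be below colour-2 ({energy2_kev})")
    for e, wl in ((energy1_kev, wavelength1_a), (energy2_kev, wavelength2_a)):
        expect = energy_to_wavelength(e)
        if abs(wl - expect) > 1e-6 * expect:
            raise ValueError(
                f"energy {e} keV and wavelength {wl} A are inconsistent")
    names = {
        "photon_energy_ev_color1": energy1_kev * 1000.0,
        "photon_energy_ev_color2": energy2_kev * 1000.0,
        "photon_wavelength_A_color1": wavelength1_a,
        "photon_wavelength_A_color2": wavelength2_a,
    }
    with h5py.File(event_path, "a") as fh:
        present = [n for n in names if n in fh]
        if present and not overwrite:
            raise ValueError(
                f"{event_path}: colour fields already present {present}; "
                "pass overwrite=True to replace")
        for n in present:
            del fh[n]
        for n, v in names.items():
            fh.create_dataset(n, data=float(v))


def write_spectra_file(path: str | Path, profiles: np.ndarray,
                       fits: list[SpectrumFit], tags: list[str]) -> Path:
    """Write a spectra file: ``spectrum`` {n, 1024}, fit parameters, ``tags``."""
    profiles = np.asarray(profiles, dtype=float)
    if profiles.ndim != 2 or profiles.shape[1] != PROFILE_LENGTH:
        raise ValueError(f"profiles must be (n, {PROFILE_LENGTH})")
    if not (len(profiles) == len(fits) == len(tags)):
        raise ValueError("profiles, fits and tags must have equal length")
    path = Path(path)
    tmp = _atomic_h5(path)
    try:
        with h5py.File(tmp, "w") as fh:
            fh.create_dataset("spectrum", data=profiles)
            for name in _FIT_FIELDS:
                fh.create_dataset(
                    name, data=np.array([getattr(f, name) for f in fits]))
            fh.create_dataset("tags", data=np.array(tags, dtype="S"))
        os.replace(tmp, path)
    finally:
        if tmp.exists():
            tmp.unlink()
    return path


def read_spectra_file(path: str | Path
                      ) -> tuple[np.ndarray, list[SpectrumFit], list[str]]:
    with h5py.File(path, "r") as fh:
        profiles = fh["spectrum"][()]
        cols = {name: fh[name][()] for name in _FIT_FIELDS}
        tags = [t.decode() for t in fh["tags"][()]]
    fits = [SpectrumFit(*(float(cols[name][i]) for name in _FIT_FIELDS))
            for i in range(len(tags))]
    return profiles, fits, tags


def write_residual_points(event_path: str | Path, residual: PeakList,
                          colour_label: str) -> None:
    """Write the weak-pattern residual peaks, ``residual_points_<label>`` {n, 3}.

    ``colour_label`` names the colour the residual plausibly belongs to
    (``'7keV'`` or ``'9keV'``).  An empty residual writes an explicit {0, 3}
    dataset.
    """
    if colour_label not in ("7keV", "9keV"):
        raise ValueError(f"colour label must be '7keV' or '9keV', got {colour_label!r}")
    name = f"residual_points_{colour_label}"
    with h5py.File(event_path, "a") as fh:
        if name in fh:
            del fh[name]
        fh.create_dataset(name, data=residual.to_array().reshape(-1, 3))


def read_residual_points(event_path: str | Path, colour_label: str) -> np.ndarray:
    with h5py.File(event_path, "r") as fh:
        return fh[f"residual_points_{colour_label}"][()]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Configuration of a full synthetic-run pipeline execution."""

    out_dir: Path
    n_events: int = 50
    seed: int = 0
    container: Path | None = None  # use an existing container instead of simulating
    synth: "object | None" = None  # SyntheticRunConfig; default conditions if None
    geometry: DetectorGeometry = field(default_factory=DetectorGeometry)
    cell: UnitCell | None = None
    strong_params: PeakFindParams = field(default_factory=PeakFindParams.strong)
    weak_params: PeakFindParams = field(default_factory=PeakFindParams.weak)
    index_params: IndexParams = field(default_factory=IndexParams)
    cal_color1: CalibrationFunction = field(
        default_factory=CalibrationFunction.color1_default)
    cal_color2: CalibrationFunction = field(
        default_factory=CalibrationFunction.color2_default)
    min_hit_peaks: int = 20
    subtract: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        """Minimal YAML loader: keys mirror the dataclass fields."""
        from .synth import SyntheticRunConfig, reduced_geometry, tetragonal_lysozyme_cell
        raw = yaml.safe_load(Path(path).read_text()) or {}
        geometry = DetectorGeometry()
        if "geometry_file" in raw:
            geometry = DetectorGeometry.from_file(raw["geometry_file"])
        elif raw.get("reduced_panels"):
            geometry = reduced_geometry(int(raw["reduced_panels"]))
        cell = (UnitCell.from_file(raw["cell_file"]) if "cell_file" in raw
                else tetragonal_lysozyme_cell())
        kwargs = dict(
            out_dir=Path(raw["out_dir"]),
            n_events=int(raw.get("n_events", 50)),
            seed=int(raw.get("seed", 0)),
            geometry=geometry,
            cell=cell,
            subtract=bool(raw.get("subtract", True)),
        )
        if "container" in raw:
            kwargs["container"] = Path(raw["container"])
        else:
            kwargs["synth"] = SyntheticRunConfig(geometry=geometry, cell=cell)
        return cls(**kwargs)


def run_pipeline(config: PipelineConfig | str | Path) -> RunSummary:
    """Execute split -> hit filter -> spectra -> two-colour processing.

    Per-event failures are logged and counted, never fatal: serial
    crystallography is per-event independent.  Returns the stage-count
    summary; per-event outcome records ride along in ``summary.events``.
    """
    from .synth import SyntheticRunConfig, tetragonal_lysozyme_cell

    if not isinstance(config, PipelineConfig):
        config = PipelineConfig.from_yaml(config)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cell = config.cell or tetragonal_lysozyme_cell()

    if config.container is None:
        synth_cfg = config.synth
        if synth_cfg is None:
            synth_cfg = SyntheticRunConfig(geometry=config.geometry, cell=cell)
        from .synth import write_synthetic_run
        container, _truth = write_synthetic_run(
            out_dir / "run.h5", config.n_events, synth_cfg, config.seed)
        geometry = synth_cfg.geometry
    else:
        container = config.container
        geometry = config.geometry
    logger.info("pipeline start: container=%s geometry=%s subtract=%s",
                container, geometry.assembled_shape, config.subtract)

    event_paths = split_events(container, out_dir / "events")
    records: list[dict] = []
    spectra_rows: list[tuple[np.ndarray, SpectrumFit, str]] = []
    n_hits = n_c1 = n_c2 = n_both = 0

    for path in event_paths:
        rec = read_event_file(path)
        outcome = {"tag": rec.tag, "stage": "hit_filter", "status": "no_hit",
                   "score": 0}
        try:
            speaks = find_peaks(rec.image, geometry, config.strong_params)
            hit = is_hit(speaks, config.min_hit_peaks)
            if not hit:
                records.append(outcome)
                continue
            n_hits += 1

            # Spectral chain: recover both photon energies.
            energies = None
            if "spectro_camera" in rec.metadata:
                profile = collapse_spectrum(rec.metadata["spectro_camera"],
                                            tag=rec.tag)
                sfit = fit_double_lorentzian(profile)
                spectra_rows.append((profile.values, sfit, rec.tag))
                if sfit.converged:
                    e1, e2, wl1, wl2 = assign_two_color_energies(
                        sfit, config.cal_color1, config.cal_color2)
                    write_color_energies(path, e1, e2, wl1, wl2, overwrite=True)
                    energies = (e1, e2)
            if energies is None:
                outcome.update(stage="spectra", status="no_energies")
                records.append(outcome)
                continue

            result = process_two_color_event(
                rec.image, energies, cell, geometry,
                config.strong_params, config.weak_params, config.index_params,
                subtract=config.subtract)
            weak_label = "7keV" if result.strong_color == "color2" else "9keV"
            if result.strong_color is not None:
                write_residual_points(path, result.residual, weak_label)
            colors = set()
            if result.strong_solution is not None:
                colors.add(result.strong_color)
            if result.weak_solution is not None:
                colors.add("color1" if result.strong_color == "color2" else "color2")
            n_c1 += "color1" in colors
            n_c2 += "color2" in colors
            n_both += result.status == "both"
            outcome.update(
                stage="two_color", status=result.status,
                score=(result.strong_solution.score
                       if result.strong_solution else 0))
            records.append(outcome)
        except Exception as exc:  # per-event isolation
            logger.warning("event %s failed: %s", rec.tag, exc)
            outcome.update(stage="error", status=str(exc))
            records.append(outcome)
        logger.info("event %s: %s (%s)", rec.tag, outcome["status"],
                    outcome["stage"])

    if spectra_rows:
        write_spectra_file(out_dir / "spectra.h5",
                           np.array([r[0] for r in spectra_rows]),
                           [r[1] for r in spectra_rows],
                           [r[2] for r in spectra_rows])
    summary = RunSummary(len(event_paths), n_hits, n_c1, n_c2, n_both,
                         tuple(records))
    (out_dir / "summary.tsv").write_text(summary.to_text())
    return summary
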