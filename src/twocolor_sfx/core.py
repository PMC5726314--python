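"""Shared domain types, physical constants and lattice geometry.

Everything downstream (simulation, peak finding, powder calibration, two-colour
indexing) speaks in terms of the types defined here: a unit cell, a flat
multi-panel detector, Bragg peaks, crystal orientations and photon beams.

Coordinate conventions
----------------------
Assembled detector images are 2-D arrays of shape ``(n_panels * panel_slow,
panel_fast)`` — panels stacked along the slow axis, matching an 8-panel
multiport CCD read out as a single ``{8192, 512}`` frame.  Pixel coordinates
are 0-based ``(slow, fast)`` pairs; an integer coordinate addresses the pixel
*centre*.  The laboratory frame puts ``z`` along the incident beam (towards
the detector), ``x`` along the fast axis and ``y`` along the slow axis; the
detector plane sits at ``z = distance``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from scipy.spatial.transform import Rotation as _ScipyRotation

#: Conversion constant between photon energy and wavelength, hc in keV * Angstrom.
HC_KEV_ANGSTROM = 12.3984193

__all__ = [
    "HC_KEV_ANGSTROM",
    "UnitCell",
    "DetectorGeometry",
    "Peak",
    "PeakList",
    "Orientation",
    "PhotonBeam",
    "energy_to_wavelength",
    "wavelength_to_energy",
    "direct_basis",
    "reciprocal_basis",
    "symmetry_rotations",
    "misorientation_deg",
    "canonical_orientation",
]


# ---------------------------------------------------------------------------
# energy / wavelength
# ---------------------------------------------------------------------------

def energy_to_wavelength(energy_kev: float) -> float:
    """Photon wavelength in Angstrom for an energy in keV (lambda = hc / E)."""
    if energy_kev <= 0:
        raise ValueError(f"photon energy must be positive, got {energy_kev}")
    return HC_KEV_ANGSTROM / energy_kev


def wavelength_to_energy(wavelength_angstrom: float) -> float:
    """Photon energy in keV for a wavelength in Angstrom (inverse map)."""
    if wavelength_angstrom <= 0:
        raise ValueError(f"wavelength must be positive, got {wavelength_angstrom}")
    return HC_KEV_ANGSTROM / wavelength_angstrom


# ---------------------------------------------------------------------------
# unit cell and lattice geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell: lengths in Angstrom, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0
    lattice_system: str = "other"

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValueError(f"cell length {name} must be positive")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValueError(f"cell angle {name} must lie in (0, 180)")
        if self.lattice_system not in ("tetragonal", "cubic", "other"):
            raise ValueError(f"unknown lattice system {self.lattice_system!r}")
        if self.lattice_system == "tetragonal":
            if not math.isclose(self.a, self.b, rel_tol=1e-9):
                raise ValueError("tetragonal cell requires a == b")
            if any(not math.isclose(getattr(self, n), 90.0, abs_tol=1e-9)
                   for n in ("alpha", "beta", "gamma")):
                raise ValueError("tetragonal cell requires all angles 90")
        if self.lattice_system == "cubic":
            if not (math.isclose(self.a, self.b, rel_tol=1e-9)
                    and math.isclose(self.a, self.c, rel_tol=1e-9)):
                raise ValueError("cubic cell requires a == b == c")
            if any(not math.isclose(getattr(self, n), 90.0, abs_tol=1e-9)
                   for n in ("alpha", "beta", "gamma")):
                raise ValueError("cubic cell requires all angles 90")

    @property
    def volume(self) -> float:
        """Cell volume in cubic Angstrom (general triclinic formula)."""
        ca, cb, cg = (math.cos(math.radians(x)) for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            raise ValueError("degenerate cell: zero or imaginary volume")
        return self.a * self.b * self.c * math.sqrt(arg)

    @classmethod
    def from_file(cls, path: str | Path) -> "UnitCell":
        """Read a key = value text cell file (a, b, c, alpha, beta, gamma, lattice_system)."""
        kv = _read_keyvalue(path)
        return cls(
            a=float(kv["a"]), b=float(kv["b"]), c=float(kv["c"]),
            alpha=float(kv.get("alpha", 90.0)),
            beta=float(kv.get("beta", 90.0)),
            gamma=float(kv.get("gamma", 90.0)),
            lattice_system=kv.get("lattice_system", "other"),
        )

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"a = {self.a!r}", f"b = {self.b!r}", f"c = {self.c!r}",
            f"alpha = {self.alpha!r}", f"beta = {self.beta!r}", f"gamma = {self.gamma!r}",
            f"lattice_system = {self.lattice_system}",
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def direct_basis(cell: UnitCell) -> np.ndarray:
    """Direct-lattice basis vectors as rows of a 3x3 matrix (Angstrom).

    Standard setting: a along x; b in the x-y plane.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    v_a = np.array([cell.a, 0.0, 0.0])
    v_b = np.array([cell.b * cg, cell.b * sg, 0.0])
    cx = cell.c * cb
    cy = cell.c * (ca - cb * cg) / sg
    cz_sq = cell.c ** 2 - cx ** 2 - cy ** 2
    if cz_sq <= 0:
        raise ValueError("degenerate cell: basis vectors are coplanar")
    v_c = np.array([cx, cy, math.sqrt(cz_sq)])
    return np.vstack([v_a, v_b, v_c])


def reciprocal_basis(cell: UnitCell) -> np.ndarray:
    """Reciprocal basis vectors a*, b*, c* as *columns* of a 3x3 matrix (1/Angstrom).

    With ``B = reciprocal_basis(cell)`` the scattering vector of reflection
    ``(h, k, l)`` in the crystal frame is ``q = B @ [h, k, l]`` (no 2*pi factor,
    so ``|q| = 1/d``).  Satisfies the duality relations ``a* . a = 1``,
    ``a* . b = 0`` etc. for any cell.
    """
    A = direct_basis(cell)  # rows are a, b, c
    # Columns of inv(A) are the reciprocal vectors: inv(A).T @ A.T = I.
    return np.linalg.inv(A)


_ROT_EPS = 1e-9


def _rotation_about(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return _ScipyRotation.from_rotvec(axis * math.radians(angle_deg)).as_matrix()


def symmetry_rotations(cell: UnitCell) -> list[np.ndarray]:
    """Proper rotations of the lattice point group, in the crystal frame.

    Tetragonal cells carry the 422 holohedry (8 rotations), cubic cells the
    432 holohedry (24 rotations).  The set is closed under composition and
    always contains the identity.
    """
    if cell.lattice_system == "tetragonal":
        z = np.array([0.0, 0.0, 1.0])
        rots = [_rotation_about(z, a) for a in (0.0, 90.0, 180.0, 270.0)]
        for axis in ([1, 0, 0], [0, 1, 0], [1, 1, 0], [1, -1, 0]):
            rots.append(_rotation_about(np.array(axis, dtype=float), 180.0))
        return rots
    if cell.lattice_system == "cubic":
        mats: list[np.ndarray] = []
        # All signed permutation matrices with determinant +1: the 24 proper
        # rotations of the octahedral group.
        from itertools import permutations, product
        for perm in permutations(range(3)):
            for signs in product((1, -1), repeat=3):
                M = np.zeros((3, 3))
                for i, (j, s) in enumerate(zip(perm, signs)):
                    M[i, j] = s
                if np.linalg.det(M) > 0:
                    mats.append(M)
        return mats
    raise NotImplementedError(
        f"point-group rotations not implemented for lattice system {cell.lattice_system!r}"
    )


# ---------------------------------------------------------------------------
# orientations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Orientation:
    """A proper rotation mapping the crystal reciprocal basis to the lab frame."""

    rotation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3):
            raise ValueError("orientation must be a 3x3 matrix")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-9):
            raise ValueError("orientation matrix is not orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-9:
            raise ValueError("orientation matrix must have determinant +1")
        object.__setattr__(self, "rotation", R)

    @classmethod
    def identity(cls) -> "Orientation":
        return cls(np.eye(3))

    @classmethod
    def from_rotvec(cls, rotvec: np.ndarray) -> "Orientation":
        return cls(_ScipyRotation.from_rotvec(np.asarray(rotvec, dtype=float)).as_matrix())

    @classmethod
    def random(cls, rng: np.random.Generator) -> "Orientation":
        """Uniform random orientation (Haar measure on SO(3))."""
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        return cls(_ScipyRotation.from_quat(q).as_matrix())


def misorientation_deg(
    r1: np.ndarray | Orientation,
    r2: np.ndarray | Orientation,
    symmetry: list[np.ndarray] | None = None,
) -> float:
    """Smallest rotation angle (degrees) between two orientations.

    With ``symmetry`` given (a list of point-group rotations in the crystal
    frame), the minimum over all symmetry-equivalent copies of ``r2`` is
    returned, i.e. the misorientation modulo lattice symmetry.
    """
    R1 = r1.rotation if isinstance(r1, Orientation) else np.asarray(r1, dtype=float)
    R2 = r2.rotation if isinstance(r2, Orientation) else np.asarray(r2, dtype=float)
    ops = symmetry if symmetry is not None else [np.eye(3)]
    best = 180.0
    for S in ops:
        D = R1 @ (R2 @ S).T
        cos = (np.trace(D) - 1.0) / 2.0
        ang = math.degrees(math.acos(min(1.0, max(-1.0, cos))))
        best = min(best, ang)
    return best


def canonical_orientation(
    orientation: Orientation, symmetry: list[np.ndarray]
) -> Orientation:
    """Deterministic symmetry-class representative of an orientation.

    Picks, among all right-multiplications by point-group rotations, the matrix
    with the largest trace (smallest rotation angle from identity); exact ties
    are broken lexicographically on the flattened matrix.
    """
    best: np.ndarray | None = None
    best_key: tuple | None = None
    for S in symmetry:
        M = orientation.rotation @ S
        key = (-round(float(np.trace(M)), 12), tuple(np.round(M.ravel(), 12)))
        if best_key is None or key < best_key:
            best_key, best = key, M
    assert best is not None
    return Orientation(best)


# ---------------------------------------------------------------------------
# photon beam
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhotonBeam:
    """Monochromatic beam with a fractional SASE bandwidth.

    ``energy`` (keV) and ``wavelength`` (Angstrom) must be mutually consistent;
    use :meth:`from_energy` to construct from the energy alone.
    """

    energy: float
    wavelength: float
    bandwidth_fraction: float = 0.003

    def __post_init__(self) -> None:
        if self.energy <= 0 or self.wavelength <= 0:
            raise ValueError("beam energy and wavelength must be positive")
        if abs(self.energy * self.wavelength - HC_KEV_ANGSTROM) > 1e-6 * HC_KEV_ANGSTROM:
            raise ValueError("energy and wavelength are inconsistent with hc")
        if self.bandwidth_fraction < 0:
            raise ValueError("bandwidth fraction must be non-negative")

    @classmethod
    def from_energy(cls, energy_kev: float, bandwidth_fraction: float = 0.003) -> "PhotonBeam":
        return cls(energy_kev, energy_to_wavelength(energy_kev), bandwidth_fraction)


# ---------------------------------------------------------------------------
# peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    """A detected or predicted Bragg peak in assembled-frame coordinates."""

    pos: tuple[float, float]  # (slow, fast), sub-pixel
    intensity: float
    panel_id: int = 0

    def __post_init__(self) -> None:
        if not (math.isfinite(self.pos[0]) and math.isfinite(self.pos[1])):
            raise ValueError("peak position must be finite")
        if not math.isfinite(self.intensity):
            raise ValueError("peak intensity must be finite")


class PeakList:
    """Ordered collection of :class:`Peak` with an event tag.

    The currency passed between peak finding, subtraction and indexing.
    Supports ``len``, iteration and indexing; :meth:`positions` and
    :meth:`to_array` expose numpy views for vectorised consumers.
    """

    def __init__(self, peaks: list[Peak] | None = None, source_tag: str = "",
                 meta: dict | None = None) -> None:
        self.peaks: list[Peak] = list(peaks) if peaks else []
        self.source_tag = source_tag
        self.meta: dict = dict(meta) if meta else {}

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def positions(self) -> np.ndarray:
        """(n, 2) array of (slow, fast) positions."""
        if not self.peaks:
            return np.zeros((0, 2))
        return np.array([p.pos for p in self.peaks], dtype=float)

    def intensities(self) -> np.ndarray:
        if not self.peaks:
            return np.zeros((0,))
        return np.array([p.intensity for p in self.peaks], dtype=float)

    def to_array(self) -> np.ndarray:
        """(n, 3) array with columns slow, fast, intensity — the deposited layout."""
        if not self.peaks:
            return np.zeros((0, 3))
        return np.array([[p.pos[0], p.pos[1], p.intensity] for p in self.peaks])

    @classmethod
    def from_array(cls, arr: np.ndarray, source_tag: str = "",
                   geometry: "DetectorGeometry | None" = None) -> "PeakList":
        arr = np.asarray(arr, dtype=float).reshape(-1, 3)
        peaks = []
        for s, f, i in arr:
            pid = geometry.panel_of(s) if geometry is not None else 0
            peaks.append(Peak((float(s), float(f)), float(i), pid))
        return cls(peaks, source_tag=source_tag)

    def __repr__(self) -> str:  # pragma: no cover
        return f"PeakList(n={len(self)}, tag={self.source_tag!r})"


# ---------------------------------------------------------------------------
# detector geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DetectorGeometry:
    """Flat multi-panel detector, panels stacked along the slow axis.

    ``panel_offsets`` places each panel's first pixel in the *lab* pixel grid
    (slow, fast); the default is a gapless stack, in which case lab pixel
    coordinates coincide with assembled-image coordinates.
    """

    n_panels: int = 8
    panel_shape: tuple[int, int] = (1024, 512)  # (slow, fast)
    pixel_size: float = 0.05  # mm / pixel
    distance: float = 51.03  # mm along the beam
    beam_center: tuple[float, float] = (4096.0, 256.0)  # (slow, fast), lab pixels
    panel_offsets: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.distance <= 0:
            raise ValueError("detector distance must be positive")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")
        if self.n_panels < 1:
            raise ValueError("need at least one panel")
        if not self.panel_offsets:
            offs = tuple((float(p * self.panel_shape[0]), 0.0) for p in range(self.n_panels))
            object.__setattr__(self, "panel_offsets", offs)
        elif len(self.panel_offsets) != self.n_panels:
            raise ValueError("panel_offsets must have one entry per panel")

    @property
    def assembled_shape(self) -> tuple[int, int]:
        return (self.n_panels * self.panel_shape[0], self.panel_shape[1])

    def panel_of(self, slow: float) -> int:
        """Panel index of an assembled slow coordinate."""
        p = int(slow // self.panel_shape[0])
        return min(max(p, 0), self.n_panels - 1)

    # -- assembled <-> lab pixel grid -------------------------------------

    def assembled_to_lab_px(self, pos: np.ndarray) -> np.ndarray:
        """Map assembled (slow, fast) positions to lab pixel coordinates."""
        pos = np.atleast_2d(np.asarray(pos, dtype=float))
        out = pos.copy()
        panel = np.clip((pos[:, 0] // self.panel_shape[0]).astype(int), 0, self.n_panels - 1)
        offs = np.asarray(self.panel_offsets, dtype=float)
        out[:, 0] = pos[:, 0] - panel * self.panel_shape[0] + offs[panel, 0]
        out[:, 1] = pos[:, 1] + offs[panel, 1]
        return out

    def lab_px_to_assembled(self, lab: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map lab pixel coordinates back to assembled positions.

        Returns ``(assembled_pos, on_detector_mask)``; positions outside every
        panel are left untouched and masked out.
        """
        lab = np.atleast_2d(np.asarray(lab, dtype=float))
        out = lab.copy()
        panel_ids = np.full(len(lab), -1, dtype=int)
        offs = np.asarray(self.panel_offsets, dtype=float)
        ps, pf = self.panel_shape
        for p in range(self.n_panels):
            ls = lab[:, 0] - offs[p, 0]
            lf = lab[:, 1] - offs[p, 1]
            # Pixel centres cover [-0.5, size - 0.5) of the panel extent.
            inside = (ls >= -0.5) & (ls < ps - 0.5) & (lf >= -0.5) & (lf < pf - 0.5)
            hit = inside & (panel_ids < 0)
            out[hit, 0] = ls[hit] + p * ps
            out[hit, 1] = lf[hit]
            panel_ids[hit] = p
        return out, panel_ids >= 0

    # -- scattering geometry ----------------------------------------------

    def pixel_to_mm(self, pos: np.ndarray) -> np.ndarray:
        """Assembled positions to lab-frame (x, y) mm relative to the beam axis."""
        lab = self.assembled_to_lab_px(pos)
        x = (lab[:, 1] - self.beam_center[1]) * self.pixel_size
        y = (lab[:, 0] - self.beam_center[0]) * self.pixel_size
        return np.column_stack([x, y])

    def scattering_vectors(self, pos: np.ndarray, wavelength: float) -> np.ndarray:
        """Scattering vectors q (1/Angstrom) for assembled pixel positions.

        q = (s_hat - z_hat) / lambda where s_hat points from the interaction
        region to the pixel; |q| = 2 sin(theta) / lambda.
        """
        xy = self.pixel_to_mm(pos)
        d = np.sqrt(xy[:, 0] ** 2 + xy[:, 1] ** 2 + self.distance ** 2)
        sx = xy[:, 0] / d
        sy = xy[:, 1] / d
        sz = self.distance / d
        q = np.column_stack([sx, sy, sz - 1.0]) / wavelength
        return q

    def project_to_detector(self, directions: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Intersect scattered-ray directions with the detector plane.

        ``directions`` is (n, 3) in the lab frame (x, y, z); rays with z <= 0
        never reach the detector.  Returns assembled positions and an
        on-detector mask.
        """
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        ok = directions[:, 2] > 1e-12
        lab = np.zeros((len(directions), 2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(ok, self.distance / directions[:, 2], np.nan)
        x = directions[:, 0] * t
        y = directions[:, 1] * t
        lab[:, 0] = self.beam_center[0] + y / self.pixel_size
        lab[:, 1] = self.beam_center[1] + x / self.pixel_size
        lab[~ok] = -1e9
        pos, on = self.lab_px_to_assembled(lab)
        return pos, on & ok

    def resolution_at(self, pos: np.ndarray, wavelength: float) -> np.ndarray:
        """Resolution d = 1/|q| in Angstrom at assembled pixel positions."""
        q = self.scattering_vectors(pos, wavelength)
        return 1.0 / np.linalg.norm(q, axis=1)

    # -- config file I/O ----------------------------------------------------

    @classmethod
    def from_file(cls, path: str | Path) -> "DetectorGeometry":
        kv = _read_keyvalue(path)
        n_panels = int(kv.get("n_panels", 8))
        shape = tuple(int(x) for x in kv.get("panel_shape", "1024 512").split())
        bc = tuple(float(x) for x in kv.get("beam_center", "").split()) or None
        offsets = []
        for p in range(n_panels):
            key = f"panel_offset_{p}"
            if key in kv:
                offsets.append(tuple(float(x) for x in kv[key].split()))
        kwargs = dict(
            n_panels=n_panels,
            panel_shape=shape,  # type: ignore[arg-type]
            pixel_size=float(kv.get("pixel_size_mm", 0.05)),
            distance=float(kv.get("distance_mm", 51.03)),
        )
        if bc:
            kwargs["beam_center"] = bc
        if offsets:
            kwargs["panel_offsets"] = tuple(offsets)
        return cls(**kwargs)  # type: ignore[arg-type]

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"n_panels = {self.n_panels}",
            f"panel_shape = {self.panel_shape[0]} {self.panel_shape[1]}",
            f"pixel_size_mm = {self.pixel_size!r}",
            f"distance_mm = {self.distance!r}",
            f"beam_center = {self.beam_center[0]!r} {self.beam_center[1]!r}",
        ]
        for p, (s, f) in enumerate(self.panel_offsets):
            lines.append(f"panel_offset_{p} = {s!r} {f!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    def with_distance(self, distance_mm: float) -> "DetectorGeometry":
        return replace(self, distance=distance_mm)


def _read_keyvalue(path: str | Path) -> dict[str, str]:
    kv: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"malformed config line: {line!r}")
        key, val = line.split("=", 1)
        kv[key.strip()] = val.strip()
    return kv
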