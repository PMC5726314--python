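"""Detector-distance calibration from Debye-Scherrer powder rings.

Silicon nanopowder mixed into the injection grease produces faint concentric
rings whose radii encode the camera length: a ring from lattice spacing ``d``
at wavelength ``lambda`` lands at radius ``r = D * tan(2 * asin(lambda/2d))``
on a flat detector at distance ``D``.  Because the high-resolution rings are
too faint for plain thresholding, ring radii are estimated from interest
points (see :mod:`twocolor_sfx.peaks`) via a radial histogram, and the
distance is fitted by least squares against the known d-spacings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .core import PeakList

__all__ = [
    "PowderReference",
    "RingEstimate",
    "DistanceFit",
    "ring_radius",
    "radial_histogram",
    "estimate_ring_radii",
    "fit_distance",
    "silicon_d_spacings",
]

#: Silicon lattice constant in Angstrom.
SILICON_A = 5.431


def silicon_d_spacings(n: int = 5) -> list[float]:
    """First ``n`` allowed d-spacings of the silicon (diamond) lattice.

    Diamond-structure extinction rules: h, k, l all odd, or all even with
    h + k + l divisible by 4 — giving 111, 220, 311, 400, 331, ...
    """
    seen = set()
    for h in range(0, 9):
        for k in range(0, h + 1):
            for l in range(0, k + 1):
                if h == k == l == 0:
                    continue
                trio = (h, k, l)
                all_odd = all(v % 2 == 1 for v in trio)
                all_even = all(v % 2 == 0 for v in trio)
                if not (all_odd or (all_even and sum(trio) % 4 == 0)):
                    continue
                seen.add(h * h + k * k + l * l)
    ds = sorted(SILICON_A / math.sqrt(s) for s in seen)[::-1]
    return ds[:n]


@dataclass(frozen=True)
class PowderReference:
    """Known powder standard: a label and its d-spacings in Angstrom, descending."""

    material: str
    d_spacings: tuple[float, ...]

    def __post_init__(self) -> None:
        ds = tuple(float(d) for d in self.d_spacings)
        if any(d <= 0 for d in ds):
            raise ValueError("d-spacings must be positive")
        if any(ds[i] <= ds[i + 1] for i in range(len(ds) - 1)):
            raise ValueError("d-spacings must be strictly decreasing")
        object.__setattr__(self, "d_spacings", ds)

    @classmethod
    def silicon(cls, n: int = 5) -> "PowderReference":
        return cls("Si", tuple(silicon_d_spacings(n)))


@dataclass(frozen=True)
class RingEstimate:
    """One estimated ring: radius (mm), supporting point count, robust spread."""

    radius: float
    support: int
    spread: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("ring radius must be positive")


@dataclass(frozen=True)
class DistanceFit:
    """Fitted detector distance with its uncertainty and ring assignment."""

    distance: float  # mm
    uncertainty: float  # mm
    assignment: tuple[int, ...]  # index into the reference d-spacings per ring
    residuals: tuple[float, ...]  # mm, per matched ring


def ring_radius(d: float, wavelength: float, distance: float) -> float:
    """Flat-detector radius (mm) of the powder ring from spacing ``d``.

    r = distance * tan(2 * asin(lambda / 2d)); requires ``lambda < 2d`` (the
    reflection exists) and ``2 theta < 90 deg`` (forward detector can see it).
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if wavelength >= 2.0 * d:
        raise ValueError(
            f"wavelength {wavelength} >= 2d = {2 * d}: reflection beyond back-scattering")
    two_theta = 2.0 * math.asin(wavelength / (2.0 * d))
    if two_theta >= math.pi / 2.0:
        raise ValueError(
            f"2theta = {math.degrees(two_theta):.1f} deg >= 90 deg: "
            "ring not representable on a forward flat detector")
    return distance * math.tan(two_theta)


def radial_histogram(points: PeakList, center: tuple[float, float],
                     pixel_size: float, bin_width_mm: float | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Histogram of point distances from the beam centre, in mm.

    Returns ``(counts, bin_edges)``; the total mass equals the number of
    points.  Default bin width is two pixels.
    """
    if bin_width_mm is None:
        bin_width_mm = 2.0 * pixel_size
    pos = points.positions()
    if len(pos) == 0:
        return np.zeros(0, dtype=int), np.zeros(1)
    r = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1]) * pixel_size
    rmax = float(r.max()) + bin_width_mm
    edges = np.arange(0.0, rmax + bin_width_mm, bin_width_mm)
    counts, edges = np.histogram(r, bins=edges)
    return counts, edges


def estimate_ring_radii(points: PeakList, center: tuple[float, float],
                        n_rings: int, pixel_size: float,
                        bin_width_mm: float | None = None,
                        min_support: int = 20) -> list[RingEstimate]:
    """Estimate ring radii as the strongest modes of the radial density.

    The ``n_rings`` highest-support histogram modes are each refined by the
    median radial distance of the points within +/- one bin of the mode;
    results are sorted ascending by radius.  If fewer modes than requested
    clear ``min_support``, the available ones are returned (the shortfall is
    visible from the list length).
    """
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    counts, edges = radial_histogram(points, center, pixel_size, bin_width_mm)
    if len(counts) == 0:
        return []
    pos = points.positions()
    r = np.hypot(pos[:, 0] - center[0], pos[:, 1] - center[1]) * pixel_size
    # Pad so modes at the histogram ends are found too.
    padded = np.concatenate([[0.0], counts.astype(float), [0.0]])
    idx, props = _signal.find_peaks(padded, height=min_support)
    idx = idx - 1
    order = np.argsort(-props["peak_heights"])
    estimates: list[RingEstimate] = []
    for k in order[:n_rings]:
        i = int(idx[k])
        lo = edges[max(i - 1, 0)]
        hi = edges[min(i + 2, len(edges) - 1)]
        sel = (r >= lo) & (r < hi)
        if np.count_nonzero(sel) < min_support:
            continue
        rs = r[sel]
        med = float(np.median(rs))
        spread = 1.4826 * float(np.median(np.abs(rs - med)))
        estimates.append(RingEstimate(med, int(np.count_nonzero(sel)), spread))
    estimates.sort(key=lambda e: e.radius)
    return estimates


def fit_distance(radii: list[RingEstimate], reference: PowderReference,
                 wavelength: float) -> DistanceFit:
    """Least-squares detector distance from matched ring radii.

    Each reference spacing ``d_j`` contributes a geometric factor
    ``t_j = tan(2 asin(lambda/2 d_j))`` with the model ``r = D * t``; the
    distance is linear in the observations, so for a candidate ring-to-
    spacing assignment ``D = sum(r_i t_i) / sum(t_i^2)`` in closed form.
    Rings are assigned to reference spacings *in order* (largest spacing =
    innermost ring), trying every contiguous alignment and keeping the one
    with the smallest normalised residual.  The uncertainty is propagated
    from the fit residuals.
    """
    if len(radii) == 0:
        raise ValueError("need at least one ring estimate")
    ts = []
    for d in reference.d_spacings:
        try:
            ts.append(ring_radius(d, wavelength, 1.0))  # tan(2theta) at unit distance
        except ValueError:
            break  # subsequent (smaller) spacings are also invalid
    if not ts:
        raise ValueError(
            f"no reference spacing of {reference.material} yields a visible ring "
            f"at wavelength {wavelength}")
    t = np.asarray(ts)
    robs = np.array(sorted(e.radius for e in radii))
    n = len(robs)
    if n > len(t):
        raise ValueError(
            f"found {n} rings but only {len(t)} visible reference spacings; "
            "no consistent assignment")
    best: tuple[float, float, int, np.ndarray] | None = None
    for k in range(len(t) - n + 1):
        tk = t[k:k + n]
        D = float(np.dot(robs, tk) / np.dot(tk, tk))
        res = robs - D * tk
        score = float(np.sqrt(np.mean((res / robs) ** 2)))
        if best is None or score < best[0]:
            best = (score, D, k, res)
    assert best is not None
    score, D, k, res = best
    if score > 0.2:
        raise ValueError(
            "no consistent ring-to-spacing assignment; candidate offsets all "
            f"leave > 20% relative residual (best {score:.2%} at offset {k})")
    tk = t[k:k + n]
    if n > 1:
        sigma = float(np.sqrt(np.sum(res ** 2) / (n - 1) / np.dot(tk, tk)))
    else:
        sigma = float(radii[0].spread / tk[0])
    return DistanceFit(D, sigma, tuple(range(k, k + n)), tuple(float(x) for x in res))
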