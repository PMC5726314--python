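"""Known-cell indexing and the strong/subtract/weak two-colour scheme.

A split-undulator double pulse records two diffraction patterns of the *same*
crystal — one per photon energy — superimposed in one image, with
anti-correlated intensities.  Because a single-lattice indexer can only deal
with one pattern at a time, the two-colour data is processed in three steps:

1. find peaks with the strong-pattern settings (threshold 200 / SNR 5) and
   index against the known cell at whichever colour scores better — this
   identifies the *strong* pattern;
2. re-find peaks with lowered settings (threshold 150 / SNR 3) and remove
   every peak explained by the strong solution's predicted reflections,
   leaving a residual list that plausibly belongs to the weak pattern;
3. index the residual at the other colour's wavelength; generous integration
   radii (6, 6, 8 pixels) absorb residual prediction error.

Orientation determination against a known cell works in reciprocal space:
each observed peak maps to a scattering vector on the Ewald sphere; pairs of
observed vectors are matched to reciprocal-lattice vectors by length and
mutual angle, each consistent pairing proposing a candidate rotation.
Candidates are scored by how many observed vectors land near lattice points,
and the best are refined by iterated nearest-lattice-point assignment and
Kabsch alignment.  The final solution is scored on the detector by
prediction-to-peak matching and reported as a canonical representative of its
lattice-symmetry class.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .core import (
    DetectorGeometry,
    Orientation,
    Peak,
    PeakList,
    PhotonBeam,
    UnitCell,
    canonical_orientation,
    misorientation_deg,
    reciprocal_basis,
    direct_basis,
    symmetry_rotations,
)
from .peaks import PeakFindParams, find_peaks, subtract_peaks

__all__ = [
    "IndexParams",
    "ReflectionPrediction",
    "PredictionSet",
    "IndexingSolution",
    "TwoColorResult",
    "predict_reflections",
    "match_peaks",
    "integrate",
    "index_known_cell",
    "process_two_color_event",
]


@dataclass(frozen=True)
class IndexParams:
    """Tunables of prediction, matching and orientation search.

    ``integration_radii`` follows the (peak, gap, background-outer)
    convention of the 6,6,8 processing parameters.  ``coarse_step`` bounds
    the angular spacing of candidate orientations retained for refinement.
    """

    coarse_step: float = 3.0  # degrees
    match_radius: float = 4.0  # pixels
    min_matched: int = 10
    bandwidth_tolerance: float = 0.003
    resolution_cutoff: float = 1.9  # Angstrom
    integration_radii: tuple[float, float, float] = (6.0, 6.0, 8.0)
    n_search_peaks: int = 40  # strongest peaks used in the orientation search
    n_pair_peaks: int = 8  # strongest peaks used to seed candidate pairs
    n_refine: int = 6  # candidates carried into refinement
    max_iterations: int = 50
    convergence_deg: float = 1e-4

    def __post_init__(self) -> None:
        if self.coarse_step <= 0:
            raise ValueError("coarse_step must be positive")
        rp, rg, rb = self.integration_radii
        if not rp <= rg < rb:
            raise ValueError("integration radii must satisfy r_peak <= r_gap < r_bg")
        if self.match_radius <= 0:
            raise ValueError("match_radius must be positive")


@dataclass(frozen=True)
class ReflectionPrediction:
    """A reflection excited within the bandwidth, mapped to the detector."""

    hkl: tuple[int, int, int]
    detector_pos: tuple[float, float]  # (slow, fast), assembled frame
    excitation_error: float  # relative Ewald offset
    resolution: float  # Angstrom


class PredictionSet:
    """Vectorised container of reflection predictions.

    Arrays: ``hkl`` (n, 3) int, ``pos`` (n, 2) assembled (slow, fast),
    ``excitation_error`` (n,), ``resolution`` (n,).  Indexing an element
    materialises a :class:`ReflectionPrediction`.
    """

    def __init__(self, hkl: np.ndarray, pos: np.ndarray,
                 excitation_error: np.ndarray, resolution: np.ndarray) -> None:
        self.hkl = np.asarray(hkl, dtype=int).reshape(-1, 3)
        self.pos = np.asarray(pos, dtype=float).reshape(-1, 2)
        self.excitation_error = np.asarray(excitation_error, dtype=float)
        self.resolution = np.asarray(resolution, dtype=float)

    def __len__(self) -> int:
        return len(self.hkl)

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def __getitem__(self, i: int) -> ReflectionPrediction:
        return ReflectionPrediction(
            tuple(int(v) for v in self.hkl[i]),
            (float(self.pos[i, 0]), float(self.pos[i, 1])),
            float(self.excitation_error[i]),
            float(self.resolution[i]),
        )


@dataclass(frozen=True)
class IndexingSolution:
    """Best orientation with its peak-to-prediction matches."""

    orientation: Orientation
    matched: tuple[tuple[Peak, ReflectionPrediction], ...]
    score: int
    rmsd: float  # pixels over matched pairs

    def __post_init__(self) -> None:
        if self.score != len(self.matched):
            raise ValueError("score must equal the number of matched pairs")
        if self.rmsd < 0:
            raise ValueError("rmsd must be non-negative")


@dataclass(frozen=True)
class TwoColorResult:
    """Outcome of the three-step two-colour processing of one event."""

    strong_color: str | None  # 'color1' | 'color2'
    strong_solution: IndexingSolution | None
    residual: PeakList
    weak_solution: IndexingSolution | None
    status: str  # 'none' | 'strong_only' | 'both'

    def __post_init__(self) -> None:
        expect = "none"
        if self.strong_solution is not None:
            expect = "both" if self.weak_solution is not None else "strong_only"
        if self.status != expect:
            raise ValueError(f"status {self.status!r} inconsistent with solutions")


# ---------------------------------------------------------------------------
# reciprocal-lattice table (cached per cell / cutoff)
# ---------------------------------------------------------------------------

_LATTICE_CACHE: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
_WEDGE_CACHE: dict[tuple, np.ndarray] = {}


def _lattice_table(cell: UnitCell, resolution_cutoff: float
                   ) -> tuple[np.ndarray, np.ndarray]:
    """All nonzero (h, k, l) with d >= cutoff and their vectors g = B @ hkl."""
    key = (round(cell.a, 9), round(cell.b, 9), round(cell.c, 9),
           round(cell.alpha, 9), round(cell.beta, 9), round(cell.gamma, 9),
           round(resolution_cutoff, 9))
    if key in _LATTICE_CACHE:
        return _LATTICE_CACHE[key]
    B = reciprocal_basis(cell)
    qmax = 1.0 / resolution_cutoff
    A = direct_basis(cell)
    # Duality: h = a . q, so |h| <= |a| * qmax (and likewise for k, l).
    nmax = [int(math.floor(np.linalg.norm(A[i]) * qmax)) for i in range(3)]
    hs = np.arange(-nmax[0], nmax[0] + 1)
    ks = np.arange(-nmax[1], nmax[1] + 1)
    ls = np.arange(-nmax[2], nmax[2] + 1)
    H, K, L = np.meshgrid(hs, ks, ls, indexing="ij")
    hkl = np.column_stack([H.ravel(), K.ravel(), L.ravel()])
    g = hkl @ B.T
    norm = np.linalg.norm(g, axis=1)
    sel = (norm > 0) & (norm <= qmax)
    out = (hkl[sel], g[sel])
    _LATTICE_CACHE[key] = out
    return out


# ---------------------------------------------------------------------------
# prediction, matching, integration
# ---------------------------------------------------------------------------

def predict_reflections(cell: UnitCell, orientation: Orientation, beam: PhotonBeam,
                        geometry: DetectorGeometry,
                        params: IndexParams | None = None) -> PredictionSet:
    """Reflections excited on the Ewald sphere, mapped to the detector.

    Enumerates every (h, k, l) with ``d >= resolution_cutoff`` whose relative
    excitation error ``(|q + k_in| - |k_in|) / |k_in|`` is within
    ``bandwidth_tolerance``, intersects the scattered ray with the detector
    plane and drops predictions that miss the panels.
    """
    params = params or IndexParams()
    hkl, g = _lattice_table(cell, params.resolution_cutoff)
    k = 1.0 / beam.wavelength
    q_lab = g @ orientation.rotation.T
    v = q_lab + np.array([0.0, 0.0, k])
    err = (np.linalg.norm(v, axis=1) - k) / k
    sel = np.abs(err) <= params.bandwidth_tolerance
    hkl_s, v_s, err_s = hkl[sel], v[sel], err[sel]
    gnorm = np.linalg.norm(g[sel], axis=1)
    pos, on = geometry.project_to_detector(v_s)
    return PredictionSet(hkl_s[on], pos[on], err_s[on], 1.0 / gnorm[on])


def match_peaks(peaks: PeakList, predictions: PredictionSet,
                match_radius: float) -> list[tuple[int, int]]:
    """Greedy one-to-one nearest-neighbour assignment within ``match_radius``.

    Candidate (peak, prediction) pairs are taken in order of increasing
    distance (ties broken by peak index, then prediction index, which the
    intensity-sorted peak order makes deterministic); each peak and each
    prediction is used at most once.  Returns ``(peak_index,
    prediction_index)`` pairs.
    """
    if match_radius <= 0:
        raise ValueError("match_radius must be positive")
    if len(peaks) == 0 or len(predictions) == 0:
        return []
    ppos = peaks.positions()
    qpos = predictions.pos
    d = np.sqrt(((ppos[:, None, :] - qpos[None, :, :]) ** 2).sum(axis=2))
    ii, jj = np.nonzero(d <= match_radius)
    order = np.lexsort((jj, ii, np.round(d[ii, jj], 12)))
    used_p: set[int] = set()
    used_q: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for t in order:
        i, j = int(ii[t]), int(jj[t])
        if i in used_p or j in used_q:
            continue
        used_p.add(i)
        used_q.add(j)
        pairs.append((i, j))
    return pairs


def integrate(image: np.ndarray, predictions: PredictionSet,
              radii: tuple[float, float, float] = (6.0, 6.0, 8.0)
              ) -> tuple[np.ndarray, np.ndarray]:
    """Ring integration at predicted positions.

    Intensity = sum of pixels within ``r_peak`` of the prediction minus the
    annulus (``r_gap`` < r <= ``r_bg``) background median times the disc
    area.  Returns ``(intensities, flags)``; predictions clipped by a
    detector edge are flagged True, fully off-image ones get NaN intensity.
    """
    r_peak, r_gap, r_bg = radii
    if not r_peak <= r_gap < r_bg:
        raise ValueError("integration radii must satisfy r_peak <= r_gap < r_bg")
    image = np.asarray(image, dtype=float)
    ns, nf = image.shape
    n = len(predictions)
    intensities = np.full(n, np.nan)
    flags = np.zeros(n, dtype=bool)
    r = int(np.ceil(r_bg))
    ds, df = np.mgrid[-r:r + 1, -r:r + 1]
    for i in range(n):
        cs, cf = predictions.pos[i]
        s0, f0 = int(round(cs)), int(round(cf))
        ss = ds + s0
        ff = df + f0
        rr = np.sqrt((ss - cs) ** 2 + (ff - cf) ** 2)
        inb = (ss >= 0) & (ss < ns) & (ff >= 0) & (ff < nf)
        disc = (rr <= r_peak)
        ann = (rr > r_gap) & (rr <= r_bg)
        clipped = bool(np.any(~inb & (disc | ann)))
        flags[i] = clipped
        disc_in = disc & inb
        ann_in = ann & inb
        if not disc_in.any():
            continue  # fully off-image: intensity stays NaN, flagged
        bg = float(np.median(image[ss[ann_in], ff[ann_in]])) if ann_in.any() else 0.0
        n_disc = int(np.count_nonzero(disc))  # nominal disc area
        intensities[i] = float(image[ss[disc_in], ff[disc_in]].sum()
                               - bg * n_disc)
    return intensities, flags


# ---------------------------------------------------------------------------
# orientation search
# ---------------------------------------------------------------------------

def _symmetry_or_identity(cell: UnitCell) -> list[np.ndarray]:
    try:
        return symmetry_rotations(cell)
    except NotImplementedError:
        return [np.eye(3)]


def _triads(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Orthonormal frames (n, 3, 3) with columns from a, the a-b plane, and a x b."""
    a = np.atleast_2d(a)
    b = np.atleast_2d(b)
    with np.errstate(divide="ignore", invalid="ignore"):
        e1 = a / np.linalg.norm(a, axis=1, keepdims=True)
        u = b - (b * e1).sum(axis=1, keepdims=True) * e1
        e2 = u / np.linalg.norm(u, axis=1, keepdims=True)
    e3 = np.cross(e1, e2)
    out = np.stack([e1, e2, e3], axis=2)
    # Degenerate (parallel) pairs yield non-finite frames; neutralise them so
    # downstream scoring simply ignores the candidate.
    bad = ~np.isfinite(out).all(axis=(1, 2))
    out[bad] = np.eye(3)
    return out


def _symmetry_wedge_mask(g: np.ndarray, sym: list[np.ndarray]) -> np.ndarray:
    """Mask selecting one representative per symmetry orbit of lattice vectors.

    Any orientation mapping some orbit member onto an observed vector has a
    symmetry-equivalent copy mapping the representative onto it, so the
    anchor side of a pair search may be restricted to representatives.
    """
    if len(sym) == 1:
        return np.ones(len(g), dtype=bool)
    key = (id(g), len(sym))
    cached = _WEDGE_CACHE.get(key)
    if cached is not None:
        return cached
    images = np.stack([g @ S.T for S in sym], axis=0)  # (n_sym, n, 3)
    keys = np.round(images, 6)
    # Representative = lexicographically largest image; a vector is kept iff
    # it is its own representative.
    rep = keys[0]
    for k in range(1, len(sym)):
        cand = keys[k]
        better = np.zeros(len(g), dtype=bool)
        decided = np.zeros(len(g), dtype=bool)
        for col in range(3):
            gt = (cand[:, col] > rep[:, col]) & ~decided
            lt = (cand[:, col] < rep[:, col]) & ~decided
            better |= gt
            decided |= gt | lt
        rep[better] = cand[better]
    mask = np.all(np.round(g, 6) == rep, axis=1)
    _WEDGE_CACHE[key] = mask
    return mask


def _select_diverse_peaks(q: np.ndarray, n: int) -> list[int]:
    """Pick peak indices with well-spread scattering directions.

    Starts from the first (strongest) peak and greedily adds the peak whose
    direction is farthest (in |cos|) from every one already chosen, so that
    candidate pairs are never near-collinear even when many strong peaks sit
    in one detector region.
    """
    dirs = q / np.linalg.norm(q, axis=1, keepdims=True)
    chosen = [0]
    while len(chosen) < min(n, len(q)):
        cos_to_chosen = np.max(np.abs(dirs @ dirs[chosen].T), axis=1)
        cos_to_chosen[chosen] = np.inf
        nxt = int(np.argmin(cos_to_chosen))
        if not np.isfinite(cos_to_chosen[nxt]):
            break
        chosen.append(nxt)
    return chosen


def _pair_candidates(q: np.ndarray, i: int, j: int, g: np.ndarray,
                     gn: np.ndarray, anchor_mask: np.ndarray, q_tol: float,
                     bandwidth: float) -> np.ndarray:
    """Candidate rotations from one observed pair, by length-and-angle match."""
    qn_i = float(np.linalg.norm(q[i]))
    qn_j = float(np.linalg.norm(q[j]))
    cos_q = float(np.dot(q[i], q[j]) / (qn_i * qn_j))
    if abs(cos_q) > 0.95:
        return np.zeros((0, 3, 3))
    mask_i = anchor_mask & (np.abs(gn - qn_i) <= qn_i * bandwidth + q_tol)
    mask_j = np.abs(gn - qn_j) <= qn_j * bandwidth + q_tol
    if not mask_i.any() or not mask_j.any():
        return np.zeros((0, 3, 3))
    Gi, Gin = g[mask_i], gn[mask_i]
    Gj, Gjn = g[mask_j], gn[mask_j]
    cos_g = (Gi @ Gj.T) / np.outer(Gin, Gjn)
    ang_tol = q_tol * (1.0 / qn_i + 1.0 / qn_j) + 2e-3
    sin_q = math.sqrt(max(0.0, 1.0 - cos_q * cos_q))
    cos_tol = sin_q * ang_tol + 1e-6
    a_idx, b_idx = np.nonzero(np.abs(cos_g - cos_q) <= cos_tol)
    if len(a_idx) == 0:
        return np.zeros((0, 3, 3))
    if len(a_idx) > 12000:  # bound the per-pair work; solutions recur across pairs
        step = len(a_idx) // 12000 + 1
        a_idx, b_idx = a_idx[::step], b_idx[::step]
    Tg = _triads(Gi[a_idx], Gj[b_idx])
    Tq = _triads(q[i][None, :], q[j][None, :])[0]
    return Tq @ np.transpose(Tg, (0, 2, 1))


def _score_block(Rs: np.ndarray, q: np.ndarray, B: np.ndarray,
                 Binv: np.ndarray, q_tol: float) -> np.ndarray:
    # h = Binv @ R^T @ q per candidate; R^T q == q @ R.
    rtq = np.matmul(q, Rs)  # (n, m, 3)
    h = np.matmul(rtq, Binv.T)
    hr = np.rint(h)
    dq = np.matmul(h - hr, B.T)
    ok = (dq * dq).sum(axis=2) <= q_tol * q_tol
    nonzero = np.abs(hr).sum(axis=2) > 0
    return (ok & nonzero).sum(axis=1)


def _score_rotations(Rs: np.ndarray, q: np.ndarray, B: np.ndarray,
                     Binv: np.ndarray, q_tol: float) -> np.ndarray:
    """Per-candidate count of observed q-vectors near reciprocal-lattice points.

    Two-stage for speed: a prefilter on a small subset of observations
    discards hopeless candidates before the full count.
    """
    if len(Rs) > 2000 and len(q) > 16:
        m1 = 12
        pre = _score_block(Rs, q[:m1], B, Binv, q_tol)
        survivors = np.nonzero(pre >= max(3, m1 // 3))[0]
        scores = np.zeros(len(Rs), dtype=int)
        if len(survivors):
            scores[survivors] = _score_block(Rs[survivors], q, B, Binv, q_tol)
        # Keep the prefilter ranking informative for the (rare) case where
        # nothing survives.
        if not len(survivors):
            return pre
        return scores
    return _score_block(Rs, q, B, Binv, q_tol)


def _kabsch(G: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Rotation R minimising sum |R g - q|^2 (proper, via SVD)."""
    M = Q.T @ G
    U, _, Vt = np.linalg.svd(M)
    d = np.sign(np.linalg.det(U @ Vt))
    return U @ np.diag([1.0, 1.0, d]) @ Vt


def _refine_orientation(R0: np.ndarray, q: np.ndarray, B: np.ndarray,
                        Binv: np.ndarray, q_tol: float,
                        max_iterations: int, convergence_deg: float) -> np.ndarray:
    """Iterated nearest-lattice-point assignment + Kabsch alignment."""
    R = R0
    for _ in range(max_iterations):
        h = (Binv @ (R.T @ q.T)).T
        hr = np.round(h)
        dq = (B @ (h - hr).T).T
        sel = (np.linalg.norm(dq, axis=1) <= 2.0 * q_tol) & \
              (np.abs(hr).sum(axis=1) > 0)
        if np.count_nonzero(sel) < 3:
            break
        G = (B @ hr[sel].T).T
        Rn = _kabsch(G, q[sel])
        delta = misorientation_deg(R, Rn)
        R = Rn
        if delta < convergence_deg:
            break
    return R


_AMBIGUITY_CACHE: dict[tuple, list[np.ndarray]] = {}


def _ambiguity_rotations(cell: UnitCell, sym: list[np.ndarray]
                         ) -> list[np.ndarray]:
    """Approximate self-coincidence rotations of the reciprocal lattice.

    Special cell-parameter ratios (here c is within 0.2% of a/2) admit
    rotations outside the point group that map a large sublattice nearly onto
    lattice points — classic indexing ambiguities.  Candidates are generated
    by matching the reciprocal basis vectors against lattice vectors of equal
    length and mutual angle; an operation qualifies if at least a quarter of
    a low-resolution lattice shell lands within a small fraction of the
    lattice spacing.  The identity class is excluded.
    """
    key = (round(cell.a, 9), round(cell.b, 9), round(cell.c, 9),
           round(cell.alpha, 9), round(cell.beta, 9), round(cell.gamma, 9),
           len(sym))
    if key in _AMBIGUITY_CACHE:
        return _AMBIGUITY_CACHE[key]
    B = reciprocal_basis(cell)
    basis = [B[:, 0], B[:, 1], B[:, 2]]
    bnorm = [np.linalg.norm(v) for v in basis]
    # Low-resolution lattice ball for probe matching and verification.
    cutoff = 1.0 / (4.0 * max(bnorm))
    hkl, g = _lattice_table(cell, max(cutoff, 1.9))
    gn = np.linalg.norm(g, axis=1)
    probe_sel = gn <= 4.0 * max(bnorm)
    gp, gpn = g[probe_sel], gn[probe_sel]
    tol = 0.15 * min(bnorm)
    ops: list[np.ndarray] = []
    for i in range(3):
        for j in range(3):
            if i == j:
                continue
            u, v = basis[i], basis[j]
            mi = np.abs(gpn - bnorm[i]) <= 0.01 * bnorm[i] + 1e-12
            mj = np.abs(gpn - bnorm[j]) <= 0.01 * bnorm[j] + 1e-12
            if not (mi.any() and mj.any()):
                continue
            cos_uv = float(u @ v / (bnorm[i] * bnorm[j]))
            cos_g = (gp[mi] @ gp[mj].T) / np.outer(gpn[mi], gpn[mj])
            a_idx, b_idx = np.nonzero(np.abs(cos_g - cos_uv) <= 0.02)
            if len(a_idx) == 0:
                continue
            Tg = _triads(gp[mi][a_idx], gp[mj][b_idx])
            Tu = _triads(u[None, :], v[None, :])[0]
            cands = np.matmul(Tg, Tu.T[None, :, :])  # maps u -> g1, v -> g2
            for S in cands:
                mapped = gp @ S.T
                h = mapped @ np.linalg.inv(B).T
                dq = (h - np.rint(h)) @ B.T
                frac = float(np.mean(np.linalg.norm(dq, axis=1) <= tol))
                if frac < 0.25:
                    continue
                if any(misorientation_deg(S, K, sym) < 0.5
                       for K in ops + [np.eye(3)]):
                    continue
                ops.append(S)
    _AMBIGUITY_CACHE[key] = ops
    return ops


def _polish_orientation(R: np.ndarray, peak_pos: np.ndarray, hkl: np.ndarray,
                        B: np.ndarray, geometry: DetectorGeometry,
                        k: float) -> np.ndarray:
    """Least-squares rotation update minimising detector-position residuals.

    The q-space Kabsch step is slightly biased because observed scattering
    vectors sit exactly on the Ewald sphere while predicted ones are off it
    by the excitation error; the measurable quantity is the spot position, so
    the final refinement minimises position residuals of the matched pairs
    over a rotation-vector perturbation.
    """
    from scipy.optimize import least_squares
    from scipy.spatial.transform import Rotation as ScipyRotation

    g = hkl @ B.T
    kin = np.array([0.0, 0.0, k])

    def residuals(delta: np.ndarray) -> np.ndarray:
        Rd = ScipyRotation.from_rotvec(delta).as_matrix() @ R
        v = g @ Rd.T + kin
        pos, on = geometry.project_to_detector(v)
        res = pos - peak_pos
        res[~on] = 0.0
        return res.ravel()

    try:
        # Soft-L1 loss keeps mismatched (contaminating) pairs from dragging
        # the rotation; the scale is of order the centroid noise.
        out = least_squares(residuals, np.zeros(3), method="trf",
                            loss="soft_l1", f_scale=1.0, max_nfev=60)
        return ScipyRotation.from_rotvec(out.x).as_matrix() @ R
    except Exception:
        return R


def index_known_cell(peaks: PeakList, cell: UnitCell, beam: PhotonBeam,
                     geometry: DetectorGeometry,
                     params: IndexParams | None = None) -> IndexingSolution | None:
    """Determine the crystal orientation given the unit cell, or ``None``.

    Failure to index (no candidate reaching ``min_matched`` detector matches)
    is a value, not an exception, so that per-run bookkeeping over many
    events is first class.  The returned orientation is the canonical
    representative of its lattice-symmetry class.
    """
    params = params or IndexParams()
    if len(peaks) < params.min_matched:
        return None
    sym = _symmetry_or_identity(cell)
    hkl_tab, g = _lattice_table(cell, params.resolution_cutoff)
    B = reciprocal_basis(cell)
    Binv = np.linalg.inv(B)

    # Strongest peaks, mapped to scattering vectors within the resolution range.
    order = np.argsort(-peaks.intensities(), kind="stable")
    pos = peaks.positions()[order][:params.n_search_peaks]
    q = geometry.scattering_vectors(pos, beam.wavelength)
    qn = np.linalg.norm(q, axis=1)
    qmax = (1.0 / params.resolution_cutoff) * (1.0 + 2 * params.bandwidth_tolerance)
    q = q[(qn > 0) & (qn <= qmax)]
    if len(q) < 2:
        return None

    q_tol = params.match_radius * geometry.pixel_size / (geometry.distance * beam.wavelength)
    gn = np.linalg.norm(g, axis=1)
    anchor_mask = _symmetry_wedge_mask(g, sym)

    # Pair search: well-spread observed pairs propose candidate rotations,
    # scored by how many observed vectors fall near lattice points; once a
    # candidate explains most observations the search stops early.
    diverse = _select_diverse_peaks(q, params.n_pair_peaks)
    pair_order = [(diverse[a], diverse[b])
                  for a in range(len(diverse)) for b in range(a + 1, len(diverse))]
    # The early-exit bar must stay above what a pseudo-symmetric near-miss
    # can reach (a cell with c ~ a/2, as here, admits a 90-degree-rotated
    # lattice that explains about half the observations), so only a candidate
    # explaining the large majority of observations stops the pair search.
    good_score = max(params.min_matched, int(0.8 * len(q)))
    pool: list[tuple[int, np.ndarray]] = []
    for i, j in pair_order[:15]:
        cands = _pair_candidates(q, i, j, g, gn, anchor_mask, q_tol,
                                 params.bandwidth_tolerance)
        if len(cands) == 0:
            continue
        scores = _score_rotations(cands, q, B, Binv, q_tol)
        top = np.argsort(-scores, kind="stable")[:params.n_refine]
        pool.extend((int(scores[k]), cands[k]) for k in top if scores[k] >= 2)
        if scores.max(initial=0) >= good_score:
            break

    # Keep the best candidates, spaced by at least coarse_step degrees modulo
    # lattice symmetry, for refinement.
    pool.sort(key=lambda t: -t[0])
    keep: list[np.ndarray] = []
    for _, R in pool:
        if any(misorientation_deg(R, K, sym) < params.coarse_step for K in keep):
            continue
        keep.append(R)
        if len(keep) >= params.n_refine:
            break
    if not keep:
        return None

    ppos = peaks.positions()
    k_in = 1.0 / beam.wavelength

    def refine_and_score(R0: np.ndarray):
        """Full refinement of one candidate: q-space Kabsch iterations, then
        detector-space polish with re-matching, then a final detector match."""
        R = _refine_orientation(R0, q, B, Binv, q_tol,
                                params.max_iterations, params.convergence_deg)
        for _ in range(2):
            preds = predict_reflections(cell, Orientation(R), beam, geometry,
                                        params)
            pairs = match_peaks(peaks, preds, params.match_radius)
            if len(pairs) < 3:
                return None
            R = _polish_orientation(
                R, np.array([ppos[i] for i, _ in pairs]),
                preds.hkl[[j for _, j in pairs]], B, geometry, k_in)
        orient = canonical_orientation(Orientation(R), sym)
        preds = predict_reflections(cell, orient, beam, geometry, params)
        pairs = match_peaks(peaks, preds, params.match_radius)
        if len(pairs) < params.min_matched:
            return None
        dist2 = [((ppos[i] - preds.pos[j]) ** 2).sum() for i, j in pairs]
        rmsd = float(np.sqrt(np.mean(dist2)))
        return len(pairs), rmsd, orient.rotation, pairs, preds

    best = None
    for R0 in keep:
        cand = refine_and_score(R0)
        if cand is None:
            continue
        if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
            best = cand
        if best[0] >= 0.85 * len(peaks):
            break  # essentially every peak explained; no better candidate exists
    if best is None:
        return None

    # Indexing-ambiguity resolution: a special cell ratio can let a wrong
    # orientation explain a large sublattice of the observations.  Re-refine
    # the winner through every approximate self-coincidence rotation of the
    # lattice and keep whichever explains the most peaks.  A winner that
    # already explains nearly everything cannot be beaten and is kept as is.
    if best[0] < 0.85 * len(peaks):
        for S in _ambiguity_rotations(cell, sym):
            R_alt = best[2] @ S
            # Cheap screen: only refine a partner that already out-matches
            # the winner before any polish.
            preds = predict_reflections(cell, Orientation(R_alt), beam,
                                        geometry, params)
            if len(match_peaks(peaks, preds, params.match_radius)) <= best[0]:
                continue
            cand = refine_and_score(R_alt)
            if cand is not None and (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
    score, rmsd, R, best_pairs, best_preds = best
    # Verification against the chance-match level: a contaminated or random
    # peak list can accumulate matches by accident (the expected number is
    # mu = n_peaks * n_predictions * pi * r^2 / detector area); a genuine
    # lattice explains far more peaks than chance, so solutions within a few
    # times mu are rejected as spurious.
    area = float(np.prod(geometry.assembled_shape))
    mu = len(peaks) * len(best_preds) * math.pi * params.match_radius ** 2 / area
    if score < max(params.min_matched, math.ceil(4.0 * mu)):
        return None
    orient = Orientation(R)
    matched = tuple((peaks[i], best_preds[j]) for i, j in best_pairs)
    return IndexingSolution(orient, matched, score, rmsd)


# ---------------------------------------------------------------------------
# three-step two-colour processing
# ---------------------------------------------------------------------------

def process_two_color_event(image: np.ndarray, energies: tuple[float, float],
                            cell: UnitCell, geometry: DetectorGeometry,
                            strong_params: PeakFindParams | None = None,
                            weak_params: PeakFindParams | None = None,
                            index_params: IndexParams | None = None,
                            subtract: bool = True,
                            subtract_radius: float = 4.0) -> TwoColorResult:
    """Run the strong -> subtract -> weak chain on one two-colour image.

    ``energies`` are the two photon energies in keV (colour 1 is the lower).
    With ``subtract=False`` step 2 is skipped and the weak colour is indexed
    on the full low-threshold peak list — the ablation baseline.  Step
    failures are recorded in ``status``; the residual list is returned
    regardless of whether step 3 succeeds.
    """
    e1, e2 = sorted(energies)
    if not e1 < e2:
        raise ValueError("the two photon energies must be distinct")
    strong_params = strong_params or PeakFindParams.strong()
    weak_params = weak_params or PeakFindParams.weak()
    index_params = index_params or IndexParams()
    beams = {
        "color1": PhotonBeam.from_energy(e1, index_params.bandwidth_tolerance),
        "color2": PhotonBeam.from_energy(e2, index_params.bandwidth_tolerance),
    }

    # Step 1: strong-pattern peaks, indexed at both colours; the better score
    # identifies the brighter colour.
    speaks = find_peaks(image, geometry, strong_params)
    sols = {c: index_known_cell(speaks, cell, beams[c], geometry, index_params)
            for c in ("color1", "color2")}
    strong_color = None
    if sols["color1"] is not None or sols["color2"] is not None:
        strong_color = max(
            (c for c in sols if sols[c] is not None),
            key=lambda c: (sols[c].score, -sols[c].rmsd),
        )
    if strong_color is None:
        return TwoColorResult(None, None, PeakList([]), None, "none")
    strong_sol = sols[strong_color]
    weak_color = "color2" if strong_color == "color1" else "color1"

    # Step 2: broader peak set; strike everything the strong solution explains.
    wpeaks = find_peaks(image, geometry, weak_params)
    if subtract:
        strong_pred = predict_reflections(cell, strong_sol.orientation,
                                          beams[strong_color], geometry, index_params)
        pred_list = PeakList.from_array(
            np.column_stack([strong_pred.pos, np.ones(len(strong_pred))]))
        residual = subtract_peaks(wpeaks, pred_list, subtract_radius)
    else:
        residual = wpeaks

    # Step 3: index the residual at the other colour, generous radii.
    weak_ip = replace(index_params,
                      match_radius=max(index_params.match_radius,
                                       index_params.integration_radii[0]))
    weak_sol = index_known_cell(residual, cell, beams[weak_color], geometry, weak_ip)
    status = "both" if weak_sol is not None else "strong_only"
    return TwoColorResult(strong_color, strong_sol, residual, weak_sol, status)
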