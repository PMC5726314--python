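"""Ewald prediction, matching, integration and known-cell indexing."""

import numpy as np
import pytest

from twocolor_sfx.core import (
    Orientation,
    Peak,
    PeakList,
    PhotonBeam,
    reciprocal_basis,
    misorientation_deg,
    symmetry_rotations,
)
from twocolor_sfx.indexing import (
    IndexParams,
    PredictionSet,
    index_known_cell,
    integrate,
    match_peaks,
    predict_reflections,
)

from conftest import gaussian_blob

BEAM9 = PhotonBeam.from_energy(9.0)


def brute_force_predictions(cell, orientation, beam, geometry, params):
    """Exhaustive triple loop over the full hkl box (independent oracle)."""
    B = reciprocal_basis(cell)
    k = 1.0 / beam.wavelength
    qmax = 1.0 / params.resolution_cutoff
    nmax = [int(np.ceil(qmax * cell.a)), int(np.ceil(qmax * cell.b)),
            int(np.ceil(qmax * cell.c))]
    ns, nf = geometry.assembled_shape
    out = set()
    for h in range(-nmax[0], nmax[0] + 1):
        for kk in range(-nmax[1], nmax[1] + 1):
            for l in range(-nmax[2], nmax[2] + 1):
                if h == kk == l == 0:
                    continue
                g = B @ (h, kk, l)
                if np.linalg.norm(g) > qmax:
                    continue
                v = orientation.rotation @ g + np.array([0.0, 0.0, k])
                if abs(np.linalg.norm(v) - k) / k > params.bandwidth_tolerance:
                    continue
                if v[2] <= 0:
                    continue
                t = geometry.distance / v[2]
                slow = geometry.beam_center[0] + v[1] * t / geometry.pixel_size
                fast = geometry.beam_center[1] + v[0] * t / geometry.pixel_size
                if -0.5 <= slow < ns - 0.5 and -0.5 <= fast < nf - 0.5:
                    out.add((h, kk, l))
    return out


class TestPredictReflections:
    def test_origin_never_predicted(self, small_cell, mid_geom):
        preds = predict_reflections(small_cell, Orientation.identity(), BEAM9,
                                    mid_geom, IndexParams(resolution_cutoff=3.0))
        assert not any((p.hkl == np.zeros(3)).all() for p in [preds])
        assert not (np.abs(preds.hkl).sum(axis=1) == 0).any()

    def test_excitation_error_recomputation(self, small_cell, mid_geom):
        params = IndexParams(resolution_cutoff=3.0)
        R = Orientation.random(np.random.default_rng(2))
        preds = predict_reflections(small_cell, R, BEAM9, mid_geom, params)
        assert len(preds) > 0
        B = reciprocal_basis(small_cell)
        k = 1.0 / BEAM9.wavelength
        for p in preds:
            g = R.rotation @ (B @ p.hkl)
            err = (np.linalg.norm(g + [0, 0, k]) - k) / k
            assert err == pytest.approx(p.excitation_error, abs=1e-12)
            assert abs(err) <= params.bandwidth_tolerance
            assert p.resolution >= params.resolution_cutoff - 1e-9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_exhaustive_enumeration(self, small_cell, mid_geom, seed):
        params = IndexParams(resolution_cutoff=3.0)
        R = (Orientation.identity() if seed == 0
             else Orientation.random(np.random.default_rng(seed)))
        preds = predict_reflections(small_cell, R, BEAM9, mid_geom, params)
        expected = brute_force_predictions(small_cell, R, BEAM9, mid_geom, params)
        assert set(map(tuple, preds.hkl.tolist())) == expected


class TestMatchPeaks:
    def _preds(self, coords):
        n = len(coords)
        return PredictionSet(np.zeros((n, 3), dtype=int), np.asarray(coords),
                             np.zeros(n), np.full(n, 2.0))

    def test_empty_predictions(self):
        peaks = PeakList([Peak((1.0, 1.0), 5.0)])
        assert match_peaks(peaks, self._preds(np.zeros((0, 2))), 4.0) == []

    def test_exact_coincidence(self):
        peaks = PeakList([Peak((10.0, 20.0), 5.0)])
        pairs = match_peaks(peaks, self._preds([(10.0, 20.0)]), 4.0)
        assert pairs == [(0, 0)]

    def test_one_to_one_assignment(self):
        peaks = PeakList([Peak((0.0, 0.0), 9.0), Peak((0.0, 1.0), 5.0)])
        pairs = match_peaks(peaks, self._preds([(0.0, 0.4)]), 4.0)
        assert pairs == [(0, 0)]  # closer peak wins, the other goes unmatched

    @pytest.mark.parametrize("seed", range(20))
    def test_near_optimal_vs_hungarian_oracle(self, seed):
        from scipy.optimize import linear_sum_assignment
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(3, 15)), int(rng.integers(3, 15))
        ppos = rng.uniform(0, 30, (n, 2))
        qpos = rng.uniform(0, 30, (m, 2))
        radius = 6.0
        peaks = PeakList([Peak(tuple(p), 1.0) for p in ppos])
        pairs = match_peaks(peaks, self._preds(qpos), radius)
        # Optimal assignment maximising the number of pairs within radius.
        d = np.hypot(*(ppos[:, None, :] - qpos[None, :, :]).transpose(2, 0, 1))
        cost = np.where(d <= radius, d, 1e6)
        ri, ci = linear_sum_assignment(cost)
        optimal = int((cost[ri, ci] < 1e6).sum())
        assert len(pairs) >= optimal - max(1, int(0.05 * optimal))


class TestIntegrate:
    def _single(self, pos):
        return PredictionSet(np.array([[1, 0, 0]]), np.array([pos]),
                             np.array([0.0]), np.array([2.0]))

    def test_flat_background_cancels(self):
        vals, flags = integrate(np.full((64, 64), 13.0), self._single((30, 30)))
        assert vals[0] == pytest.approx(0.0, abs=1e-9)
        assert not flags[0]

    def test_gaussian_spot_recovery(self):
        img = np.full((64, 64), 7.0) + gaussian_blob((64, 64), (30.2, 31.7),
                                                     1.2, 5000 / (2 * np.pi * 1.44))
        vals, _ = integrate(img, self._single((30.2, 31.7)), (6, 6, 8))
        assert vals[0] == pytest.approx(5000.0, rel=0.02)

    def test_background_invariance(self):
        spot = gaussian_blob((64, 64), (30.0, 30.0), 1.2, 500.0)
        v1, _ = integrate(spot + 5.0, self._single((30.0, 30.0)))
        v2, _ = integrate(spot + 10.0, self._single((30.0, 30.0)))
        assert v1[0] == pytest.approx(v2[0], rel=1e-9)

    def test_edge_clipping_flagged(self):
        vals, flags = integrate(np.zeros((64, 64)), self._single((2.0, 30.0)))
        assert flags[0]

    def test_off_image_absent(self):
        vals, flags = integrate(np.zeros((64, 64)), self._single((-50.0, 30.0)))
        assert np.isnan(vals[0]) and flags[0]

    def test_bad_radii_rejected(self):
        with pytest.raises(ValueError):
            integrate(np.zeros((64, 64)), self._single((30, 30)), (8, 6, 7))


class TestIndexKnownCell:
    def test_roundtrip_from_exact_positions(self, lyso_cell, geom2):
        sym = symmetry_rotations(lyso_cell)
        for seed in (1, 2):
            R = Orientation.random(np.random.default_rng(seed))
            preds = predict_reflections(lyso_cell, R, BEAM9, geom2)
            peaks = PeakList([Peak((p[0], p[1]), 100.0) for p in preds.pos])
            sol = index_known_cell(peaks, lyso_cell, BEAM9, geom2)
            assert sol is not None
            assert misorientation_deg(sol.orientation, R, sym) < 0.2
            assert sol.score == len(peaks)

    def test_symmetry_equivalent_truths_give_same_solution(self, lyso_cell, geom2):
        sym = symmetry_rotations(lyso_cell)
        R = Orientation.random(np.random.default_rng(4))
        sols = []
        for S in sym[:4]:
            preds = predict_reflections(lyso_cell, Orientation(R.rotation @ S),
                                        BEAM9, geom2)
            peaks = PeakList([Peak((p[0], p[1]), 100.0) for p in preds.pos])
            sol = index_known_cell(peaks, lyso_cell, BEAM9, geom2)
            assert sol is not None
            sols.append(sol.orientation)
        for s in sols[1:]:
            assert misorientation_deg(sols[0], s, sym) < 0.2

    @pytest.mark.parametrize("seed", range(5))
    def test_random_peaks_fail(self, lyso_cell, geom2, seed):
        rng = np.random.default_rng(100 + seed)
        pos = np.column_stack([rng.uniform(0, 2047, 30), rng.uniform(0, 511, 30)])
        peaks = PeakList([Peak(tuple(p), 100.0) for p in pos])
        assert index_known_cell(peaks, lyso_cell, BEAM9, geom2) is None

    def test_too_few_peaks_fail_immediately(self, lyso_cell, geom2):
        peaks = PeakList([Peak((100.0, 100.0), 1.0) for _ in range(5)])
        assert index_known_cell(peaks, lyso_cell, BEAM9, geom2) is None
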