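"""Physical constants, lattice geometry and shared domain types."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from twocolor_sfx.core import (
    HC_KEV_ANGSTROM,
    DetectorGeometry,
    Orientation,
    PhotonBeam,
    UnitCell,
    canonical_orientation,
    direct_basis,
    energy_to_wavelength,
    misorientation_deg,
    reciprocal_basis,
    symmetry_rotations,
    wavelength_to_energy,
)


class TestEnergyWavelength:
    @pytest.mark.parametrize("energy, expected", [
        (12.3984193, 1.0),                 # definition of the constant
        (7.0, HC_KEV_ANGSTROM / 7.0),      # independent oracle: hc / E
        (9.0, HC_KEV_ANGSTROM / 9.0),
    ])
    def test_known_conversions(self, energy, expected):
        assert energy_to_wavelength(energy) == pytest.approx(expected, rel=1e-12)

    def test_printed_wavelengths(self):
        # The two study colours, to the precision used in the data fields.
        assert energy_to_wavelength(7.0) == pytest.approx(1.77120, abs=5e-6)
        assert energy_to_wavelength(9.0) == pytest.approx(1.37760, abs=5e-6)

    @given(st.floats(min_value=0.1, max_value=100.0))
    @settings(max_examples=50, derandomize=True)
    def test_roundtrip_bijection(self, energy):
        wl = energy_to_wavelength(energy)
        assert wavelength_to_energy(wl) == pytest.approx(energy, rel=1e-12)

    def test_strictly_decreasing(self):
        es = np.linspace(0.5, 30.0, 100)
        wls = [energy_to_wavelength(e) for e in es]
        assert all(a > b for a, b in zip(wls, wls[1:]))

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_nonpositive_energy_rejected(self, bad):
        with pytest.raises(ValueError):
            energy_to_wavelength(bad)


class TestUnitCell:
    def test_tetragonal_constraints(self):
        with pytest.raises(ValueError):
            UnitCell(78.3, 70.0, 39.1, lattice_system="tetragonal")
        with pytest.raises(ValueError):
            UnitCell(78.3, 78.3, 39.1, alpha=89.0, lattice_system="tetragonal")

    @pytest.mark.parametrize("kwargs", [
        dict(a=-1.0, b=1.0, c=1.0),
        dict(a=1.0, b=1.0, c=1.0, alpha=0.0),
        dict(a=1.0, b=1.0, c=1.0, gamma=180.0),
    ])
    def test_invalid_cells_rejected(self, kwargs):
        with pytest.raises(ValueError):
            UnitCell(**kwargs)

    def test_file_roundtrip(self, tmp_path, lyso_cell):
        path = tmp_path / "cell.txt"
        lyso_cell.to_file(path)
        back = UnitCell.from_file(path)
        assert back == lyso_cell


class TestReciprocalBasis:
    def test_cubic_identity_case(self):
        B = reciprocal_basis(UnitCell(1.0, 1.0, 1.0, lattice_system="cubic"))
        np.testing.assert_allclose(B, np.eye(3), atol=1e-12)

    def test_study_cell_lengths(self, lyso_cell):
        B = reciprocal_basis(lyso_cell)
        norms = np.linalg.norm(B, axis=0)
        assert norms[0] == pytest.approx(1 / 78.3, rel=1e-12)
        assert norms[1] == pytest.approx(1 / 78.3, rel=1e-12)
        assert norms[2] == pytest.approx(1 / 39.1, rel=1e-12)
        # mutual orthogonality for the orthogonal cell
        assert abs(B[:, 0] @ B[:, 1]) < 1e-15

    @pytest.mark.parametrize("cell", [
        UnitCell(78.3, 78.3, 39.1, lattice_system="tetragonal"),
        UnitCell(10.0, 12.0, 14.0, 75.0, 85.0, 95.0),
    ])
    def test_duality_relations(self, cell):
        A = direct_basis(cell)  # rows a, b, c
        B = reciprocal_basis(cell)  # columns a*, b*, c*
        np.testing.assert_allclose(A @ B, np.eye(3), atol=1e-10)

    def test_direct_basis_reconstruction(self):
        cell = UnitCell(10.0, 12.0, 14.0, 75.0, 85.0, 95.0)
        A = direct_basis(cell)
        lengths = np.linalg.norm(A, axis=1)
        np.testing.assert_allclose(lengths, [10.0, 12.0, 14.0], rtol=1e-9)
        cosg = A[0] @ A[1] / (lengths[0] * lengths[1])
        assert math.degrees(math.acos(cosg)) == pytest.approx(95.0, rel=1e-9)


def _closed_under_composition(rots):
    def find(M):
        return any(np.allclose(M, R, atol=1e-9) for R in rots)
    return all(find(R1 @ R2) for R1 in rots for R2 in rots)


class TestSymmetryRotations:
    def test_tetragonal_group(self, lyso_cell):
        rots = symmetry_rotations(lyso_cell)
        assert len(rots) == 8
        assert any(np.allclose(R, np.eye(3)) for R in rots)
        assert _closed_under_composition(rots)

    def test_cubic_group(self):
        rots = symmetry_rotations(UnitCell(5.0, 5.0, 5.0, lattice_system="cubic"))
        assert len(rots) == 24
        assert _closed_under_composition(rots)

    def test_unsupported_system(self):
        with pytest.raises(NotImplementedError):
            symmetry_rotations(UnitCell(10.0, 11.0, 12.0))

    @pytest.mark.parametrize("cell", [
        UnitCell(78.3, 78.3, 39.1, lattice_system="tetragonal"),
        UnitCell(5.0, 5.0, 5.0, lattice_system="cubic"),
    ])
    def test_rotations_map_lattice_onto_itself(self, cell):
        # Brute force over all |h|,|k|,|l| <= 2.
        B = reciprocal_basis(cell)
        hs = np.array([(h, k, l) for h in range(-2, 3) for k in range(-2, 3)
                       for l in range(-2, 3)])
        g = hs @ B.T
        gset = {tuple(np.round(v, 9)) for v in g}
        for S in symmetry_rotations(cell):
            mapped = g @ S.T
            assert all(tuple(np.round(v, 9)) in gset for v in mapped)


class TestOrientation:
    def test_rejects_improper_matrix(self):
        M = np.diag([1.0, 1.0, -1.0])  # reflection
        with pytest.raises(ValueError):
            Orientation(M)

    def test_random_is_proper(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            R = Orientation.random(rng).rotation
            np.testing.assert_allclose(R @ R.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-12)

    def test_misorientation_modulo_symmetry(self, lyso_cell):
        sym = symmetry_rotations(lyso_cell)
        rng = np.random.default_rng(11)
        R = Orientation.random(rng)
        for S in sym:
            equiv = Orientation(R.rotation @ S)
            assert misorientation_deg(R, equiv, sym) < 1e-5

    def test_canonicalization_is_class_invariant(self, lyso_cell):
        sym = symmetry_rotations(lyso_cell)
        rng = np.random.default_rng(13)
        R = Orientation.random(rng)
        reps = {tuple(np.round(
            canonical_orientation(Orientation(R.rotation @ S), sym
                                  ).rotation.ravel(), 9)) for S in sym}
        assert len(reps) == 1


class TestPhotonBeam:
    def test_consistency_enforced(self):
        with pytest.raises(ValueError):
            PhotonBeam(7.0, 1.5)
        beam = PhotonBeam.from_energy(7.0)
        assert beam.energy * beam.wavelength == pytest.approx(
            HC_KEV_ANGSTROM, rel=1e-12)


class TestDetectorGeometry:
    def test_assembled_shape_matches_deposited_frame(self):
        geom = DetectorGeometry()
        assert geom.assembled_shape == (8192, 512)

    def test_pixel_projection_roundtrip(self, geom2):
        rng = np.random.default_rng(5)
        pos = np.column_stack([rng.uniform(0, 2047, 50), rng.uniform(0, 511, 50)])
        q = geom2.scattering_vectors(pos, 1.3776)
        k = 1.0 / 1.3776
        v = q + np.array([0.0, 0.0, k])
        back, on = geom2.project_to_detector(v)
        assert on.all()
        np.testing.assert_allclose(back, pos, atol=1e-9)

    def test_scattering_vectors_lie_on_ewald_sphere(self, geom2):
        pos = np.array([[100.0, 100.0], [1500.0, 300.0]])
        wl = 1.77
        q = geom2.scattering_vectors(pos, wl)
        k = 1.0 / wl
        np.testing.assert_allclose(
            np.linalg.norm(q + [0, 0, k], axis=1), k, rtol=1e-12)

    def test_config_file_roundtrip(self, tmp_path):
        geom = DetectorGeometry(n_panels=2, panel_shape=(1024, 512),
                                pixel_size=0.05, distance=51.03,
                                beam_center=(1024.0, 256.0))
        path = tmp_path / "geom.txt"
        geom.to_file(path)
        back = DetectorGeometry.from_file(path)
        assert back == geom

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            DetectorGeometry(distance=-1.0)
        with pytest.raises(ValueError):
            DetectorGeometry(pixel_size=0.0)
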