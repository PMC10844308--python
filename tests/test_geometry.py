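"""Internal-angle featurization, NeRF reconstruction, and PDB round-trips."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from torsiondiff.geometry import (AngleFeaturization, BackboneStructure,
                                  BondLengthConstants, DEFAULT_BOND_LENGTHS,
                                  DegenerateGeometryError,
                                  IncompleteResidueError, bond_angle,
                                  dihedral_angle, featurize_backbone,
                                  place_oxygens, read_pdb,
                                  reconstruct_backbone, superimpose_rmsd,
                                  wrap_angles, write_pdb)
from torsiondiff.data import make_ideal_secondary_fixture

from conftest import random_angle_matrix


def rotation_matrix(axis, angle):
    from scipy.spatial.transform import Rotation
    return Rotation.from_rotvec(np.asarray(axis) / np.linalg.norm(axis) * angle
                                ).as_matrix()


class TestDihedral:
    def test_quarter_turn_example(self):
        """Staircase arrangement gives +pi/2; biotite is the oracle."""
        from biotite.structure import dihedral as biotite_dihedral

        pts = [np.array(p, dtype=float) for p in
               [(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)]]
        ours = dihedral_angle(*pts)
        oracle = float(biotite_dihedral(*pts))
        assert ours == pytest.approx(oracle, abs=1e-6)
        assert ours == pytest.approx(np.pi / 2, abs=1e-12)

    def test_cis_coplanar_is_zero(self):
        p = [(0, 0, 0), (1, 0, 0), (1, 1, 0), (0, 1, 0)]  # p3 on same side as p0
        assert dihedral_angle(*p) == pytest.approx(0.0, abs=1e-12)

    def test_mirror_flips_sign(self, rng):
        for _ in range(20):
            p0, p1, p2, p3 = rng.normal(size=(4, 3)) * 2
            try:
                t = dihedral_angle(p0, p1, p2, p3)
            except DegenerateGeometryError:
                continue
            p3m = p3.copy()
            # reflect p3 through the p0-p1-p2 plane
            n = np.cross(p1 - p0, p2 - p0)
            n = n / np.linalg.norm(n)
            p3m = p3 - 2 * np.dot(p3 - p0, n) * n
            tm = dihedral_angle(p0, p1, p2, p3m)
            assert abs(tm) == pytest.approx(abs(t), abs=1e-9)
            if abs(t) > 1e-9 and abs(abs(t) - np.pi) > 1e-9:
                assert np.sign(tm) == -np.sign(t)

    def test_collinear_raises(self):
        with pytest.raises(DegenerateGeometryError):
            dihedral_angle((0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 1, 0))


class TestBondAngle:
    def test_collinear_is_pi(self):
        assert bond_angle((0, 0, 0), (1, 0, 0), (2, 0, 0)) == pytest.approx(np.pi)

    def test_orthogonal_is_half_pi(self):
        assert bond_angle((1, 0, 0), (0, 0, 0), (0, 1, 0)) == pytest.approx(np.pi / 2)

    def test_coincident_raises(self):
        with pytest.raises(DegenerateGeometryError):
            bond_angle((0, 0, 0), (0, 0, 0), (1, 0, 0))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rigid_transform_invariance(self, seed):
        rng = np.random.default_rng(seed)
        pts = rng.normal(size=(3, 3)) * 3
        rot = rotation_matrix(rng.normal(size=3) + 1e-3, rng.uniform(0, np.pi))
        shift = rng.normal(size=3) * 10
        before = bond_angle(*pts)
        after = bond_angle(*(p @ rot.T + shift for p in pts))
        assert after == pytest.approx(before, abs=1e-12)


class TestFeaturize:
    def test_two_residue_trans_planar_omega(self):
        """A planar trans peptide fragment has omega = -pi (pi wrapped)."""
        row = wrap_angles(np.array([0.3, np.pi, -0.7,
                                    *np.deg2rad([111.0, 116.2, 121.7])]))
        s = reconstruct_backbone(AngleFeaturization(row[None, :]))
        feats = featurize_backbone(s)
        assert feats.angles[0, 1] == pytest.approx(-np.pi, abs=1e-9)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_roundtrip_identity_on_angle_space(self, seed):
        rng = np.random.default_rng(seed)
        A = AngleFeaturization(wrap_angles(random_angle_matrix(rng, 12)))
        back = featurize_backbone(reconstruct_backbone(A))
        assert np.abs(wrap_angles(back.angles - A.angles)).max() < 1e-6

    def test_helix_fixture_reproduces_phi_psi(self):
        phi, psi = np.deg2rad(-57.0), np.deg2rad(-47.0)
        s = make_ideal_secondary_fixture("helix", 25)
        feats = featurize_backbone(s)
        assert np.allclose(feats.angles[:, 2], phi, atol=1e-6)
        assert np.allclose(feats.angles[:, 0], psi, atol=1e-6)

    def test_missing_atom_raises_with_residue_index(self):
        s = make_ideal_secondary_fixture("helix", 6)
        s.ca[3] = np.nan
        with pytest.raises(IncompleteResidueError, match="3"):
            featurize_backbone(s)


class TestReconstruct:
    def test_inverse_composition_on_idealized_geometry(self, rng):
        A = AngleFeaturization(wrap_angles(random_angle_matrix(rng, 20)))
        s = reconstruct_backbone(A)
        s2 = reconstruct_backbone(featurize_backbone(s))
        assert superimpose_rmsd(s, s2) < 1e-3

    def test_straight_bond_angles_give_collinear_chain(self):
        rows = np.column_stack([
            np.random.default_rng(0).uniform(-np.pi, np.pi, size=(8, 3)),
            np.full((8, 3), wrap_angles(np.pi)),
        ])
        s = reconstruct_backbone(AngleFeaturization(wrap_angles(rows)))
        atoms = s.atoms()
        d = atoms - atoms[0]
        ref = d[-1] / np.linalg.norm(d[-1])
        cross = np.linalg.norm(np.cross(d[1:], ref), axis=1)
        assert cross.max() < 1e-6

    def test_no_error_growth_along_128_residue_chain(self, rng):
        A = AngleFeaturization(wrap_angles(random_angle_matrix(rng, 127)))
        s = reconstruct_backbone(A)
        s2 = reconstruct_backbone(featurize_backbone(s))
        # per-atom displacement after superposition, checked at both termini
        from scipy.spatial.transform import Rotation
        pa, pb = s.atoms(), s2.atoms()
        ca, cb = pa - pa.mean(0), pb - pb.mean(0)
        rot, _ = Rotation.align_vectors(ca, cb)
        disp = np.linalg.norm(ca - rot.apply(cb), axis=1)
        assert disp[:3].max() < 1e-3
        assert disp[-3:].max() < 1e-3

    def test_mirror_image_on_negated_dihedrals(self, rng):
        A = wrap_angles(random_angle_matrix(rng, 10))
        M = A.copy()
        M[:, :3] = wrap_angles(-M[:, :3])
        s = reconstruct_backbone(AngleFeaturization(A))
        m = reconstruct_backbone(AngleFeaturization(M))
        from scipy.spatial.distance import pdist
        assert np.allclose(pdist(s.atoms()), pdist(m.atoms()), atol=1e-8)
        vol_s = np.linalg.det(np.array([s.ca[0] - s.n[0], s.c[0] - s.ca[0],
                                        s.n[1] - s.c[0]]))
        vol_m = np.linalg.det(np.array([m.ca[0] - m.n[0], m.c[0] - m.ca[0],
                                        m.n[1] - m.c[0]]))
        assert np.sign(vol_s) == -np.sign(vol_m)

    def test_locality_of_angle_rows(self, rng):
        A = wrap_angles(random_angle_matrix(rng, 15))
        s = reconstruct_backbone(AngleFeaturization(A))
        B = A.copy()
        B[7] = wrap_angles(B[7] + 0.5)
        s2 = reconstruct_backbone(AngleFeaturization(B))
        # atoms of residues 0..7 are placed before row 7 is consumed
        assert np.allclose(s.atoms()[:3 * 8 - 2], s2.atoms()[:3 * 8 - 2], atol=1e-12)

    def test_reconstructed_bond_lengths_match_constants(self, rng):
        A = AngleFeaturization(wrap_angles(random_angle_matrix(rng, 10)))
        s = reconstruct_backbone(A)
        L = DEFAULT_BOND_LENGTHS
        for i in range(s.residue_count):
            assert np.linalg.norm(s.ca[i] - s.n[i]) == pytest.approx(L.n_ca, abs=1e-6)
            assert np.linalg.norm(s.c[i] - s.ca[i]) == pytest.approx(L.ca_c, abs=1e-6)
            if i + 1 < s.residue_count:
                assert np.linalg.norm(s.n[i + 1] - s.c[i]) == pytest.approx(
                    L.c_n, abs=1e-6)

    def test_bond_length_constants_validated(self):
        with pytest.raises(ValueError):
            BondLengthConstants(n_ca=0.5)


class TestPlaceOxygens:
    def test_geometry_of_placed_oxygens(self, helix_structure):
        s = place_oxygens(helix_structure)
        L = DEFAULT_BOND_LENGTHS
        for i in range(s.residue_count - 1):
            o, c, ca, nn = s.o[i], s.c[i], s.ca[i], s.n[i + 1]
            # coplanarity of O, C, N_{i+1}, CA_i
            triple = np.dot(np.cross(ca - c, nn - c), o - c)
            assert abs(triple) < 1e-9
            assert np.linalg.norm(o - c) == pytest.approx(L.c_o, abs=1e-9)
            assert bond_angle(o, c, nn) == pytest.approx(L.o_c_n_angle, abs=1e-9)
        assert np.linalg.norm(s.o[-1] - s.c[-1]) == pytest.approx(L.c_o, abs=1e-9)


class TestPdbIO:
    def test_write_read_roundtrip(self, tmp_path, helix_structure):
        path = tmp_path / "helix.pdb"
        write_pdb(place_oxygens(helix_structure), path)
        (back,) = read_pdb(path)
        assert back.residue_count == helix_structure.residue_count
        assert np.allclose(back.n, helix_structure.n, atol=1e-3)
        assert np.allclose(back.ca, helix_structure.ca, atol=1e-3)
        assert np.allclose(back.c, helix_structure.c, atol=1e-3)
        assert back.o is not None

    def test_chain_with_missing_ca_skipped(self, tmp_path, helix_structure, caplog):
        import logging
        path = tmp_path / "broken.pdb"
        write_pdb(helix_structure, path)
        lines = [l for l in path.read_text().splitlines()
                 if not (" CA " in l and " GLY A   5 " in l)]
        path.write_text("\n".join(lines) + "\n")
        with caplog.at_level(logging.WARNING):
            structures = read_pdb(path)
        assert structures == []
        assert any("backbone atom" in r.message for r in caplog.records)
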