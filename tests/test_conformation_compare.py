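"""Kabsch superposition, Cα r.m.s.d. and radius of gyration."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from statemap.conformation_compare import (
    CoordinateEnsemble,
    SegmentSpec,
    ca_rmsd,
    kabsch_superpose,
    radius_of_gyration,
    read_xyz_frames,
    rg_profile,
)
from statemap.synthetic_data import BundleSpec, make_two_state_bundle, make_unfolding_ensemble


def _quaternion_rmsd(a, b):
    """Independent oracle: optimal-superposition RMSD via the quaternion
    eigenvalue method (Kearsley)."""
    a0 = a - a.mean(axis=0)
    b0 = b - b.mean(axis=0)
    xm, ym, zm = (b0 - a0).T
    xp, yp, zp = (b0 + a0).T
    k = np.empty((4, 4))
    k[0, 0] = (xm**2 + ym**2 + zm**2).sum()
    k[1, 1] = (xm**2 + yp**2 + zp**2).sum()
    k[2, 2] = (xp**2 + ym**2 + zp**2).sum()
    k[3, 3] = (xp**2 + yp**2 + zm**2).sum()
    k[0, 1] = k[1, 0] = (yp * zm - ym * zp).sum()
    k[0, 2] = k[2, 0] = (xm * zp - xp * zm).sum()
    k[0, 3] = k[3, 0] = (xp * ym - xm * yp).sum()
    k[1, 2] = k[2, 1] = (xm * ym - xp * yp).sum()
    k[1, 3] = k[3, 1] = (xm * zm - xp * zp).sum()
    k[2, 3] = k[3, 2] = (ym * zm - yp * zp).sum()
    lam = np.linalg.eigvalsh(k)[0]
    return np.sqrt(max(lam, 0.0) / len(a))


class TestKabsch:
    def test_identity(self, rng):
        a = rng.normal(size=(10, 3))
        res = kabsch_superpose(a, a)
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.rotation, np.eye(3), atol=1e-9)

    def test_translation_invariance(self, rng):
        a = rng.normal(size=(10, 3))
        res = kabsch_superpose(a, a + np.array([5.0, 0.0, 0.0]))
        assert res.rmsd == pytest.approx(0.0, abs=1e-12)

    def test_agrees_with_quaternion_oracle(self, rng):
        """4-point set with one displaced point: second-method agreement to 1e-6."""
        a = np.array([[0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]], float)
        b = a.copy()
        b[3] += [0.6, -0.8, 0.0]  # 1 Å displacement
        rot = Rotation.from_euler("zyx", [31, -17, 55], degrees=True).as_matrix()
        b = b @ rot.T + [2.0, -1.0, 4.0]
        res = kabsch_superpose(a, b)
        assert res.rmsd == pytest.approx(_quaternion_rmsd(a, b), abs=1e-6)
        assert np.linalg.det(res.rotation) == pytest.approx(1.0, abs=1e-6)

    def test_symmetry_and_rigid_invariance(self, rng):
        a = rng.normal(size=(12, 3))
        b = rng.normal(size=(12, 3))
        rot = Rotation.random(rng=42).as_matrix()
        assert kabsch_superpose(a, b).rmsd == pytest.approx(
            kabsch_superpose(b, a).rmsd, abs=1e-9)
        assert kabsch_superpose(a, b @ rot.T + 3.0).rmsd == pytest.approx(
            kabsch_superpose(a, b).rmsd, abs=1e-9)

    def test_rejects_degenerate_input(self):
        line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
        with pytest.raises(ValueError):
            kabsch_superpose(line, line)
        with pytest.raises(ValueError):
            kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))


class TestCaRmsd:
    def _bundle(self, seed=0):
        spec = BundleSpec(n_helices=2, residues_per_helix=8,
                          axis_positions=[(0, 0), (9.0, 0)], seed=seed)
        active, _, gmap, _ = make_two_state_bundle(spec)
        return active, gmap

    def test_self_rmsd_zero(self):
        model, gmap = self._bundle()
        res = ca_rmsd(model, gmap, model, gmap)
        assert res.rmsd == pytest.approx(0.0, abs=1e-9)
        assert res.n_atoms == 16  # every mapped residue has a Cα

    def test_rotated_copy_rmsd_zero(self):
        import copy
        from statemap.structure_io import AtomRecord, ResidueRecord, StructureModel
        model, gmap = self._bundle()
        rot = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        moved = StructureModel("rot", model.receptor, "unspecified", [
            ResidueRecord(r.chain, r.seqnum, r.icode, r.resname, tuple(
                AtomRecord(a.name, a.element, rot @ a.position + 7.0)
                for a in r.atoms))
            for r in model.residues])
        assert ca_rmsd(model, gmap, moved, gmap).rmsd == pytest.approx(0.0, abs=1e-6)

    def test_planted_displacement_matches_bruteforce(self):
        """One helix displaced: r.m.s.d. equals the brute-force optimal-fit value."""
        from statemap.structure_io import AtomRecord, ResidueRecord, StructureModel
        model, gmap = self._bundle()
        shift = np.array([2.0, 0.0, 0.0])
        moved = StructureModel("shift", model.receptor, "unspecified", [
            ResidueRecord(r.chain, r.seqnum, r.icode, r.resname, tuple(
                AtomRecord(a.name, a.element,
                           a.position + (shift if i >= 8 else 0.0))
                for a in r.atoms))
            for i, r in enumerate(model.residues)])
        res = ca_rmsd(model, gmap, moved, gmap)
        ca_a = np.array([r.atom("CA").position for r in model.residues])
        ca_b = np.array([r.atom("CA").position for r in moved.residues])
        assert res.rmsd == pytest.approx(_quaternion_rmsd(ca_a, ca_b), abs=1e-9)
        assert res.rmsd > 0.5  # the displacement is not absorbed by the fit


class TestRadiusOfGyration:
    def test_single_atom_zero(self):
        assert radius_of_gyration(np.array([[1.0, 2.0, 3.0]])) == 0.0

    def test_two_equal_masses_half_separation(self):
        coords = np.array([[0.0, 0.0, 0.0], [2.0, 0.0, 0.0]])
        assert radius_of_gyration(coords) == pytest.approx(1.0, abs=1e-12)

    def test_unequal_masses_match_direct_sum(self, rng):
        coords = rng.normal(size=(8, 3)) * 4.0
        masses = rng.uniform(1.0, 32.0, size=8)
        com = (masses[:, None] * coords).sum(0) / masses.sum()
        direct = np.sqrt(sum(m * ((c - com) ** 2).sum()
                             for m, c in zip(masses, coords)) / masses.sum())
        assert radius_of_gyration(coords, masses) == pytest.approx(direct, abs=1e-9)

    def test_rigid_invariance_and_scaling(self, rng):
        coords = rng.normal(size=(20, 3)) * 5.0
        rot = Rotation.random(rng=7).as_matrix()
        rg = radius_of_gyration(coords)
        assert radius_of_gyration(coords @ rot.T + 11.0) == pytest.approx(rg, abs=1e-9)
        centroid = coords.mean(axis=0)
        assert radius_of_gyration(centroid + 3.0 * (coords - centroid)) == pytest.approx(
            3.0 * rg, abs=1e-9)

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            radius_of_gyration(np.empty((0, 3)))


class TestRgProfile:
    def test_constant_for_identical_frames(self):
        labels = [("A", 244 + i, "CA", "C") for i in range(6)]
        frame = np.column_stack([np.zeros(6), np.zeros(6), np.arange(6.0)])
        ens = CoordinateEnsemble(frames=[frame.copy() for _ in range(4)],
                                 atom_labels=labels)
        prof = rg_profile(ens, SegmentSpec("A", 244, 249))
        rgs = {rg for _, rg in prof}
        assert len(prof) == 4 and max(rgs) - min(rgs) < 1e-12

    def test_scaled_frames_scale_rg(self, rng):
        labels = [("A", 244 + i, "CA", "C") for i in range(6)]
        frame = rng.normal(size=(6, 3)) * 3.0
        centroid = frame.mean(axis=0)
        ens = CoordinateEnsemble(
            frames=[frame, centroid + 2.0 * (frame - centroid)], atom_labels=labels)
        (t0, rg0), (t1, rg1) = rg_profile(ens, SegmentSpec("A", 244, 249))
        assert rg1 == pytest.approx(2.0 * rg0, abs=1e-9)

    def test_unfolding_ensemble_monotone_increasing(self):
        ens = make_unfolding_ensemble(n_frames=12, segment_length=8, seed=5)
        prof = rg_profile(ens, SegmentSpec("A", 244, 251))
        rgs = [rg for _, rg in prof]
        assert all(b > a for a, b in zip(rgs, rgs[1:]))

    def test_label_mismatch_raises(self):
        ens = make_unfolding_ensemble(3, 8, 0)
        with pytest.raises(ValueError, match="matches no atoms"):
            rg_profile(ens, SegmentSpec("B", 1, 5))

    def test_xyz_round_trip(self, tmp_path):
        ens = make_unfolding_ensemble(3, 8, 0)
        p = tmp_path / "frames.xyz"
        with open(p, "w") as fh:
            for frame in ens.frames:
                for row in frame:
                    fh.write(f"{row[0]:.6f} {row[1]:.6f} {row[2]:.6f}\n")
                fh.write("\n")
        back = read_xyz_frames(p, ens.atom_labels)
        assert len(back) == 3
        for fa, fb in zip(ens.frames, back.frames):
            assert np.allclose(fa, fb, atol=1e-6)
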