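"""Superposition, per-residue RMSD closed forms, chi1 dihedrals and rotamer
residence.  The superposition oracle is an independent quaternion (Horn)
implementation; chi1 oracles are internal-coordinate constructions."""

import numpy as np
import pytest

from conftest import rigid_move, rotation_matrix
from k2pva.structdev import (
    AlignmentReference,
    chi1_series,
    dihedral,
    kabsch,
    per_residue_rmsd,
    rotamer_residence,
    superpose,
    superpose_trajectory,
    DihedralSeries,
)
from k2pva.synthgen import make_toy_system, place_atom
from k2pva.trajmodel import Trajectory, select


def horn_quaternion_superpose(P, Q):
    """Independent oracle: optimal rotation via Horn's quaternion method."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    Sxx, Sxy, Sxz = P0[:, 0] @ Q0[:, 0], P0[:, 0] @ Q0[:, 1], P0[:, 0] @ Q0[:, 2]
    Syx, Syy, Syz = P0[:, 1] @ Q0[:, 0], P0[:, 1] @ Q0[:, 1], P0[:, 1] @ Q0[:, 2]
    Szx, Szy, Szz = P0[:, 2] @ Q0[:, 0], P0[:, 2] @ Q0[:, 1], P0[:, 2] @ Q0[:, 2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
    ])
    w, v = np.linalg.eigh(N)
    q = v[:, -1]  # eigenvector of the largest eigenvalue
    q0, q1, q2, q3 = q
    R = np.array([
        [q0*q0+q1*q1-q2*q2-q3*q3, 2*(q1*q2-q0*q3), 2*(q1*q3+q0*q2)],
        [2*(q1*q2+q0*q3), q0*q0-q1*q1+q2*q2-q3*q3, 2*(q2*q3-q0*q1)],
        [2*(q1*q3-q0*q2), 2*(q2*q3+q0*q1), q0*q0-q1*q1-q2*q2+q3*q3],
    ])
    return R


class TestSuperpose:
    def test_identity_when_frame_equals_reference(self, phe_system):
        sel = select(phe_system.topology, "residues 1,3,5 heavy atoms")
        ref = AlignmentReference(phe_system.coordinates, sel)
        R, t, out = superpose(phe_system.coordinates, ref, phe_system.topology)
        assert np.allclose(R, np.eye(3), atol=1e-10)
        assert np.allclose(t, 0, atol=1e-9)
        assert np.abs(out - phe_system.coordinates).max() < 1e-9

    def test_recovers_planted_rigid_motion(self, phe_system):
        sel = select(phe_system.topology, "residues 1,3,5 heavy atoms")
        ref = AlignmentReference(phe_system.coordinates, sel)
        moved = rigid_move(phe_system.coordinates, seed=4)
        _R, _t, out = superpose(moved, ref, phe_system.topology)
        assert np.abs(out - phe_system.coordinates).max() < 1e-6

    def test_matches_quaternion_oracle_under_noise(self, phe_system):
        rng = np.random.default_rng(8)
        sel = select(phe_system.topology, "residues 1,2,3 heavy atoms")
        idx = phe_system.topology.indices_of(sel.atom_ids)
        ref_xyz = phe_system.coordinates
        noisy = rigid_move(ref_xyz, seed=2) + rng.normal(scale=0.3, size=ref_xyz.shape)
        ref = AlignmentReference(ref_xyz, sel)
        _R, _t, out = superpose(noisy, ref, phe_system.topology)
        # oracle: quaternion superposition of the alignment atoms
        R_o = horn_quaternion_superpose(noisy[idx], ref_xyz[idx])
        aligned_oracle = (noisy[idx] - noisy[idx].mean(0)) @ R_o.T + ref_xyz[idx].mean(0)
        rmsd_impl = np.sqrt(((out[idx] - ref_xyz[idx]) ** 2).sum(1).mean())
        rmsd_oracle = np.sqrt(((aligned_oracle - ref_xyz[idx]) ** 2).sum(1).mean())
        assert abs(rmsd_impl - rmsd_oracle) < 1e-6

    def test_degenerate_alignment_rejected(self):
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            kabsch(line, line + 1.0)


class TestPerResidueRMSD:
    def _ref(self, system, align="residues 1,3,5 heavy atoms"):
        sel = select(system.topology, align)
        return AlignmentReference(system.coordinates, sel)

    def test_reference_repeated_gives_zero(self, phe_system):
        traj = Trajectory(
            phe_system.topology, np.repeat(phe_system.coordinates[None], 4, 0), 1.0
        )
        prof = per_residue_rmsd(traj, self._ref(phe_system))
        assert (prof.mean.to_numpy() < 1e-9).all()

    def test_displaced_side_chain_closed_form(self, phe_system):
        # displace the side chain of residue 2 by v; alignment residues 1,3,5
        top = phe_system.topology
        res = top.residue(2)
        by_id = {a.atom_id: a for a in top.atoms}
        side_ids = [
            i for i in res.atom_ids
            if by_id[i].name not in ("N", "CA", "C", "O")
        ]
        v = np.array([0.7, -0.3, 0.2])
        coords = phe_system.coordinates.copy()
        coords[top.indices_of(side_ids)] += v
        traj = Trajectory(top, coords[None], 1.0)
        prof_all = per_residue_rmsd(traj, self._ref(phe_system), mode="all-atom")
        n_res = len(res.atom_ids)
        n_moved = len(side_ids)
        expected = np.linalg.norm(v) * np.sqrt(n_moved / n_res)
        assert prof_all.mean["PHE2"] == pytest.approx(expected, rel=1e-9)
        prof_ca = per_residue_rmsd(traj, self._ref(phe_system), mode="ca-only")
        assert prof_ca.mean["PHE2"] == pytest.approx(0.0, abs=1e-9)

    def test_global_rigid_motion_removed(self, phe_system):
        frames = np.stack(
            [rigid_move(phe_system.coordinates, seed=s) for s in range(5)]
        )
        traj = Trajectory(phe_system.topology, frames, 1.0)
        prof = per_residue_rmsd(traj, self._ref(phe_system))
        assert (prof.mean.to_numpy() < 1e-6).all()

    def test_ca_profile_is_all_atom_restricted_to_ca(self, phe_system):
        rng = np.random.default_rng(1)
        coords = phe_system.coordinates + rng.normal(scale=0.5, size=phe_system.coordinates.shape)
        traj = Trajectory(phe_system.topology, coords[None], 1.0)
        ref = self._ref(phe_system)
        prof_ca = per_residue_rmsd(traj, ref, mode="ca-only")
        # recompute by hand from the superposed frame restricted to CA
        aligned = superpose_trajectory(traj, ref)
        top = phe_system.topology
        for residx in (1, 2, 3, 4, 5):
            res = top.residue(residx)
            ca_id = [i for i in res.atom_ids
                     if {a.atom_id: a for a in top.atoms}[i].name == "CA"]
            col = top.indices_of(ca_id)
            manual = np.sqrt(((aligned.coordinates[0, col] - ref.coordinates[col]) ** 2).sum())
            assert prof_ca.mean[res.label] == pytest.approx(manual, rel=1e-12)


class TestChi1:
    def test_constructed_dihedrals_recovered(self):
        for target in (-60.0, 60.0, 175.0, 180.0, -120.0):
            system = make_toy_system(4, ring_residues=(2,), seed=1,
                                     chi1_targets={2: target})
            traj = Trajectory(system.topology, system.coordinates[None], 1.0)
            chi = chi1_series(traj, 2).angles_deg[0]
            # compare on the circle
            delta = (chi - target + 180.0) % 360.0 - 180.0
            assert abs(delta) < 1e-6

    def test_antiperiplanar_construction_exact(self):
        a = np.array([0.0, 1.0, 0.0])
        b = np.array([0.0, 0.0, 0.0])
        c = np.array([1.5, 0.0, 0.0])
        d = place_atom(a, b, c, 1.5, 109.5, 180.0)
        assert dihedral(a, b, c, d) == pytest.approx(180.0, abs=1e-9)

    def test_whole_molecule_rotation_invariance(self, phe_system):
        traj = Trajectory(phe_system.topology, phe_system.coordinates[None], 1.0)
        base = chi1_series(traj, 2).angles_deg[0]
        moved = Trajectory(
            phe_system.topology, rigid_move(phe_system.coordinates, seed=9)[None], 1.0
        )
        assert chi1_series(moved, 2).angles_deg[0] == pytest.approx(base, abs=1e-9)

    def test_uniform_scaling_invariance(self, phe_system):
        traj = Trajectory(phe_system.topology, phe_system.coordinates[None], 1.0)
        base = chi1_series(traj, 2).angles_deg[0]
        scaled = Trajectory(phe_system.topology, 3.7 * phe_system.coordinates[None], 1.0)
        assert chi1_series(scaled, 2).angles_deg[0] == pytest.approx(base, abs=1e-9)

    def test_glycine_rejected(self, toy_pdb):
        from k2pva.trajmodel import load_topology

        top = load_topology(toy_pdb)
        traj = Trajectory(top, np.zeros((1, top.n_atoms, 3)) + np.arange(top.n_atoms)[None, :, None], 1.0)
        with pytest.raises(ValueError, match="GLY2"):
            chi1_series(traj, 2)


class TestRotamerResidence:
    def test_all_trans(self):
        s = DihedralSeries("X1", np.full(50, 179.0))
        res = rotamer_residence(s)
        assert res["trans"] == 1.0
        assert res["gauche+"] == 0.0

    def test_planted_70_30_schedule(self):
        angles = np.concatenate([np.full(70, -178.0), np.full(30, 62.0)])
        res = rotamer_residence(DihedralSeries("X1", angles))
        assert res["trans"] == pytest.approx(0.70, abs=0)
        assert res["gauche+"] == pytest.approx(0.30, abs=0)

    def test_wraparound_single_bin(self):
        angles = np.array([179.5, -179.5, 180.0, -180.0 + 1e-9])
        res = rotamer_residence(DihedralSeries("X1", angles))
        assert res["trans"] == 1.0
        assert sum(res.values()) == pytest.approx(1.0, abs=1e-12)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(0)
        angles = rng.uniform(-180, 180, size=500)
        res = rotamer_residence(DihedralSeries("X1", angles))
        assert sum(res.values()) == pytest.approx(1.0, abs=1e-12)
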