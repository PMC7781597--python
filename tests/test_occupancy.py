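"""Ligand-residue occupancy: brute-force oracle agreement, planted-contact
recovery, bound-state conditioning, and binding-site escape detection."""

import numpy as np
import pytest

from conftest import rigid_move
from k2pva.occupancy import (
    NO_ESCAPE,
    OccupancyConfig,
    bound_fraction_near,
    residue_occupancy,
    site_residence,
)
from k2pva.synthgen import (
    make_toy_system,
    place_ligand_at_distance,
    simulate_ligand_walk,
)
from k2pva.trajmodel import Trajectory, select


def brute_force_occupancy(traj, ligand_sel, residue_index, cutoff):
    """Independent oracle: explicit per-frame, all-pairs heavy-atom scan."""
    top = traj.topology
    by_id = {a.atom_id: a for a in top.atoms}
    lig_ids = [i for i in ligand_sel.atom_ids if by_id[i].is_heavy]
    res = top.residue(residue_index)
    res_ids = [i for i in res.atom_ids if by_id[i].is_heavy]
    hits = 0
    for f in range(traj.n_frames):
        within = False
        for li in lig_ids:
            for ri in res_ids:
                d = 0.0
                for k in range(3):
                    d += (
                        traj.coordinates[f, top.index_of(li), k]
                        - traj.coordinates[f, top.index_of(ri), k]
                    ) ** 2
                if d ** 0.5 <= cutoff:
                    within = True
                    break
            if within:
                break
        hits += within
    return hits / traj.n_frames


@pytest.fixture
def walk(wide_system):
    traj, gt = simulate_ligand_walk(
        wide_system, {3: 0.6}, n_frames=100, seed=42
    )
    return wide_system, traj, gt


class TestResidueOccupancy:
    def test_always_within_cutoff_gives_one(self, wide_system):
        coords = place_ligand_at_distance(
            wide_system.topology, wide_system.coordinates, 3, 3.0
        )
        traj = Trajectory(wide_system.topology, np.repeat(coords[None], 10, axis=0), 1.0)
        lig = select(wide_system.topology, "ligand heavy atoms")
        tab = residue_occupancy(traj, lig, [3])
        assert tab.fraction("LEU3") == 1.0

    def test_far_ligand_gives_zero_everywhere(self, wide_system):
        coords = wide_system.coordinates.copy()
        lig = select(wide_system.topology, "ligand heavy atoms")
        idx = wide_system.topology.indices_of(lig.atom_ids)
        coords[idx] += 500.0
        traj = Trajectory(wide_system.topology, np.repeat(coords[None], 5, axis=0), 1.0)
        tab = residue_occupancy(traj, lig, [1, 2, 3, 4, 5])
        assert (tab.table["occupancy"] == 0.0).all()

    def test_planted_walk_matches_brute_force_exactly(self, walk):
        system, traj, gt = walk
        lig = select(system.topology, "ligand heavy atoms")
        tab = residue_occupancy(traj, lig, [3])
        expected = gt.realized_contacts[3] / gt.n_frames
        assert tab.fraction("LEU3") == pytest.approx(expected, abs=0)
        oracle = brute_force_occupancy(traj, lig, 3, 7.0)
        assert tab.fraction("LEU3") == oracle

    def test_brute_force_equivalence_on_random_coordinates(self, wide_system):
        # adversarial: fully random ligand positions, not generator poses
        rng = np.random.default_rng(5)
        top = wide_system.topology
        coords = np.repeat(wide_system.coordinates[None], 60, axis=0)
        lig = select(top, "ligand heavy atoms")
        idx = top.indices_of(lig.atom_ids)
        for f in range(60):
            coords[f, idx] += rng.uniform(-15, 15, size=3)
        traj = Trajectory(top, coords, 1.0)
        for residue in (2, 3, 4):
            res_label = top.residue(residue).label
            tab = residue_occupancy(traj, lig, [residue])
            assert tab.fraction(res_label) == brute_force_occupancy(traj, lig, residue, 7.0)

    def test_rigid_motion_invariance(self, walk):
        system, traj, _ = walk
        lig = select(system.topology, "ligand heavy atoms")
        base = residue_occupancy(traj, lig, [3]).fraction("LEU3")
        moved = Trajectory(
            system.topology,
            np.stack([rigid_move(traj.coordinates[f], seed=f) for f in range(traj.n_frames)]),
            1.0,
        )
        assert residue_occupancy(moved, lig, [3]).fraction("LEU3") == base

    def test_occupancy_nondecreasing_in_cutoff(self, walk):
        system, traj, _ = walk
        lig = select(system.topology, "ligand heavy atoms")
        fracs = [
            residue_occupancy(traj, lig, [3], OccupancyConfig(cutoff=c)).fraction("LEU3")
            for c in (2.0, 4.0, 7.0, 12.0, 30.0)
        ]
        assert fracs == sorted(fracs)

    def test_binomial_recovery_within_three_se(self, wide_system):
        p, n = 0.6, 1000
        traj, gt = simulate_ligand_walk(wide_system, {3: p}, n_frames=n, seed=9)
        lig = select(wide_system.topology, "ligand heavy atoms")
        est = residue_occupancy(traj, lig, [3]).fraction("LEU3")
        se = np.sqrt(p * (1 - p) / n)
        assert abs(est - p) <= 3 * se

    def test_ligand_overlapping_residue_rejected(self, wide_system):
        top = wide_system.topology
        lig = select(top, "residue 3 heavy atoms")  # not a ligand: overlaps
        traj = Trajectory(top, wide_system.coordinates[None], 1.0)
        with pytest.raises(ValueError, match="overlap"):
            residue_occupancy(traj, lig, [3])


class TestBoundConditioning:
    def _traj_with_bound_schedule(self, system, n_bound_near, n_bound_far, n_unbound):
        """Frames: bound+near residue 3, bound-but-far is impossible for a
        single-residue site, so 'bound far' frames use a two-residue site."""
        top = system.topology
        frames = []
        for _ in range(n_bound_near):
            frames.append(place_ligand_at_distance(top, system.coordinates, 3, 4.0))
        for _ in range(n_bound_far):
            # near residue 2 => inside a site defined around residues 2+3
            # only if the site centroid is close enough; use residue 2 pose
            frames.append(place_ligand_at_distance(top, system.coordinates, 2, 4.0))
        for _ in range(n_unbound):
            base = system.coordinates.copy()
            idx = top.indices_of(select(top, "ligand heavy atoms").atom_ids)
            base[idx] += 300.0
            frames.append(base)
        return Trajectory(top, np.stack(frames), 1.0)

    def test_bound_and_adjacent_every_frame(self, wide_system):
        traj = self._traj_with_bound_schedule(wide_system, 20, 0, 0)
        top = wide_system.topology
        lig = select(top, "ligand heavy atoms")
        cfg = OccupancyConfig(
            condition_on_bound=True, site_selection=select(top, "residue 3 heavy atoms")
        )
        assert bound_fraction_near(traj, lig, 3, cfg) == 1.0

    def test_planted_bound_fraction(self, wide_system):
        # 40 frames posed near residue 3, 10 near residue 2, 50 unbound.
        # Site = residues 2+3 with a wide bound cutoff, so both poses count
        # as bound; contact with residue 3 then holds in 40 of 50 bound frames.
        traj = self._traj_with_bound_schedule(wide_system, 40, 10, 50)
        top = wide_system.topology
        lig = select(top, "ligand heavy atoms")
        site = select(top, "residues 2,3 heavy atoms")
        cfg = OccupancyConfig(
            cutoff=25.0, condition_on_bound=True, site_selection=site
        )
        from k2pva.occupancy import bound_frame_mask

        mask = bound_frame_mask(traj, lig, cfg)
        assert mask.sum() == 50
        near3 = []
        for f in np.where(mask)[0]:
            sub = Trajectory(top, traj.coordinates[[f]], 1.0)
            near3.append(residue_occupancy(sub, lig, [3]).fraction("LEU3"))
        assert np.mean(near3) == pytest.approx(40 / 50, abs=0)

    def test_no_bound_frames_is_an_error(self, wide_system):
        traj = self._traj_with_bound_schedule(wide_system, 0, 0, 10)
        top = wide_system.topology
        lig = select(top, "ligand heavy atoms")
        cfg = OccupancyConfig(
            condition_on_bound=True, site_selection=select(top, "residue 3 heavy atoms")
        )
        with pytest.raises(ValueError, match="no bound frames"):
            residue_occupancy(traj, lig, [3], cfg)


class TestSiteResidence:
    def _escape_traj(self, system, escape_frame, n_frames, blip=None):
        top = system.topology
        near = place_ligand_at_distance(top, system.coordinates, 3, 3.0)
        far = near.copy()
        idx = top.indices_of(select(top, "ligand heavy atoms").atom_ids)
        far[idx] += 200.0
        frames = np.repeat(near[None], n_frames, axis=0)
        frames[escape_frame:] = far
        if blip is not None:
            frames[blip] = far
        return Trajectory(top, frames, frame_interval=2.0)

    def test_planted_escape_frame_reported(self, wide_system):
        traj = self._escape_traj(wide_system, 180, 250)
        top = wide_system.topology
        res = site_residence(
            traj,
            select(top, "ligand heavy atoms"),
            select(top, "residue 3 heavy atoms"),
        )
        assert res.escaped
        assert res.frame == 180
        assert res.time_ps == 360.0  # frame x 2 ps

    def test_never_escapes_sentinel(self, wide_system):
        traj = self._escape_traj(wide_system, 250, 250)  # escape beyond end
        top = wide_system.topology
        res = site_residence(
            traj,
            select(top, "ligand heavy atoms"),
            select(top, "residue 3 heavy atoms"),
        )
        assert res is NO_ESCAPE
        assert not res
        assert res.frame is None  # distinct from frame 0

    def test_single_frame_blip_not_an_escape(self, wide_system):
        traj = self._escape_traj(wide_system, 240, 250, blip=100)
        top = wide_system.topology
        res = site_residence(
            traj,
            select(top, "ligand heavy atoms"),
            select(top, "residue 3 heavy atoms"),
            persistence_window=10,
        )
        assert res.escaped
        assert res.frame == 240  # not 100

    def test_unbound_start_rejected(self, wide_system):
        top = wide_system.topology
        far = wide_system.coordinates.copy()
        idx = top.indices_of(select(top, "ligand heavy atoms").atom_ids)
        far[idx] += 200.0
        traj = Trajectory(top, np.repeat(far[None], 20, axis=0), 1.0)
        with pytest.raises(ValueError, match="not bound"):
            site_residence(
                traj,
                select(top, "ligand heavy atoms"),
                select(top, "residue 3 heavy atoms"),
            )
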