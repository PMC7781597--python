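"""Synthetic systems with planted ground truth.

Real inputs to this toolkit are MD trajectories of a K2P channel with a
bound volatile anesthetic, and TEVC recordings from oocytes — neither of
which can be regenerated on demand.  This module builds small protein-like
systems and noisy dose-response curves whose relevant properties (contact
probabilities, stacking episodes, rotamer targets, escape frames, Hill
parameters) are planted exactly and emitted as serializable ground truth,
so every analysis stage can be validated against a known answer.

Generated topologies use standard residue and atom names (N, CA, CB, CG,
Phe ring templates), so selections, chi1 dihedrals and ring geometry work
unmodified.  All generators are deterministic given their seed; there is
no physical force field and no dynamics — geometry is posed, not
simulated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .ephys import (
    DoseResponseCurve,
    hill_activation,
    ph_inhibition_difference,
    ph_inhibition_printed,
)
from .trajmodel import Atom, Selection, Topology, Trajectory, select

__all__ = [
    "GroundTruth",
    "ToySystem",
    "place_atom",
    "make_toy_system",
    "place_ligand_at_distance",
    "simulate_ligand_walk",
    "plant_stacking",
    "simulate_dose_response",
]


@dataclass
class GroundTruth:
    """Planted facts about a generated dataset, serializable to JSON."""

    seed: int
    n_frames: int | None = None
    cutoff: float | None = None
    contact_probs: dict[int, float] | None = None
    realized_contacts: dict[int, int] | None = None
    escape_frame: int | None = None
    stacking_schedule: list[tuple[int, int]] | None = None
    chi1_targets: dict[int, float] | None = None
    dose_model: str | None = None
    dose_params: dict[str, float] | None = None
    noise_sd: float | None = None

    def to_json(self, path: str | Path) -> None:
        def _clean(obj):
            if isinstance(obj, dict):
                return {str(k): _clean(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_clean(v) for v in obj]
            if isinstance(obj, (np.integer,)):
                return int(obj)
            if isinstance(obj, (np.floating,)):
                return float(obj)
            return obj

        Path(path).write_text(
            json.dumps(_clean(dataclasses.asdict(self)), indent=2) + "\n"
        )


@dataclass
class ToySystem:
    """A generated topology with its reference-frame coordinates."""

    topology: Topology
    coordinates: np.ndarray  # (n_atoms, 3), Å
    chi1_targets: dict[int, float]

    def selection(self, spec: str) -> Selection:
        return select(self.topology, spec)


# ---------------------------------------------------------------------------
# Internal-coordinate construction
# ---------------------------------------------------------------------------

def place_atom(a, b, c, bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Position atom d such that |cd| = bond, angle(b,c,d) = angle and
    dihedral(a,b,c,d) = dihedral (NeRF construction)."""
    a, b, c = (np.asarray(v, float) for v in (a, b, c))
    theta = np.radians(angle_deg)
    # sign convention matched to the IUPAC torsion measured by
    # structdev.dihedral (right-handed, viewed from b towards c)
    phi = -np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(theta), np.sin(theta) * np.cos(phi), np.sin(theta) * np.sin(phi)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


_PHE_RING_RADIUS = 1.39  # Å, benzene C-C bond == circumradius of the hexagon


def _build_residue(
    kind: str, ca: np.ndarray, axes: np.ndarray, chi1: float
) -> dict[str, np.ndarray]:
    """Backbone + side chain atoms of one residue in a rotated local frame.

    ``axes`` is a 3x3 rotation applied to the canonical local geometry, so
    residues along the chain are not all identically oriented.  Internal
    torsions (notably chi1) are rotation-invariant, so the construction
    target survives.
    """
    ex, ey, _ez = axes

    def g(v):  # local -> global
        return ca + v @ axes

    atoms: dict[str, np.ndarray] = {}
    atoms["N"] = g(np.array([-1.458, 0.0, 0.0]))
    atoms["CA"] = ca.copy()
    # C direction makes the canonical ~111 deg N-CA-C angle, in-plane
    ang = np.radians(180.0 - 111.0)
    atoms["C"] = g(1.525 * np.array([np.cos(ang), np.sin(ang), 0.0]))
    atoms["O"] = place_atom(atoms["N"], atoms["CA"], atoms["C"], 1.23, 121.0, 180.0)
    if kind == "GLY":
        return atoms
    atoms["CB"] = place_atom(atoms["C"], atoms["N"], atoms["CA"], 1.53, 110.5, 122.5)
    if kind == "ALA":
        return atoms
    gamma = place_atom(atoms["N"], atoms["CA"], atoms["CB"], 1.52, 114.0, chi1)
    if kind in ("PHE", "TYR"):
        atoms["CG"] = gamma
        u = gamma - atoms["CB"]
        u /= np.linalg.norm(u)
        w = atoms["CA"] - atoms["CB"]
        v = w - np.dot(w, u) * u
        if np.linalg.norm(v) < 1e-8:
            v = np.cross(u, np.array([0.0, 0.0, 1.0]))
        v /= np.linalg.norm(v)
        center = gamma + _PHE_RING_RADIUS * u
        names_angles = [
            ("CD1", 120.0), ("CE1", 60.0), ("CZ", 0.0),
            ("CE2", -60.0), ("CD2", -120.0),
        ]
        for name, th in names_angles:
            th_r = np.radians(th)
            atoms[name] = center + _PHE_RING_RADIUS * (np.cos(th_r) * u + np.sin(th_r) * v)
        # CG sits at angle 180 on the same circle: center - radius*u == gamma
    else:  # LEU-like generic side chain
        atoms["CG"] = gamma
        atoms["CD1"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 1.52, 112.0, 60.0)
        atoms["CD2"] = place_atom(atoms["CA"], atoms["CB"], atoms["CG"], 1.52, 112.0, -60.0)
    return atoms


def _rotation_matrix(rng: np.random.Generator, max_angle_deg: float = 25.0) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    ang = np.radians(rng.uniform(-max_angle_deg, max_angle_deg))
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)


_LIGAND_TEMPLATE = {
    # a small isoflurane-like rigid body: three heavy atoms
    "C1": np.array([-0.8, 0.0, 0.0]),
    "O1": np.array([0.0, 0.7, 0.0]),
    "C2": np.array([0.8, 0.0, 0.0]),
}


def make_toy_system(
    n_residues: int = 5,
    ring_residues: tuple[int, ...] = (),
    seed: int = 0,
    spacing: float = 6.0,
    chi1_targets: dict[int, float] | None = None,
    include_ligand: bool = True,
    ligand_start: np.ndarray | None = None,
) -> ToySystem:
    """Build a deterministic toy protein with optional Phe rings and ligand.

    Residues are placed with Cα positions ``spacing`` Å apart along x with
    seeded jitter and per-residue orientation noise.  ``ring_residues``
    become PHE (full six-carbon ring); all others are LEU-like.
    ``chi1_targets`` plants exact chi1 torsions (degrees) per residue;
    unlisted residues default to 180°.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    rng = np.random.default_rng(seed)
    chi1_targets = dict(chi1_targets or {})
    ring_set = set(ring_residues)
    for r in ring_set:
        if not 1 <= r <= n_residues:
            raise ValueError(f"ring residue {r} outside 1..{n_residues}")

    atoms: list[Atom] = []
    coords: list[np.ndarray] = []
    planted_chi1: dict[int, float] = {}
    atom_id = 0
    for i in range(1, n_residues + 1):
        kind = "PHE" if i in ring_set else "LEU"
        chi1 = float(chi1_targets.get(i, 180.0))
        planted_chi1[i] = chi1
        ca = np.array([spacing * (i - 1), 0.0, 0.0]) + rng.normal(scale=0.2, size=3)
        axes = _rotation_matrix(rng)
        res_atoms = _build_residue(kind, ca, axes, chi1)
        for name, xyz in res_atoms.items():
            atom_id += 1
            atoms.append(
                Atom(
                    atom_id=atom_id,
                    name=name,
                    element=name[0],
                    residue_index=i,
                    residue_name=kind,
                    chain_id="A",
                )
            )
            coords.append(xyz)

    if include_ligand:
        start = (
            np.asarray(ligand_start, float)
            if ligand_start is not None
            else np.array([spacing * (n_residues - 1) / 2.0, 12.0, 0.0])
        )
        for name, offset in _LIGAND_TEMPLATE.items():
            atom_id += 1
            atoms.append(
                Atom(
                    atom_id=atom_id,
                    name=name,
                    element=name[0],
                    residue_index=n_residues + 1,
                    residue_name="ISO",
                    chain_id="L",
                    is_hetero=True,
                )
            )
            coords.append(start + offset)

    return ToySystem(
        topology=Topology(atoms),
        coordinates=np.array(coords),
        chi1_targets=planted_chi1,
    )


# ---------------------------------------------------------------------------
# Ligand placement and contact walks
# ---------------------------------------------------------------------------

def _ligand_indices(topology: Topology) -> np.ndarray:
    ids = [i for r in topology.ligand_residues for i in r.atom_ids]
    if not ids:
        raise ValueError("topology has no ligand residue")
    return topology.indices_of(ids)


def _residue_heavy_xyz(topology: Topology, coords: np.ndarray, residue_index: int) -> np.ndarray:
    res = topology.residue(residue_index)
    return coords[topology.indices_of(topology.heavy_atom_ids(res))]


def place_ligand_at_distance(
    topology: Topology,
    coords: np.ndarray,
    residue_index: int,
    distance: float,
    direction: np.ndarray | None = None,
) -> np.ndarray:
    """Return a copy of ``coords`` with the ligand rigidly translated so its
    minimum heavy-atom distance to ``residue_index`` equals ``distance``.

    The ligand is moved along ``direction`` (default: outward from the
    protein through the residue centroid); the min-distance is monotone in
    that shift, so a few fixed-point corrections converge far below the
    contact margins used by the generators.
    """
    coords = np.array(coords, dtype=float)
    lig_idx = _ligand_indices(topology)
    res_xyz = _residue_heavy_xyz(topology, coords, residue_index)
    res_c = res_xyz.mean(axis=0)
    prot_idx = topology.indices_of(
        [i for r in topology.protein_residues for i in r.atom_ids]
    )
    prot_c = coords[prot_idx].mean(axis=0)
    if direction is None:
        direction = res_c - prot_c
        if np.linalg.norm(direction) < 1e-6:
            direction = np.array([0.0, 1.0, 0.0])
    d = np.asarray(direction, float)
    d /= np.linalg.norm(d)

    lig = coords[lig_idx]
    lig = lig - lig.mean(axis=0) + res_c + d * (distance + 3.0)
    for _ in range(8):
        dist_now = np.sqrt(
            ((lig[:, None, :] - res_xyz[None, :, :]) ** 2).sum(-1)
        ).min()
        err = dist_now - distance
        if abs(err) < 1e-9:
            break
        lig = lig - err * d
    coords[lig_idx] = lig
    return coords


def _place_far(topology: Topology, coords: np.ndarray, offset: float = 80.0) -> np.ndarray:
    coords = np.array(coords, dtype=float)
    lig_idx = _ligand_indices(topology)
    lig = coords[lig_idx]
    coords[lig_idx] = lig - lig.mean(axis=0) + np.array([0.0, offset, offset])
    return coords


def simulate_ligand_walk(
    system: ToySystem,
    contact_probs: dict[int, float],
    n_frames: int = 1000,
    cutoff: float = 7.0,
    margin: float = 0.3,
    escape_frame: int | None = None,
    seed: int = 0,
    frame_interval: float = 1.0,
) -> tuple[Trajectory, GroundTruth]:
    """Pose the ligand frame by frame according to planted contact draws.

    Per frame at most one monitored residue is contacted (the per-residue
    Bernoulli draws are realised as one categorical draw, so the planted
    probabilities must sum to <= 1; contacting several residues of a
    well-separated toy system simultaneously is geometrically infeasible
    and is rejected with the conflicting residues named).  Contact frames
    place the ligand inside the residue's cutoff shell with ``margin`` to
    spare; non-contact frames place it far from everything.  From
    ``escape_frame`` on, the ligand stays outside the site permanently.

    Returns the trajectory and a :class:`GroundTruth` with the realised
    per-residue contact counts.
    """
    top = system.topology
    probs = {int(k): float(v) for k, v in contact_probs.items()}
    if any(p < 0 or p > 1 for p in probs.values()):
        raise ValueError("contact probabilities must be in [0, 1]")
    if sum(probs.values()) > 1.0 + 1e-12:
        raise ValueError(
            "infeasible simultaneous constraints: planted contact "
            f"probabilities for residues {sorted(probs)} sum to "
            f"{sum(probs.values()):.3f} > 1; the toy ligand can contact at "
            "most one residue per frame"
        )
    rng = np.random.default_rng(seed)
    residues = sorted(probs)
    edges = np.cumsum([probs[r] for r in residues])

    frames = np.empty((n_frames, top.n_atoms, 3))
    realized = {r: 0 for r in residues}
    for f in range(n_frames):
        if escape_frame is not None and f >= escape_frame:
            frames[f] = _place_far(top, system.coordinates)
            continue
        u = rng.random()
        hit = None
        for r, edge in zip(residues, edges):
            if u < edge:
                hit = r
                break
        if hit is None:
            frames[f] = _place_far(top, system.coordinates)
        else:
            dist = rng.uniform(3.0, cutoff - margin)
            frames[f] = place_ligand_at_distance(top, system.coordinates, hit, dist)
            realized[hit] += 1
            # verify the pose does not accidentally contact other residues
            conflicts = []
            for other in residues:
                if other == hit:
                    continue
                oxyz = _residue_heavy_xyz(top, frames[f], other)
                lxyz = frames[f][_ligand_indices(top)]
                dmin = np.sqrt(((lxyz[:, None] - oxyz[None]) ** 2).sum(-1)).min()
                if dmin <= cutoff + margin:
                    conflicts.append(other)
            if conflicts:
                raise ValueError(
                    "infeasible simultaneous constraints: contacting residue "
                    f"{hit} also places the ligand within the cutoff shell of "
                    f"residues {conflicts}; increase the toy-system spacing"
                )
    traj = Trajectory(top, frames, frame_interval=frame_interval)
    gt = GroundTruth(
        seed=seed,
        n_frames=n_frames,
        cutoff=cutoff,
        contact_probs=probs,
        realized_contacts=realized,
        escape_frame=escape_frame,
    )
    return traj, gt


# ---------------------------------------------------------------------------
# Stacking schedules
# ---------------------------------------------------------------------------

def _hexagon(center: np.ndarray, normal: np.ndarray, seed_dir: np.ndarray) -> np.ndarray:
    n = normal / np.linalg.norm(normal)
    u = seed_dir - np.dot(seed_dir, n) * n
    if np.linalg.norm(u) < 1e-8:
        u = np.cross(n, np.array([1.0, 0.0, 0.0]))
        if np.linalg.norm(u) < 1e-8:
            u = np.cross(n, np.array([0.0, 1.0, 0.0]))
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    out = np.empty((6, 3))
    for k in range(6):
        th = np.radians(60.0 * k)
        out[k] = center + _PHE_RING_RADIUS * (np.cos(th) * u + np.sin(th) * v)
    return out


def plant_stacking(
    system: ToySystem,
    ring_a_residue: int,
    ring_b_residue: int,
    schedule: list[tuple[int, int]],
    n_frames: int,
    frame_interval: float = 1.0,
    stacked_distance: float = 3.5,
    unstacked_distance: float = 6.0,
    unstacked_angle: float = 60.0,
) -> tuple[Trajectory, GroundTruth]:
    """Pose ring B relative to ring A per a stacked/unstacked schedule.

    ``schedule`` lists half-open stacked intervals ``(start, end)`` in
    frames.  Within them ring B is parallel to ring A at
    ``stacked_distance`` (satisfying the stacking criterion with margin);
    outside, it sits at ``unstacked_distance`` tilted by
    ``unstacked_angle`` degrees (violating it with margin).  Overlapping
    intervals are rejected.
    """
    from .pistacking import ring_geometry

    intervals = sorted((int(s), int(e)) for s, e in schedule)
    for s, e in intervals:
        if not 0 <= s < e <= n_frames:
            raise ValueError(f"schedule interval ({s}, {e}) outside 0..{n_frames}")
    for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
        if s2 < e1:
            raise ValueError(
                f"overlapping schedule intervals ({s1},{e1}) and ({s2},{e2})"
            )

    top = system.topology
    sel_a = select(top, f"ring atoms of residue {ring_a_residue}")
    sel_b = select(top, f"ring atoms of residue {ring_b_residue}")
    idx_b = top.indices_of(sel_b.atom_ids)
    xyz_a = system.coordinates[top.indices_of(sel_a.atom_ids)]
    cen_a, norm_a = ring_geometry(xyz_a)
    seed_dir = xyz_a[0] - cen_a

    stacked_mask = np.zeros(n_frames, dtype=bool)
    for s, e in intervals:
        stacked_mask[s:e] = True

    # tilt axis within ring A's plane for the unstacked pose
    tilt_axis = seed_dir / np.linalg.norm(seed_dir)
    ang = np.radians(unstacked_angle)
    K = np.array([
        [0, -tilt_axis[2], tilt_axis[1]],
        [tilt_axis[2], 0, -tilt_axis[0]],
        [-tilt_axis[1], tilt_axis[0], 0],
    ])
    R_tilt = np.eye(3) + np.sin(ang) * K + (1 - np.cos(ang)) * (K @ K)

    frames = np.repeat(system.coordinates[None, :, :], n_frames, axis=0)
    ring_stacked = _hexagon(cen_a + stacked_distance * norm_a, norm_a, seed_dir)
    ring_unstacked = _hexagon(
        cen_a + unstacked_distance * norm_a, R_tilt @ norm_a, seed_dir
    )
    for f in range(n_frames):
        frames[f, idx_b] = ring_stacked if stacked_mask[f] else ring_unstacked

    traj = Trajectory(top, frames, frame_interval=frame_interval)
    gt = GroundTruth(
        seed=0, n_frames=n_frames, stacking_schedule=intervals
    )
    return traj, gt


# ---------------------------------------------------------------------------
# Dose-response generation
# ---------------------------------------------------------------------------

_DOSE_MODELS = {
    "hill-activation": hill_activation,
    "ph-printed-ratio": ph_inhibition_printed,
    "ph-difference": ph_inhibition_difference,
}


def simulate_dose_response(
    model: str,
    params: dict[str, float],
    x_values: np.ndarray,
    replicates: int = 1,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[DoseResponseCurve, GroundTruth]:
    """Generate noisy dose-response data from a known Hill model.

    ``params`` must provide i_min, i_max, midpoint and h.  Gaussian noise
    of standard deviation ``noise_sd`` (response units) is added per
    observation, seeded.
    """
    if model not in _DOSE_MODELS:
        raise ValueError(f"model must be one of {sorted(_DOSE_MODELS)}")
    fn = _DOSE_MODELS[model]
    needed = ("i_min", "i_max", "midpoint", "h")
    missing = [k for k in needed if k not in params]
    if missing:
        raise ValueError(f"params missing {missing}")
    rng = np.random.default_rng(seed)
    x = np.asarray(x_values, dtype=float)
    rows = []
    for rep in range(replicates):
        clean = fn(x, params["i_min"], params["i_max"], params["midpoint"], params["h"])
        noisy = clean + rng.normal(scale=noise_sd, size=x.shape)
        for xi, yi in zip(x, noisy):
            rows.append({"x": xi, "response": yi, "replicate": rep})
    import pandas as pd

    curve = DoseResponseCurve(
        pd.DataFrame(rows),
        x_kind="pH" if model.startswith("ph") else "concentration_uM",
    )
    gt = GroundTruth(
        seed=seed,
        dose_model=model,
        dose_params={k: float(params[k]) for k in needed},
        noise_sd=noise_sd,
    )
    return curve, gt
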