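"""Structural deviation analyses: superposition, per-residue RMSD, and
side-chain chi1 dihedral residence.

Frames are first superposed onto a reference using only an alignment
selection (for TREK1, all heavy atoms of the selectivity-filter residues
I143/F145/N147); the optimal rigid transform is then applied to every atom.
Per-residue RMSD against the reference isolates local rearrangements (e.g.
within a ligand-binding pocket) from global tumbling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajmodel import Selection, Trajectory

__all__ = [
    "AlignmentReference",
    "RMSDProfile",
    "DihedralSeries",
    "kabsch",
    "superpose",
    "per_residue_rmsd",
    "dihedral",
    "chi1_series",
    "rotamer_residence",
    "CHI1_GAMMA_ATOM",
]

#: chi1 is the N-CA-CB-G torsion; the gamma heavy atom varies by residue type.
CHI1_GAMMA_ATOM: dict[str, str] = {
    "ARG": "CG", "ASN": "CG", "ASP": "CG", "GLN": "CG", "GLU": "CG",
    "HIS": "CG", "LEU": "CG", "LYS": "CG", "MET": "CG", "PHE": "CG",
    "PRO": "CG", "TRP": "CG", "TYR": "CG",
    "ILE": "CG1", "VAL": "CG1", "THR": "OG1", "SER": "OG", "CYS": "SG",
}


@dataclass
class AlignmentReference:
    """A reference frame plus the selection used for superposition."""

    coordinates: np.ndarray  # (n_atoms, 3), Å
    alignment: Selection

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("reference coordinates must be (n_atoms, 3)")


@dataclass
class RMSDProfile:
    """Per-residue RMSD against the reference.

    ``per_frame`` maps residue label -> (n_frames,) series; ``mean`` is the
    trajectory average and ``final`` the last-frame value.
    """

    mode: str
    residue_labels: list[str]
    per_frame: dict[str, np.ndarray]

    @property
    def mean(self) -> pd.Series:
        return pd.Series({r: float(self.per_frame[r].mean()) for r in self.residue_labels})

    @property
    def final(self) -> pd.Series:
        return pd.Series({r: float(self.per_frame[r][-1]) for r in self.residue_labels})

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "residue": self.residue_labels,
            "mean_rmsd_A": [self.mean[r] for r in self.residue_labels],
        })
        df.to_csv(path, index=False)


@dataclass
class DihedralSeries:
    """Per-frame chi1 angles in degrees, wrapped to (-180, 180]."""

    residue_label: str
    angles_deg: np.ndarray

    def __len__(self) -> int:
        return len(self.angles_deg)


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares rigid transform (R, t) minimising |R @ mobile + t - target|.

    Uses the SVD solution with determinant correction so that R is a proper
    rotation.  Degenerate (collinear or <3 point) sets are rejected.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be matching (n, 3) arrays")
    if P.shape[0] < 3:
        raise ValueError("superposition requires >= 3 alignment atoms")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - pc, Q - qc
    s = np.linalg.svd(P0, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("alignment atoms are collinear; rotation underdetermined")
    H = P0.T @ Q0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    return R, t


def superpose(
    frame: np.ndarray, ref: AlignmentReference, topology=None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Superpose one frame onto the reference over the alignment selection.

    Returns ``(R, t, transformed_frame)``; the transform is fit on the
    alignment atoms only and applied to all atoms.
    """
    frame = np.asarray(frame, float)
    if frame.shape != ref.coordinates.shape:
        raise ValueError("frame and reference must have identical shapes")
    if topology is None:
        raise ValueError("superpose requires the topology to resolve the alignment selection")
    idx = topology.indices_of(ref.alignment.atom_ids)
    R, t = kabsch(frame[idx], ref.coordinates[idx])
    return R, t, frame @ R.T + t


def superpose_trajectory(traj: Trajectory, ref: AlignmentReference) -> Trajectory:
    """Apply :func:`superpose` to every frame, returning a new Trajectory."""
    out = np.empty_like(traj.coordinates)
    for f in range(traj.n_frames):
        _R, _t, out[f] = superpose(traj.coordinates[f], ref, traj.topology)
    return Trajectory(traj.topology, out, frame_interval=traj.frame_interval)


# ---------------------------------------------------------------------------
# Per-residue RMSD
# ---------------------------------------------------------------------------

def per_residue_rmsd(
    traj: Trajectory,
    ref: AlignmentReference,
    mode: str = "all-atom",
    residues: list[int] | None = None,
) -> RMSDProfile:
    """Per-residue RMSD against the reference after superposition.

    mode : "all-atom" uses every atom of the residue; "ca-only" uses the
        Cα atom alone (so it reports backbone displacement and is blind to
        side-chain rotamer changes).
    Residues lacking the mode's atoms are excluded with a warning.
    """
    if mode not in ("all-atom", "ca-only"):
        raise ValueError("mode must be 'all-atom' or 'ca-only'")
    top = traj.topology
    if residues is None:
        residues = [r.residue_index for r in top.protein_residues]
    by_id = {a.atom_id: a for a in top.atoms}

    aligned = superpose_trajectory(traj, ref)
    labels: list[str] = []
    per_frame: dict[str, np.ndarray] = {}
    for idx in residues:
        res = top.residue(idx)
        if mode == "ca-only":
            ids = [i for i in res.atom_ids if by_id[i].name.upper() == "CA"]
        else:
            ids = list(res.atom_ids)
        if not ids:
            warnings.warn(f"residue {res.label} has no atoms for mode {mode!r}; excluded")
            continue
        cols = top.indices_of(ids)
        diff = aligned.coordinates[:, cols, :] - ref.coordinates[cols, :]
        rmsd = np.sqrt((diff**2).sum(axis=-1).mean(axis=-1))
        labels.append(res.label)
        per_frame[res.label] = rmsd
    return RMSDProfile(mode=mode, residue_labels=labels, per_frame=per_frame)


# ---------------------------------------------------------------------------
# chi1 dihedrals and rotamer residence
# ---------------------------------------------------------------------------

def dihedral(p0, p1, p2, p3) -> float:
    """Signed torsion angle p0-p1-p2-p3 in degrees, IUPAC convention,
    wrapped to (-180, 180]."""
    b0 = np.asarray(p1, float) - np.asarray(p0, float)
    b1 = np.asarray(p2, float) - np.asarray(p1, float)
    b2 = np.asarray(p3, float) - np.asarray(p2, float)
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    m1 = np.cross(n1, b1 / np.linalg.norm(b1))
    x = float(np.dot(n1, n2))
    y = float(np.dot(m1, n2))
    ang = np.degrees(np.arctan2(y, x))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def chi1_series(traj: Trajectory, residue_index: int) -> DihedralSeries:
    """chi1 (N-CA-CB-gamma) torsion per frame for one residue.

    Glycine and alanine have no chi1 and are rejected by name.
    """
    res = traj.topology.residue(residue_index)
    rname = res.residue_name.upper()
    if rname in ("GLY", "ALA"):
        raise ValueError(f"residue {res.label} ({rname}) has no chi1 dihedral")
    gamma = CHI1_GAMMA_ATOM.get(rname, "CG")
    by_id = {a.atom_id: a for a in traj.topology.atoms}
    name_to_id = {by_id[i].name.upper(): i for i in res.atom_ids}
    needed = ["N", "CA", "CB", gamma]
    missing = [n for n in needed if n not in name_to_id]
    if missing:
        raise ValueError(f"residue {res.label} is missing atoms {missing} for chi1")
    cols = traj.topology.indices_of([name_to_id[n] for n in needed])
    xyz = traj.coordinates[:, cols, :]
    angles = np.fromiter(
        (dihedral(*xyz[f]) for f in range(traj.n_frames)),
        dtype=float,
        count=traj.n_frames,
    )
    return DihedralSeries(residue_label=res.label, angles_deg=angles)


#: Rotameric thirds of the chi1 circle, centred at -60 (gauche-), 180
#: (trans) and +60 (gauche+).
DEFAULT_ROTAMER_BINS = {
    "gauche-": (-120.0, 0.0),
    "gauche+": (0.0, 120.0),
    "trans": (120.0, -120.0),  # wraps through 180
}


def rotamer_residence(
    series: DihedralSeries,
    bins: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Fraction of frames in each rotameric chi1 bin.

    Bins are half-open ``[lo, hi)`` arcs on the dihedral circle; a bin with
    ``lo > hi`` wraps through 180°, so angles near +180 and -180 land in a
    single bin.  Default bins are the gauche-/trans/gauche+ thirds.
    """
    if len(series.angles_deg) == 0:
        raise ValueError("empty dihedral series")
    bins = bins or DEFAULT_ROTAMER_BINS
    ang = np.mod(series.angles_deg + 180.0, 360.0) - 180.0
    ang[ang == -180.0] = 180.0  # keep the (-180, 180] convention
    out: dict[str, float] = {}
    for name, (lo, hi) in bins.items():
        if lo <= hi:
            mask = (ang >= lo) & (ang < hi)
        else:  # wrap-around arc
            mask = (ang >= lo) | (ang < hi)
        out[name] = float(mask.mean())
    return out
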