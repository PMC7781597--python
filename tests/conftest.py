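"""Shared fixtures: toy PDB text, generated systems, and rigid-motion helpers."""

from __future__ import annotations

import numpy as np
import pytest

from k2pva import synthgen
from k2pva.trajmodel import Trajectory


def rotation_matrix(axis, angle_rad) -> np.ndarray:
    axis = np.asarray(axis, float)
    axis = axis / np.linalg.norm(axis)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def rigid_move(coords: np.ndarray, seed: int = 0) -> np.ndarray:
    """Apply a seeded random rotation + translation to (..., 3) coordinates."""
    rng = np.random.default_rng(seed)
    R = rotation_matrix(rng.normal(size=3), rng.uniform(0.1, 3.0))
    t = rng.uniform(-20, 20, size=3)
    return coords @ R.T + t


TOY_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.919   6.898  -5.040  1.00  0.00           C
ATOM      4  HB1 ALA A   1      13.650   6.500  -5.750  1.00  0.00           H
ATOM      5  C   ALA A   1      10.601   6.588  -4.150  1.00  0.00           C
ATOM      6  N   GLY A   2       9.963   7.715  -4.470  1.00  0.00           N
ATOM      7  CA  GLY A   2       8.940   8.295  -3.610  1.00  0.00           C
ATOM      8  C   GLY A   2       7.580   7.610  -3.720  1.00  0.00           C
ATOM      9  N   SER B   3       6.870   7.950  -4.790  1.00  0.00           N
ATOM     10  CA  SER B   3       5.550   7.380  -5.030  1.00  0.00           C
ATOM     11  OG  SER B   3       4.650   8.400  -5.450  1.00  0.00           O
HETATM   12  C1  ISO L   4       2.000   2.000   2.000  1.00  0.00           C
HETATM   13  O1  ISO L   4       2.800   2.700   2.000  1.00  0.00           O
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    p = tmp_path / "toy.pdb"
    p.write_text(TOY_PDB)
    return p


@pytest.fixture
def phe_system():
    """Five-residue toy with Phe rings at positions 2 and 4 and a ligand."""
    return synthgen.make_toy_system(
        n_residues=5, ring_residues=(2, 4), seed=11,
        chi1_targets={2: -65.0, 4: 175.0},
    )


@pytest.fixture
def wide_system():
    """Well-separated residues (25 Å spacing) for contact-walk tests."""
    return synthgen.make_toy_system(n_residues=5, seed=7, spacing=25.0)


@pytest.fixture
def one_frame_traj(phe_system):
    return Trajectory(phe_system.topology, phe_system.coordinates[None], 1.0)
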