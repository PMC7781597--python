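"""Core data model for molecular systems and trajectories.

Defines :class:`Topology`, :class:`Trajectory` and :class:`Selection` — the
containers every downstream analysis stage consumes — together with readers
and writers for PDB topologies and DCD/XTC coordinate trajectories.

Conventions
-----------
* Coordinates are always stored in angstroms (Å); trajectory formats that
  store nanometres (XTC) are converted on read and write.
* Residue numbering follows the numbering of the input PDB file; no
  renumbering is ever applied, so a residue referred to in the literature as
  "G182" is addressed here as residue 182.
* Distance-based statistics operate on heavy atoms (element != H) unless an
  operation explicitly says otherwise: hydrogen placement is force-field
  dependent and the contact analyses are defined on residue proximity.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Topology",
    "Trajectory",
    "Selection",
    "load_topology",
    "write_topology",
    "load_trajectory",
    "write_trajectory",
    "select",
    "RING_ATOM_NAMES",
]

#: Ring heavy-atom names per aromatic residue type.  Phe/Tyr carry the
#: six-membered benzene ring used in the F185/F214 stacking analysis.
RING_ATOM_NAMES: dict[str, tuple[str, ...]] = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
}


@dataclass(frozen=True)
class Atom:
    """A single atom record, in file order."""

    atom_id: int
    name: str
    element: str
    residue_index: int
    residue_name: str
    chain_id: str
    is_hetero: bool = False

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"


@dataclass(frozen=True)
class Residue:
    """A residue: contiguous run of atoms sharing (index, name, chain)."""

    residue_index: int
    residue_name: str
    chain_id: str
    atom_ids: tuple[int, ...]
    is_ligand: bool = False

    @property
    def label(self) -> str:
        return f"{self.residue_name}{self.residue_index}"


class Topology:
    """Ordered atom list plus the residue partition derived from it.

    Parameters
    ----------
    atoms : sequence of Atom
        Atoms in file order.  ``atom_id`` values must be unique.
    """

    def __init__(self, atoms: Sequence[Atom]):
        atoms = tuple(atoms)
        if not atoms:
            raise ValueError("Topology requires at least one atom")
        seen: set[int] = set()
        for a in atoms:
            if a.atom_id in seen:
                raise ValueError(f"duplicate atom id {a.atom_id}")
            seen.add(a.atom_id)
        self.atoms: tuple[Atom, ...] = atoms
        self._id_to_index = {a.atom_id: i for i, a in enumerate(atoms)}
        self.residues: tuple[Residue, ...] = self._build_residues(atoms)
        self._residue_by_key = {
            (r.chain_id, r.residue_index): r for r in self.residues
        }

    @staticmethod
    def _build_residues(atoms: Sequence[Atom]) -> tuple[Residue, ...]:
        residues: list[Residue] = []
        key = None
        bucket: list[Atom] = []
        for a in atoms:
            k = (a.chain_id, a.residue_index, a.residue_name)
            if k != key:
                if bucket:
                    residues.append(Topology._make_residue(bucket))
                key, bucket = k, []
            bucket.append(a)
        if bucket:
            residues.append(Topology._make_residue(bucket))
        return tuple(residues)

    @staticmethod
    def _make_residue(bucket: list[Atom]) -> Residue:
        a0 = bucket[0]
        return Residue(
            residue_index=a0.residue_index,
            residue_name=a0.residue_name,
            chain_id=a0.chain_id,
            atom_ids=tuple(a.atom_id for a in bucket),
            is_ligand=all(a.is_hetero for a in bucket),
        )

    # -- lookups ---------------------------------------------------------
    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def index_of(self, atom_id: int) -> int:
        """Position of ``atom_id`` in the coordinate array."""
        return self._id_to_index[atom_id]

    def indices_of(self, atom_ids: Iterable[int]) -> np.ndarray:
        return np.array([self._id_to_index[i] for i in atom_ids], dtype=np.intp)

    def residue(self, residue_index: int, chain_id: str | None = None) -> Residue:
        matches = [
            r
            for r in self.residues
            if r.residue_index == residue_index
            and (chain_id is None or r.chain_id == chain_id)
        ]
        if not matches:
            raise KeyError(f"no residue with index {residue_index}"
                           + (f" in chain {chain_id}" if chain_id else ""))
        if len(matches) > 1:
            raise KeyError(
                f"residue index {residue_index} is ambiguous across chains "
                f"{sorted(r.chain_id for r in matches)}; pass chain_id"
            )
        return matches[0]

    @property
    def protein_residues(self) -> tuple[Residue, ...]:
        return tuple(r for r in self.residues if not r.is_ligand)

    @property
    def ligand_residues(self) -> tuple[Residue, ...]:
        return tuple(r for r in self.residues if r.is_ligand)

    def heavy_atom_ids(self, residue: Residue) -> tuple[int, ...]:
        by_id = {a.atom_id: a for a in self.atoms}
        return tuple(i for i in residue.atom_ids if by_id[i].is_heavy)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Topology({self.n_atoms} atoms, {len(self.residues)} residues,"
                f" {len(self.ligand_residues)} ligand)")


@dataclass(frozen=True)
class Selection:
    """An ordered, non-empty set of atom ids with a provenance string."""

    atom_ids: tuple[int, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        if not self.atom_ids:
            raise ValueError(f"empty selection: {self.provenance!r}")
        if len(set(self.atom_ids)) != len(self.atom_ids):
            raise ValueError(f"selection has duplicate atom ids: {self.provenance!r}")

    def __len__(self) -> int:
        return len(self.atom_ids)


class Trajectory:
    """Topology plus a (frames, atoms, 3) coordinate array in Å.

    Parameters
    ----------
    topology : Topology
    coordinates : ndarray, shape (n_frames, n_atoms, 3), Å
    frame_interval : float
        Time between stored frames, in picoseconds.
    box : ndarray or None
        Optional per-frame box vectors, shape (n_frames, 3, 3), Å.
    """

    def __init__(
        self,
        topology: Topology,
        coordinates: np.ndarray,
        frame_interval: float = 1.0,
        box: np.ndarray | None = None,
    ):
        coords = np.asarray(coordinates, dtype=np.float64)
        if coords.ndim != 3 or coords.shape[2] != 3:
            raise ValueError(f"coordinates must be (frames, atoms, 3); got {coords.shape}")
        if coords.shape[1] != topology.n_atoms:
            raise ValueError(
                f"coordinate atom count {coords.shape[1]} does not match "
                f"topology atom count {topology.n_atoms}"
            )
        if not np.isfinite(coords).all():
            raise ValueError("coordinates contain non-finite values")
        if frame_interval <= 0:
            raise ValueError("frame_interval must be positive (ps)")
        self.topology = topology
        self.coordinates = coords
        self.frame_interval = float(frame_interval)
        self.box = None if box is None else np.asarray(box, dtype=np.float64)

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[1]

    @property
    def times_ps(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def subset_coords(self, sel: Selection) -> np.ndarray:
        """Coordinates of the selection, shape (n_frames, len(sel), 3)."""
        return self.coordinates[:, self.topology.indices_of(sel.atom_ids), :]

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (f"Trajectory({self.n_frames} frames x {self.n_atoms} atoms, "
                f"dt={self.frame_interval} ps)")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    if not name:
        return "X"
    # strip leading digits (e.g. 1HG1)
    stripped = name.lstrip("0123456789")
    if not stripped:
        return "X"
    first = stripped[0].upper()
    if first == "H":
        return "H"
    if len(stripped) >= 2 and stripped[:2].upper() in {"CL", "BR", "FE", "ZN", "MG", "NA"}:
        # only for het atoms with explicit two-letter names; protein atom
        # names like "CA" are carbon
        if name != stripped or name[0].isdigit():
            return stripped[:2].capitalize()
    return first


def load_topology(path: str | Path) -> Topology:
    """Parse a PDB file's ATOM/HETATM records into a :class:`Topology`.

    Only the first MODEL of a multi-model file is read (a warning is
    emitted).  HETATM records are flagged as ligand atoms.  Occupancy and
    B-factor columns are ignored.

    Raises
    ------
    FileNotFoundError
        If the file does not exist.
    ValueError
        If the file contains no atoms or a duplicate atom serial within a
        model (the message names the offending line number).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"topology file not found: {path}")
    atoms: list[Atom] = []
    seen_serials: set[int] = set()
    in_first_model = True
    n_models = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            rec = line[:6].strip()
            if rec == "MODEL":
                n_models += 1
                if n_models > 1:
                    in_first_model = False
            elif rec == "ENDMDL":
                if n_models >= 1:
                    in_first_model = False
            elif rec in ("ATOM", "HETATM") and in_first_model:
                try:
                    serial = int(line[6:11])
                    name = line[12:16].strip()
                    resname = line[17:20].strip() or line[17:21].strip()
                    chain = line[21].strip() or "A"
                    resseq = int(line[22:26])
                except ValueError as exc:
                    raise ValueError(f"malformed PDB record at line {lineno}: {exc}")
                if serial in seen_serials:
                    raise ValueError(
                        f"duplicate atom serial {serial} at line {lineno} of {path.name}"
                    )
                seen_serials.add(serial)
                element = line[76:78].strip() if len(line) >= 78 else ""
                if not element:
                    element = _guess_element(name)
                atoms.append(
                    Atom(
                        atom_id=serial,
                        name=name,
                        element=element.capitalize(),
                        residue_index=resseq,
                        residue_name=resname,
                        chain_id=chain,
                        is_hetero=(rec == "HETATM"),
                    )
                )
    if n_models > 1:
        warnings.warn(
            f"{path.name}: {n_models} models present; only the first was read",
            stacklevel=2,
        )
    if not atoms:
        raise ValueError(f"no ATOM/HETATM records found in {path}")
    return Topology(atoms)


def write_topology(topology: Topology, coords: np.ndarray, path: str | Path) -> None:
    """Write one frame as a PDB file (ATOM/HETATM records, Å)."""
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (topology.n_atoms, 3):
        raise ValueError("coords must be (n_atoms, 3) for one frame")
    with open(path, "w") as fh:
        for i, a in enumerate(topology.atoms):
            rec = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            x, y, z = coords[i]
            fh.write(
                f"{rec}{a.atom_id:>5d} {name:<4s} {a.residue_name:<3s} "
                f"{a.chain_id:1s}{a.residue_index:>4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}"
                f"          {a.element:>2s}\n"
            )
        fh.write("END\n")


# ---------------------------------------------------------------------------
# Trajectory I/O (DCD / XTC via mdtraj's low-level format readers)
# ---------------------------------------------------------------------------

_NM_TO_A = 10.0


def load_trajectory(
    topology: Topology, path: str | Path, frame_interval: float = 1.0
) -> Trajectory:
    """Read a DCD or XTC trajectory file into a :class:`Trajectory`.

    Coordinates are converted to Å on read (XTC stores nm).  The frame atom
    count must match the topology.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"trajectory file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path)) as fh:
            xyz, cell_lengths, cell_angles = fh.read()
        coords = np.asarray(xyz, dtype=np.float64)  # DCD stores Å
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path)) as fh:
            xyz, _time, _step, _box = fh.read()
        coords = np.asarray(xyz, dtype=np.float64) * _NM_TO_A
    else:
        raise ValueError(f"unsupported trajectory format: {suffix!r} (use .dcd or .xtc)")
    if coords.size == 0:
        raise ValueError(f"no readable frames in {path}")
    if coords.shape[1] != topology.n_atoms:
        raise ValueError(
            f"atom-count mismatch: trajectory has {coords.shape[1]} atoms per "
            f"frame, topology has {topology.n_atoms} (last readable frame: "
            f"{coords.shape[0] - 1})"
        )
    return Trajectory(topology, coords, frame_interval=frame_interval)


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """Write trajectory coordinates to DCD (Å) or XTC (nm) by extension."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".dcd":
        from mdtraj.formats import DCDTrajectoryFile

        with DCDTrajectoryFile(str(path), "w") as fh:
            fh.write(traj.coordinates.astype(np.float32))
    elif suffix == ".xtc":
        from mdtraj.formats import XTCTrajectoryFile

        with XTCTrajectoryFile(str(path), "w") as fh:
            fh.write((traj.coordinates / _NM_TO_A).astype(np.float32))
    else:
        raise ValueError(f"unsupported trajectory format: {suffix!r} (use .dcd or .xtc)")


# ---------------------------------------------------------------------------
# Selection language
# ---------------------------------------------------------------------------

_RES_LIST = r"(?P<residues>\d+(?:\s*,\s*\d+)*)"


def _parse_res_list(text: str) -> list[int]:
    return [int(tok) for tok in re.split(r"\s*,\s*", text.strip())]


def select(topology: Topology, spec: str) -> Selection:
    """Resolve a selection expression to an ordered atom-id set.

    Supported expressions (case-insensitive)::

        "ligand"                          all ligand (HETATM) atoms
        "ligand heavy atoms"              ligand heavy atoms
        "protein heavy atoms"             all protein heavy atoms
        "residue 182 heavy atoms"         heavy atoms of residue 182
        "residues 182,185 heavy atoms"    heavy atoms of several residues
        "residue 182 all atoms"           every atom of residue 182
        "ca of residues 143,145,147"      Cα atoms ("Cα" also accepted)
        "ring atoms of residue 185"       aromatic ring heavy atoms
        "ring atoms of PHE 185"           ring atoms, type-checked
        "all"                             every atom

    Selections are deterministic (topology order) and never silently empty:
    an expression matching nothing raises ``ValueError``.
    """
    raw = spec
    text = spec.strip().lower().replace("cα", "ca").replace("c-alpha", "ca")
    by_id = {a.atom_id: a for a in topology.atoms}

    def res_atoms(idx: int) -> Residue:
        try:
            return topology.residue(idx)
        except KeyError as exc:
            raise ValueError(f"selection {raw!r}: {exc.args[0]}") from None

    if text == "all":
        ids = tuple(a.atom_id for a in topology.atoms)
        return Selection(ids, provenance=raw)

    if text in ("ligand", "ligand atoms", "ligand heavy atoms"):
        heavy_only = "heavy" in text
        ids = tuple(
            a.atom_id
            for r in topology.ligand_residues
            for a in (by_id[i] for i in r.atom_ids)
            if (a.is_heavy or not heavy_only)
        )
        if not ids:
            raise ValueError(f"selection {raw!r}: topology has no ligand (HETATM) atoms")
        return Selection(ids, provenance=raw)

    if text in ("protein heavy atoms", "protein"):
        heavy_only = "heavy" in text
        ids = tuple(
            a.atom_id
            for r in topology.protein_residues
            for a in (by_id[i] for i in r.atom_ids)
            if (a.is_heavy or not heavy_only)
        )
        if not ids:
            raise ValueError(f"selection {raw!r}: topology has no protein atoms")
        return Selection(ids, provenance=raw)

    m = re.fullmatch(rf"residues?\s+{_RES_LIST}\s*(?P<mode>heavy atoms|all atoms)?", text)
    if m:
        heavy_only = (m.group("mode") or "heavy atoms") == "heavy atoms"
        ids: list[int] = []
        for idx in _parse_res_list(m.group("residues")):
            r = res_atoms(idx)
            for i in r.atom_ids:
                if by_id[i].is_heavy or not heavy_only:
                    ids.append(i)
        if not ids:
            raise ValueError(f"selection {raw!r} matched no atoms")
        return Selection(tuple(ids), provenance=raw)

    m = re.fullmatch(rf"ca of residues?\s+{_RES_LIST}", text)
    if m:
        ids = []
        for idx in _parse_res_list(m.group("residues")):
            r = res_atoms(idx)
            ca = [i for i in r.atom_ids if by_id[i].name.upper() == "CA"]
            if not ca:
                raise ValueError(f"selection {raw!r}: residue {idx} has no CA atom")
            ids.extend(ca)
        return Selection(tuple(ids), provenance=raw)

    m = re.fullmatch(r"ring atoms of (?:(?P<rtype>[a-z]{3})\s+)?(?:residue\s+)?(?P<idx>\d+)", text)
    if m:
        idx = int(m.group("idx"))
        r = res_atoms(idx)
        if m.group("rtype") and r.residue_name.upper() != m.group("rtype").upper():
            raise ValueError(
                f"selection {raw!r}: residue {idx} is {r.residue_name}, "
                f"not {m.group('rtype').upper()}"
            )
        ring_names = RING_ATOM_NAMES.get(r.residue_name.upper())
        if ring_names is None:
            raise ValueError(
                f"selection {raw!r}: residue {r.label} ({r.residue_name}) has no aromatic ring"
            )
        name_to_id = {by_id[i].name.upper(): i for i in r.atom_ids}
        missing = [n for n in ring_names if n not in name_to_id]
        if missing:
            raise ValueError(
                f"selection {raw!r}: residue {r.label} is missing ring atoms {missing}"
            )
        return Selection(tuple(name_to_id[n] for n in ring_names), provenance=raw)

    raise ValueError(f"cannot parse selection expression: {raw!r}")


def centroid(coords: np.ndarray) -> np.ndarray:
    """Geometric center of a (n, 3) or (frames, n, 3) coordinate array."""
    return np.asarray(coords, dtype=float).mean(axis=-2)
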