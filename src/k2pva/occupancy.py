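"""Per-residue ligand occupancy and binding-site residence analysis.

Occupancy of a residue is the fraction of trajectory snapshots in which the
ligand lies within a distance cutoff (default 7 Å) of that residue.  The
distance is, by default, the minimum heavy-atom/heavy-atom distance between
ligand and residue; a ligand-centroid mode is available.  Occupancy can be
conditioned on the ligand being bound (its centroid within the cutoff of the
binding-site centroid), which matters for trajectories containing a
binding-site escape.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajmodel import Selection, Trajectory, centroid

__all__ = [
    "OccupancyConfig",
    "OccupancyTable",
    "EscapeResult",
    "NO_ESCAPE",
    "residue_occupancy",
    "bound_fraction_near",
    "site_residence",
    "bound_frame_mask",
]

_DISTANCE_MODES = ("min-heavy-atom", "ligand-centroid")


@dataclass
class OccupancyConfig:
    """Parameters of the occupancy calculation.

    cutoff : Å, contact threshold (inclusive: distance == cutoff counts).
    distance_mode : "min-heavy-atom" (minimum pairwise heavy-atom distance)
        or "ligand-centroid" (ligand geometric center to nearest residue
        heavy atom).
    condition_on_bound : restrict to frames where the ligand centroid is
        within ``cutoff`` of the centroid of ``site_selection``.
    site_selection : defines "bound"; required when conditioning.
    """

    cutoff: float = 7.0
    distance_mode: str = "min-heavy-atom"
    condition_on_bound: bool = False
    site_selection: Selection | None = None

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive (Å)")
        if self.distance_mode not in _DISTANCE_MODES:
            raise ValueError(
                f"distance_mode must be one of {_DISTANCE_MODES}; got {self.distance_mode!r}"
            )
        if self.condition_on_bound and self.site_selection is None:
            raise ValueError("condition_on_bound=True requires site_selection")


@dataclass
class OccupancyTable:
    """Per-residue occupancy fractions for one trajectory."""

    table: pd.DataFrame  # columns: residue_label, occupancy
    n_frames_used: int
    cfg: OccupancyConfig

    def fraction(self, residue_label: str) -> float:
        row = self.table[self.table["residue_label"] == residue_label]
        if row.empty:
            raise KeyError(f"no occupancy row for {residue_label}")
        return float(row["occupancy"].iloc[0])

    def to_csv(self, path, trajectory_id: str = "traj1") -> None:
        """CSV with occupancy as a percentage at two decimals."""
        out = self.table.copy()
        out.insert(1, "trajectory_id", trajectory_id)
        out["occupancy_percent"] = (100.0 * out.pop("occupancy")).map(
            lambda v: f"{v:.2f}"
        )
        out.to_csv(path, index=False)


def _residue_heavy_coords(traj: Trajectory, residue_index: int) -> np.ndarray:
    res = traj.topology.residue(residue_index)
    heavy = traj.topology.heavy_atom_ids(res)
    if not heavy:
        raise ValueError(f"residue {res.label} has no heavy atoms")
    return traj.coordinates[:, traj.topology.indices_of(heavy), :]


def _ligand_heavy_coords(traj: Trajectory, ligand: Selection) -> np.ndarray:
    by_id = {a.atom_id: a for a in traj.topology.atoms}
    heavy = tuple(i for i in ligand.atom_ids if by_id[i].is_heavy)
    if not heavy:
        raise ValueError("ligand selection has no heavy atoms")
    return traj.coordinates[:, traj.topology.indices_of(heavy), :]


def _min_distance_series(lig: np.ndarray, res: np.ndarray, mode: str) -> np.ndarray:
    """Per-frame ligand-residue distance.  lig: (F, nl, 3), res: (F, nr, 3)."""
    if mode == "ligand-centroid":
        lig = centroid(lig)[:, None, :]
    # pairwise distances per frame, then min over both atom axes
    diff = lig[:, :, None, :] - res[:, None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    return d.reshape(d.shape[0], -1).min(axis=1)


def bound_frame_mask(traj: Trajectory, ligand: Selection, cfg: OccupancyConfig) -> np.ndarray:
    """Boolean mask of frames where the ligand centroid is within
    ``cfg.cutoff`` of the site-selection centroid."""
    if cfg.site_selection is None:
        raise ValueError("bound_frame_mask requires cfg.site_selection")
    lig_c = centroid(traj.subset_coords(ligand))
    site_c = centroid(traj.subset_coords(cfg.site_selection))
    d = np.linalg.norm(lig_c - site_c, axis=1)
    return d <= cfg.cutoff


def residue_occupancy(
    traj: Trajectory,
    ligand: Selection,
    residues: list[int],
    cfg: OccupancyConfig | None = None,
) -> OccupancyTable:
    """Fraction of frames with the ligand within ``cfg.cutoff`` of each residue.

    Frames are weighted equally.  When ``cfg.condition_on_bound`` is set the
    denominator is the number of bound frames; zero bound frames is an error
    ("no bound frames"), never a silent NaN.
    """
    cfg = cfg or OccupancyConfig()
    lig_ids = set(ligand.atom_ids)
    for idx in residues:
        res = traj.topology.residue(idx)
        if lig_ids & set(res.atom_ids):
            raise ValueError(f"ligand selection overlaps residue {res.label}")

    if cfg.condition_on_bound:
        mask = bound_frame_mask(traj, ligand, cfg)
        if not mask.any():
            raise ValueError("no bound frames after conditioning on the binding site")
    else:
        mask = np.ones(traj.n_frames, dtype=bool)

    lig_xyz = _ligand_heavy_coords(traj, ligand)[mask]
    rows = []
    for idx in residues:
        res = traj.topology.residue(idx)
        res_xyz = _residue_heavy_coords(traj, idx)[mask]
        d = _min_distance_series(lig_xyz, res_xyz, cfg.distance_mode)
        rows.append({"residue_label": res.label, "occupancy": float((d <= cfg.cutoff).mean())})
    return OccupancyTable(pd.DataFrame(rows), n_frames_used=int(mask.sum()), cfg=cfg)


def bound_fraction_near(
    traj: Trajectory,
    ligand: Selection,
    residue: int,
    cfg: OccupancyConfig,
) -> float:
    """Fraction of *bound* frames with the ligand within cutoff of ``residue``.

    Quantifies statements of the form "the ligand remained near residue X
    for >94% of the time it occupied the binding site".
    """
    if not cfg.condition_on_bound:
        cfg = OccupancyConfig(
            cutoff=cfg.cutoff,
            distance_mode=cfg.distance_mode,
            condition_on_bound=True,
            site_selection=cfg.site_selection,
        )
    return residue_occupancy(traj, ligand, [residue], cfg).table["occupancy"].iloc[0]


@dataclass(frozen=True)
class EscapeResult:
    """First sustained departure of the ligand from the binding site."""

    escaped: bool
    frame: int | None = None
    time_ps: float | None = None

    def __bool__(self) -> bool:
        return self.escaped


NO_ESCAPE = EscapeResult(escaped=False)


def site_residence(
    traj: Trajectory,
    ligand: Selection,
    site: Selection,
    cutoff: float = 7.0,
    persistence_window: int = 10,
) -> EscapeResult:
    """First frame at which the ligand centroid leaves the site and stays out.

    The ligand must be bound in frame 0.  An excursion counts as an escape
    only if the centroid remains beyond ``cutoff`` from the site centroid
    for at least ``persistence_window`` consecutive frames (or through the
    end of the trajectory); single-frame recrossings are ignored.  Returns
    :data:`NO_ESCAPE` (falsy, distinct from frame 0) when the ligand never
    escapes.
    """
    if persistence_window < 1:
        raise ValueError("persistence_window must be >= 1")
    lig_c = centroid(traj.subset_coords(ligand))
    site_c = centroid(traj.subset_coords(site))
    outside = np.linalg.norm(lig_c - site_c, axis=1) > cutoff
    if outside[0]:
        raise ValueError("ligand is not bound in frame 0")
    n = len(outside)
    # run_from[i] = length of the consecutive outside-run starting at i
    run_from = np.zeros(n + 1, dtype=int)
    for i in range(n - 1, -1, -1):
        run_from[i] = run_from[i + 1] + 1 if outside[i] else 0
    for i in range(n):
        if run_from[i] >= persistence_window:
            return EscapeResult(True, i, i * traj.frame_interval)
    return NO_ESCAPE
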