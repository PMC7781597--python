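"""Aromatic pi-stacking detection and rolling-window stacking fractions.

Two rings are considered pi-stacked in a frame when their centroids are
separated by at most ``centroid_cutoff`` (default 4.4 Å, inclusive) and the
angle between their least-squares ring planes is strictly less than
``max_plane_angle`` (default 30°).  The plane normal is fit to all ring
atoms, which tolerates thermal pucker; normals are sign-ambiguous, so the
interplanar angle is folded to [0°, 90°].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .trajmodel import Selection, Trajectory

__all__ = [
    "PiStackConfig",
    "PiStackSeries",
    "ring_geometry",
    "interplanar_angle",
    "is_stacked",
    "stacking_series",
]


@dataclass(frozen=True)
class PiStackConfig:
    centroid_cutoff: float = 4.4   # Å, inclusive ("4.4 Å or less")
    max_plane_angle: float = 30.0  # degrees, exclusive ("less than 30°")
    window: int = 10               # rolling-window width in stored snapshots

    def __post_init__(self) -> None:
        if self.centroid_cutoff <= 0:
            raise ValueError("centroid_cutoff must be positive")
        if not 0 < self.max_plane_angle <= 90:
            raise ValueError("max_plane_angle must be in (0, 90] degrees")
        if self.window < 1:
            raise ValueError("window must be >= 1")


@dataclass
class PiStackSeries:
    """Per-frame verdicts plus the rolling stacking fraction.

    ``rolling`` has length ``n_frames - window + 1`` and is indexed by
    window start; it is empty when the trajectory is shorter than the
    window.  ``overall_fraction`` is the plain mean of the boolean series.
    """

    stacked: np.ndarray          # bool, (n_frames,)
    rolling: np.ndarray          # float, (n_frames - window + 1,) or (0,)
    window: int
    frame_interval: float

    @property
    def overall_fraction(self) -> float:
        return float(self.stacked.mean())

    @property
    def overall_percent(self) -> float:
        return 100.0 * self.overall_fraction

    def to_frame(self):
        import pandas as pd

        n = len(self.stacked)
        roll = np.full(n, np.nan)
        roll[: len(self.rolling)] = self.rolling
        return pd.DataFrame(
            {
                "frame": np.arange(n),
                "time_ps": np.arange(n) * self.frame_interval,
                "stacked": self.stacked.astype(int),
                "rolling_fraction": roll,
            }
        )


def ring_geometry(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit least-squares plane normal of a ring.

    Parameters
    ----------
    coords : (n, 3) array, n >= 3, non-collinear ring atom positions.

    Returns
    -------
    centroid : (3,) mean position.
    normal : (3,) unit normal of the best-fit plane (sign unspecified).
    """
    xyz = np.asarray(coords, dtype=float)
    if xyz.ndim != 2 or xyz.shape[1] != 3 or xyz.shape[0] < 3:
        raise ValueError("ring requires an (n>=3, 3) coordinate array")
    c = xyz.mean(axis=0)
    centered = xyz - c
    # smallest right singular vector = least-squares plane normal
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-8 * max(s[0], 1e-30):
        raise ValueError("ring atoms are collinear; plane normal undefined")
    return c, vt[2]


def interplanar_angle(normal_a: np.ndarray, normal_b: np.ndarray) -> float:
    """Angle between two ring planes in degrees, folded to [0, 90]."""
    na = np.asarray(normal_a, float)
    nb = np.asarray(normal_b, float)
    cosang = abs(float(np.dot(na, nb)) / (np.linalg.norm(na) * np.linalg.norm(nb)))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def is_stacked(
    ring_a_coords: np.ndarray,
    ring_b_coords: np.ndarray,
    cfg: PiStackConfig | None = None,
) -> bool:
    """Stacking verdict for one frame.

    True iff centroid distance <= cutoff (inclusive) AND interplanar angle
    < max_plane_angle (exclusive).
    """
    cfg = cfg or PiStackConfig()
    ca, na = ring_geometry(ring_a_coords)
    cb, nb = ring_geometry(ring_b_coords)
    # snap to well below thermal noise so exact-boundary geometries get the
    # verdict their construction intends (<=  at the distance, < at the angle)
    dist = round(float(np.linalg.norm(ca - cb)), 9)
    if dist > cfg.centroid_cutoff:
        return False
    angle = round(interplanar_angle(na, nb), 6)
    return angle < cfg.max_plane_angle


def stacking_series(
    traj: Trajectory,
    ring_a: Selection,
    ring_b: Selection,
    cfg: PiStackConfig | None = None,
) -> PiStackSeries:
    """Per-frame stacking verdicts and left-aligned rolling mean."""
    cfg = cfg or PiStackConfig()
    xa = traj.subset_coords(ring_a)
    xb = traj.subset_coords(ring_b)
    flags = np.fromiter(
        (is_stacked(xa[f], xb[f], cfg) for f in range(traj.n_frames)),
        dtype=bool,
        count=traj.n_frames,
    )
    if traj.n_frames >= cfg.window:
        # integer window counts keep the fractions exact (e.g. 10/10 == 1.0)
        counts = np.convolve(flags.astype(np.int64), np.ones(cfg.window, np.int64), "valid")
        rolling = counts / cfg.window
    else:
        rolling = np.empty(0)
    return PiStackSeries(
        stacked=flags,
        rolling=rolling,
        window=cfg.window,
        frame_interval=traj.frame_interval,
    )
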