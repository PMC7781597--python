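"""Flat-well (flat-bottom) spherical ligand restraint energetics.

A flat-well restraint confines a ligand's center of geometry to a sphere of
radius R around a binding-site center: the potential is exactly zero inside
the sphere and rises half-harmonically beyond the wall, so it perturbs the
simulation only during rare wall excursions.  Because the restraint limits
only the volume the ligand may occupy, its thermodynamic effect is purely
entropic and has the closed form

    dG_restraint = -R_gas * T * ln(V_sphere / V_1M)

where V_1M is the volume per molecule at 1 M standard concentration
(~1660.54 A^3).  For R = 7 A at 303.15 K this costs ~0.09 kcal/mol.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "R_GAS_KCAL",
    "V_STD_A3",
    "FlatWellRestraint",
    "EntropicCost",
    "WallContact",
    "flatwell_energy",
    "wall_contact_fraction",
    "wall_contact_from_counts",
    "restraint_entropic_cost",
    "read_restraint_series",
]

#: Gas constant in kcal mol^-1 K^-1.
R_GAS_KCAL = 1.9872e-3
#: Avogadro constant, mol^-1.
_N_AVOGADRO = 6.02214076e23
#: Volume per molecule at 1 M standard concentration, in A^3
#: (1 L = 1e27 A^3 divided by Avogadro's number).
V_STD_A3 = 1.0e27 / _N_AVOGADRO


@dataclass(frozen=True)
class FlatWellRestraint:
    """Spherical flat-bottom restraint on a ligand center of geometry.

    radius : Å, wall position (flat region inside).
    k : kcal mol^-1 Å^-2, wall stiffness of the half-harmonic branch.
    center : optional (3,) point or a selection string naming the centroid
        that defines the well center; informational for the colvar export.
    """

    radius: float = 7.0
    k: float = 10.0
    center: object = None

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive (Å)")
        if self.k < 0:
            raise ValueError("force constant must be non-negative")

    def to_colvar_json(self) -> str:
        """Engine-neutral JSON block describing the restraint."""
        center = self.center
        if isinstance(center, np.ndarray):
            center = center.tolist()
        return json.dumps(
            {
                "type": "flat_well_sphere",
                "center": center,
                "radius_A": self.radius,
                "force_constant_kcal_per_mol_A2": self.k,
                "wall_form": "half_harmonic",
            },
            indent=2,
        )


@dataclass(frozen=True)
class EntropicCost:
    """Standard-state entropic cost of a spherical volume restraint."""

    radius_A: float
    T_K: float
    V_star_A3: float
    V_std_A3: float
    dG_kcal_mol: float


@dataclass(frozen=True)
class WallContact:
    """Wall-excursion statistics of a restraint-coordinate series."""

    n_outside: int
    n_total: int

    @property
    def percentage(self) -> float:
        return 100.0 * self.n_outside / self.n_total


def flatwell_energy(r: float | np.ndarray, restraint: FlatWellRestraint) -> float | np.ndarray:
    """Restraint energy at distance ``r`` from the well center, kcal/mol.

    Zero for r <= R; half-harmonic ``k * (r - R)**2`` beyond the wall.  The
    form is continuous and C1 at the boundary.
    """
    r_arr = np.asarray(r, dtype=float)
    if np.any(r_arr < 0):
        raise ValueError("distance r must be non-negative")
    excess = np.clip(r_arr - restraint.radius, 0.0, None)
    e = restraint.k * excess**2
    return float(e) if np.isscalar(r) else e


def wall_contact_fraction(series: np.ndarray, radius: float) -> WallContact:
    """Count snapshots whose restraint coordinate exceeds the wall radius.

    ``series`` is the per-snapshot distance of the ligand center of
    geometry from the restraint center, in Å.
    """
    s = np.asarray(series, dtype=float)
    if s.size == 0:
        raise ValueError("empty restraint-coordinate series")
    n_outside = int((s > radius).sum())
    return WallContact(n_outside=n_outside, n_total=int(s.size))


def wall_contact_from_counts(n_outside: int, n_total: int) -> WallContact:
    """Wall-contact statistics from pre-tabulated snapshot counts."""
    if n_total <= 0 or n_outside < 0 or n_outside > n_total:
        raise ValueError("require 0 <= n_outside <= n_total, n_total > 0")
    return WallContact(n_outside=n_outside, n_total=n_total)


def restraint_entropic_cost(radius: float = 7.0, T: float = 303.15) -> EntropicCost:
    """Analytic standard-state cost of confining a ligand to a sphere.

    dG = -R_gas*T*ln(V*/V_std) with V* = (4/3) pi R^3 and V_std the volume
    per molecule at 1 M.  dG is monotonically decreasing in R and crosses
    zero where the sphere volume equals V_std (R ~ 7.34 Å).
    """
    if radius <= 0:
        raise ValueError("radius must be positive (Å)")
    if T <= 0:
        raise ValueError("temperature must be positive (K)")
    v_star = (4.0 / 3.0) * math.pi * radius**3
    dg = -R_GAS_KCAL * T * math.log(v_star / V_STD_A3)
    return EntropicCost(
        radius_A=radius, T_K=T, V_star_A3=v_star, V_std_A3=V_STD_A3, dG_kcal_mol=dg
    )


def read_restraint_series(path: str | Path) -> np.ndarray:
    """Read a one-column text series of restraint coordinates (Å)."""
    return np.loadtxt(path, ndmin=1)
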