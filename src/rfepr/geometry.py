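"""Geometric observables: torsions, center-of-mass pseudodihedrals,
hydrogen-bond geometry, angle wrapping and basin assignment.

All torsion angles follow the IUPAC sign convention: looking down the
p2 -> p3 axis, a clockwise rotation of the far bond relative to the near bond
is positive.  The convention is pinned by the cis = 0 deg / trans = 180 deg
identities tested in the suite.  Functions broadcast over leading axes so a
whole trajectory can be evaluated in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .units import GAS_CONSTANT_KCAL, ThermoState

__all__ = [
    "UndefinedAngleError",
    "PseudoDihedralSpec",
    "BasinAssignment",
    "wrap_deg",
    "wrap_rad",
    "torsion",
    "pseudodihedral",
    "hbond_geometry",
    "population_ratio",
    "free_energy_from_ratio",
    "basin_boundaries",
    "assign_basins",
]

#: Particles at least this light (amu) count as hydrogens for group exclusion.
HYDROGEN_MASS_CUTOFF = 1.5


class UndefinedAngleError(ValueError):
    """A dihedral or angle is geometrically undefined (collinear/coincident)."""


def wrap_deg(angle):
    """Wrap angle(s) in degrees onto (-180, 180]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a - 360.0 * np.floor((a + 180.0) / 360.0)
    wrapped = np.where(wrapped == -180.0, 180.0, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def wrap_rad(angle):
    """Wrap angle(s) in radians onto (-pi, pi]."""
    a = np.asarray(angle, dtype=float)
    wrapped = a - 2.0 * np.pi * np.floor((a + np.pi) / (2.0 * np.pi))
    wrapped = np.where(wrapped == -np.pi, np.pi, wrapped)
    return wrapped if wrapped.ndim else float(wrapped)


def _cross(a, b):
    # manual cross product: np.cross carries large per-call overhead for
    # the small arrays used here
    out = np.empty(np.broadcast_shapes(a.shape, b.shape))
    out[..., 0] = a[..., 1] * b[..., 2] - a[..., 2] * b[..., 1]
    out[..., 1] = a[..., 2] * b[..., 0] - a[..., 0] * b[..., 2]
    out[..., 2] = a[..., 0] * b[..., 1] - a[..., 1] * b[..., 0]
    return out


def torsion(p1, p2, p3, p4, degenerate_tol: float = 1e-10):
    """Signed dihedral angle of four points, in degrees on (-180, 180].

    Parameters are arrays of shape ``(..., 3)``; the result broadcasts over
    the leading axes.  Raises :class:`UndefinedAngleError` when the first or
    last bond is parallel to the central bond (the plane normals vanish).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    n1_norm = np.linalg.norm(n1, axis=-1)
    n2_norm = np.linalg.norm(n2, axis=-1)
    b2_norm = np.linalg.norm(b2, axis=-1)
    if np.any(n1_norm < degenerate_tol) or np.any(n2_norm < degenerate_tol) \
            or np.any(b2_norm < degenerate_tol):
        raise UndefinedAngleError(
            "dihedral undefined: collinear bond vectors or coincident points")
    m = _cross(n1, n2)
    y = np.sum(m * (b2 / b2_norm[..., None]), axis=-1)
    x = np.sum(n1 * n2, axis=-1)
    ang = np.degrees(np.arctan2(y, x))
    ang = wrap_deg(ang)
    return ang if np.ndim(ang) else float(ang)


@dataclass(frozen=True)
class PseudoDihedralSpec:
    """Four particle groups defining a center-of-mass pseudodihedral.

    ``groups`` holds four index sequences (P1..P4).  ``weights`` optionally
    carries explicit per-group weights; when absent the particle masses are
    used.  With ``exclude_hydrogen`` set, particles lighter than
    ``HYDROGEN_MASS_CUTOFF`` amu are dropped from every group before the
    centers of mass are formed.
    """

    groups: tuple = ()
    weights: tuple | None = None
    exclude_hydrogen: bool = False

    def __post_init__(self):
        if len(self.groups) != 4:
            raise ValueError("a pseudodihedral needs exactly four groups")
        for g in self.groups:
            if len(g) == 0:
                raise ValueError("pseudodihedral groups must be nonempty")
            if len(set(g)) != len(g):
                raise ValueError("duplicate particle index within a group")
        if self.weights is not None:
            if len(self.weights) != 4:
                raise ValueError("weights must be given for all four groups")
            for w in self.weights:
                if np.any(np.asarray(w, dtype=float) <= 0):
                    raise ValueError("group weights must be positive")


def _group_center(indices, weights, coords):
    idx = np.asarray(indices, dtype=int)
    w = np.asarray(weights, dtype=float)
    sel = np.take(coords, idx, axis=-2)          # (..., g, 3)
    return np.sum(sel * w[..., :, None], axis=-2) / np.sum(w)


def pseudodihedral(spec: PseudoDihedralSpec, coords, masses=None):
    """Torsion of the four mass-weighted group centers, in degrees.

    ``coords`` has shape ``(..., n, 3)``.  Weight normalization makes the
    angle invariant under a uniform rescaling of all masses.
    """
    coords = np.asarray(coords, dtype=float)
    centers = []
    for gi, group in enumerate(spec.groups):
        idx = np.asarray(group, dtype=int)
        if spec.weights is not None:
            w = np.asarray(spec.weights[gi], dtype=float)
        elif masses is not None:
            w = np.asarray(masses, dtype=float)[idx]
        else:
            w = np.ones(len(idx))
        if spec.exclude_hydrogen:
            if masses is None:
                raise ValueError("hydrogen exclusion requires masses")
            keep = np.asarray(masses, dtype=float)[idx] >= HYDROGEN_MASS_CUTOFF
            if not np.any(keep):
                raise UndefinedAngleError(
                    f"group P{gi + 1} empty after hydrogen exclusion")
            idx, w = idx[keep], w[keep]
        centers.append(_group_center(idx, w, coords))
    return torsion(*centers)


def hbond_geometry(donor, hydrogen, acceptor, tol: float = 1e-12):
    """Donor-acceptor distance (nm) and donor-hydrogen-acceptor angle (deg)."""
    d = np.asarray(donor, dtype=float)
    h = np.asarray(hydrogen, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    v1 = d - h
    v2 = a - h
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < tol) or np.any(n2 < tol):
        raise UndefinedAngleError("hydrogen-bond geometry undefined: coincident points")
    cosang = np.clip(np.sum(v1 * v2, axis=-1) / (n1 * n2), -1.0, 1.0)
    dist = np.linalg.norm(a - d, axis=-1)
    angle = np.degrees(np.arccos(cosang))
    if np.ndim(dist):
        return dist, angle
    return float(dist), float(angle)


def population_ratio(delta_g_kcal: float, thermo: ThermoState) -> float:
    """Boltzmann population ratio exp(dG / RT) for a free-energy gap.

    With the convention dG = -RT ln(P_minor / P_major), a positive gap in
    kcal/mol maps to the favored-over-disfavored population ratio.  The
    inverse operation is :func:`free_energy_from_ratio`.
    """
    return float(np.exp(delta_g_kcal / (GAS_CONSTANT_KCAL * thermo.temperature)))


def free_energy_from_ratio(ratio: float, thermo: ThermoState) -> float:
    """Inverse of :func:`population_ratio`: dG (kcal/mol) from a ratio."""
    if ratio <= 0:
        raise ValueError("population ratio must be positive")
    return float(GAS_CONSTANT_KCAL * thermo.temperature * np.log(ratio))


def basin_boundaries(minima_deg: Sequence[float]) -> np.ndarray:
    """Midpoints between circularly adjacent minima, degrees on (-180, 180].

    For ``m`` minima there are ``m`` boundaries partitioning the torsion
    circle; each basin is the arc between consecutive boundaries containing
    exactly one minimum.
    """
    mins = np.sort(wrap_deg(np.asarray(minima_deg, dtype=float)))
    if len(mins) < 2:
        raise ValueError("need at least two minima to define basins")
    gaps = np.diff(np.concatenate([mins, [mins[0] + 360.0]]))
    return wrap_deg(mins + gaps / 2.0)


@dataclass
class BasinAssignment:
    """Per-frame basin labels for a torsion time series."""

    series_deg: np.ndarray
    labels: np.ndarray
    minima_deg: dict = field(default_factory=dict)

    def occupancy(self, label: str) -> float:
        return float(np.mean(self.labels == label))


def assign_basins(series_deg, minima_deg: dict) -> BasinAssignment:
    """Label each torsion value by its nearest minimum on the circle.

    ``minima_deg`` maps basin names (e.g. ``anti``/``syn``) to minimum
    locations in degrees.  Nearest-on-circle assignment is equivalent to
    splitting at the midpoints between adjacent minima.
    """
    series = np.atleast_1d(np.asarray(series_deg, dtype=float))
    names = list(minima_deg)
    locs = np.array([minima_deg[n] for n in names], dtype=float)
    dist = np.abs(wrap_deg(series[:, None] - locs[None, :]))
    labels = np.array(names, dtype=object)[np.argmin(dist, axis=1)]
    return BasinAssignment(series_deg=series, labels=labels, minima_deg=dict(minima_deg))
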