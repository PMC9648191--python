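"""Toy molecular systems with a two-basin torsion, and brute-force reference
free energies.

The generator stands in for a DNA purine base that can occupy either the
*anti* (chi near -105 deg) or *syn* (chi near +64 deg) orientation about a
glycosidic-like bond.  A toy consists of

* a **dual set**: a stem/axis triad plus a rigid arm that rotates about the
  axis (the analogue of the base), carrying the two-well torsion profile and
  the nonbonded parameters that couple it to its surroundings;
* a **shared set**: static "frame" particles arranged around the rotor (the
  analogue of the helix environment, creating an anti/syn asymmetry through
  Lennard-Jones and Coulomb interactions), plus harmonically tethered mobile
  particles with zero nonbonded parameters that emulate orthogonal
  environmental fluctuations.

Because the only degrees of freedom coupled to the alchemical transformation
are the rotor angles, every free-energy difference the restrain-FEP-release
cycle targets reduces to one-dimensional integrals over the torsion circle,
which :func:`exact_free_energy_1d` and :func:`exact_cycle_reference` evaluate
by quadrature to essentially machine precision.  This is what makes the toys
usable as ground truth for the estimator and pipeline layers.

Energies are in kJ/mol, distances in nm, angles in degrees at the API surface
(radians internally where noted).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .geometry import basin_boundaries, torsion, wrap_deg, wrap_rad
from .units import ThermoState, kj_to_kcal

__all__ = [
    "InvalidTopologyError",
    "InconsistentTopologyError",
    "OracleFailureError",
    "TorsionProfile",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "ProfileTerm",
    "Tether",
    "RotorSpec",
    "ToyTopology",
    "build_torsion_toy",
    "build_hybrid_topology",
    "standard_profile",
    "torsion_energy_function",
    "exact_free_energy_1d",
    "exact_cycle_reference",
    "topology_to_dict",
    "topology_from_dict",
    "save_topology",
    "load_topology",
]


class InvalidTopologyError(ValueError):
    """A topology violates a structural precondition."""


class InconsistentTopologyError(ValueError):
    """Two topologies that must agree (e.g. shared sets) do not."""


class OracleFailureError(RuntimeError):
    """The brute-force quadrature oracle could not produce a reliable value."""


@dataclass(frozen=True)
class TorsionProfile:
    """A periodic multi-well torsion potential.

    Each well is a periodic Gaussian ``-D exp(-wrap(chi-chi0)^2 / (2 w^2))``
    with width ``w = sqrt(D/c)`` so that the curvature at the bottom equals
    the requested ``c`` (kJ/mol/rad^2).  ``minima`` is a sequence of
    ``(location_deg, depth_kj, curvature_kj_per_rad2)`` triples with
    locations on (-180, 180].  ``quadruple`` names the four particles whose
    dihedral the profile acts on; it may be ``None`` for a free-standing
    profile and is assigned by the builders.
    """

    minima: tuple
    quadruple: tuple | None = None

    def __post_init__(self):
        if len(self.minima) < 1:
            raise ValueError("a torsion profile needs at least one minimum")
        for loc, depth, curv in self.minima:
            if not (-180.0 < loc <= 180.0):
                raise ValueError(f"minimum location {loc} outside (-180, 180]")
            if depth <= 0 or curv <= 0:
                raise ValueError("well depth and curvature must be positive")
        if self.quadruple is not None and len(set(self.quadruple)) != 4:
            raise InvalidTopologyError(
                "dihedral quadruple needs four distinct particles")

    @property
    def locations_deg(self) -> np.ndarray:
        return np.array([m[0] for m in self.minima], dtype=float)

    def energy(self, chi_rad):
        """Potential energy (kJ/mol) at torsion angle(s) in radians."""
        chi = np.asarray(chi_rad, dtype=float)
        u = np.zeros_like(chi)
        for loc, depth, curv in self.minima:
            w2 = depth / curv
            d = wrap_rad(chi - np.radians(loc))
            u = u - depth * np.exp(-np.square(d) / (2.0 * w2))
        return u if u.ndim else float(u)


@dataclass(frozen=True)
class BondTerm:
    i: int
    j: int
    k: float          # kJ/mol/nm^2
    r0: float         # nm


@dataclass(frozen=True)
class AngleTerm:
    triple: tuple
    k: float          # kJ/mol/rad^2
    theta0: float     # rad


@dataclass(frozen=True)
class DihedralTerm:
    """Cosine-series proper dihedral k*(1 + cos(n*phi - phase))."""

    quadruple: tuple
    periodicity: int
    barrier: float    # kJ/mol
    phase: float      # rad
    always_on: bool = True


@dataclass(frozen=True)
class ProfileTerm:
    """A torsion profile bound to a particle set of a topology."""

    profile: TorsionProfile
    owner: str = "dual"
    always_on: bool = True


@dataclass(frozen=True)
class Tether:
    index: int
    k: float          # kJ/mol/nm^2
    site: tuple       # nm


@dataclass(frozen=True)
class RotorSpec:
    """Rigid-rotation move template: particles in ``moving`` rotate about the
    axis through particles ``axis[0] -> axis[1]``."""

    axis: tuple
    moving: tuple
    quadruple: tuple


_SET_LABELS = {"shared", "dual", "dual-RV", "dual-VR"}
_MOBILITY = {"static", "tethered", "rotor"}


@dataclass
class ToyTopology:
    """Particles, bonded terms and set partition of a toy system."""

    masses: np.ndarray
    charges: np.ndarray
    lj_epsilon: np.ndarray
    lj_sigma: np.ndarray
    set_labels: np.ndarray
    mobility: np.ndarray
    tethers: list = field(default_factory=list)
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)
    profiles: list = field(default_factory=list)
    exclusions: set = field(default_factory=set)
    rotors: dict = field(default_factory=dict)

    def __post_init__(self):
        self.masses = np.asarray(self.masses, dtype=float)
        self.charges = np.asarray(self.charges, dtype=float)
        self.lj_epsilon = np.asarray(self.lj_epsilon, dtype=float)
        self.lj_sigma = np.asarray(self.lj_sigma, dtype=float)
        self.set_labels = np.asarray(self.set_labels, dtype=object)
        self.mobility = np.asarray(self.mobility, dtype=object)
        self.validate()

    # -- structure -----------------------------------------------------

    @property
    def n_particles(self) -> int:
        return len(self.masses)

    def indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.set_labels == label)

    @property
    def dual_set_labels(self) -> list:
        return [lab for lab in ("dual", "dual-RV", "dual-VR")
                if len(self.indices(lab))]

    @property
    def is_hybrid(self) -> bool:
        return len(self.indices("dual-RV")) > 0 and len(self.indices("dual-VR")) > 0

    def validate(self) -> None:
        n = self.n_particles
        for arr, name in ((self.charges, "charges"), (self.lj_epsilon, "lj_epsilon"),
                          (self.lj_sigma, "lj_sigma"), (self.set_labels, "set_labels"),
                          (self.mobility, "mobility")):
            if len(arr) != n:
                raise InvalidTopologyError(f"{name} length {len(arr)} != {n} particles")
        if np.any(self.masses <= 0):
            raise InvalidTopologyError("all masses must be positive")
        if np.any(self.lj_sigma <= 0):
            raise InvalidTopologyError("all LJ sigmas must be positive")
        bad = set(self.set_labels) - _SET_LABELS
        if bad:
            raise InvalidTopologyError(f"unknown set labels: {bad}")
        bad = set(self.mobility) - _MOBILITY
        if bad:
            raise InvalidTopologyError(f"unknown mobility flags: {bad}")
        for term in self.profiles:
            quad = term.profile.quadruple
            if quad is None or len(set(quad)) != 4:
                raise InvalidTopologyError(
                    "bound torsion profiles need a 4-particle quadruple")
        if self.is_hybrid and ("dual" in set(self.set_labels)):
            raise InvalidTopologyError("hybrid topology may not contain plain 'dual'")

    def profile_for(self, label: str) -> ProfileTerm:
        for term in self.profiles:
            if term.owner == label:
                return term
        raise KeyError(f"no torsion profile bound to set {label!r}")


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def _frame_layout(minima_deg: Sequence[float]):
    """Static environment particles: an attractor aligned with the second
    torsion minimum, a weak partner at the first, and two neutral LJ spheres."""
    primary = minima_deg[1] if len(minima_deg) > 1 else 0.0
    secondary = minima_deg[0]
    return [
        # (azimuth deg, radius nm, z nm, charge e, eps kJ/mol, sigma nm, mass amu)
        (primary, 0.55, 0.15, +0.10, 0.25, 0.33, 16.0),
        (secondary, 0.55, 0.15, -0.03, 0.25, 0.33, 16.0),
        # deliberately not diametrically opposed: their joint center of mass
        # must stay off the rotor axis for the base-flipping pseudodihedral
        (140.0, 0.60, 0.05, 0.0, 0.20, 0.35, 12.0),
        (-30.0, 0.60, 0.25, 0.0, 0.20, 0.35, 12.0),
    ]


def _rotate_z(points: np.ndarray, angle_rad: float) -> np.ndarray:
    c, s = np.cos(angle_rad), np.sin(angle_rad)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return points @ rot.T


def build_torsion_toy(profile: TorsionProfile, n_shared: int, n_dual: int,
                      seed: int, start_minimum: int = 0):
    """Construct a single-state toy topology plus initial coordinates.

    The dual set holds ``n_dual`` particles: a stem reference, two axis
    particles and an ``n_dual - 3`` particle rigid arm whose rotation about
    the axis is the two-state torsion coordinate.  The shared set holds up to
    four static frame particles (the rotor's interaction partners) and
    ``n_shared - 4`` tethered mobile particles with zero nonbonded
    parameters.  Coordinates start in the basin selected by
    ``start_minimum`` (an index into ``profile.minima``).

    Returns ``(topology, coords)`` with coords of shape ``(n, 3)`` in nm.
    """
    if n_dual < 4:
        raise InvalidTopologyError(
            f"n_dual must be >= 4 so a torsion quadruple fits, got {n_dual}")
    if len(profile.minima) < 2:
        raise InvalidTopologyError(
            "two-state toy requires a profile with at least two minima")
    if not 0 <= start_minimum < len(profile.minima):
        raise ValueError("start_minimum out of range")
    rng = np.random.default_rng(seed)

    n = n_shared + n_dual
    masses = np.empty(n)
    charges = np.zeros(n)
    eps = np.zeros(n)
    sig = np.full(n, 0.30)
    labels = np.empty(n, dtype=object)
    mobility = np.empty(n, dtype=object)
    coords = np.zeros((n, 3))
    tethers: list = []

    minima_deg = profile.locations_deg
    n_frame = min(4, n_shared)
    frame = _frame_layout(minima_deg)
    for i in range(n_frame):
        az, rad, z, q, e, s, m = frame[i]
        coords[i] = (rad * np.cos(np.radians(az)), rad * np.sin(np.radians(az)), z)
        masses[i], charges[i], eps[i], sig[i] = m, q, e, s
        labels[i], mobility[i] = "shared", "static"
    for k, i in enumerate(range(n_frame, n_shared)):
        site = np.array([1.5 + 0.25 * k, 1.5, 1.2]) + rng.normal(0.0, 0.05, 3)
        coords[i] = site + rng.normal(0.0, 0.03, 3)
        masses[i] = 18.0
        labels[i], mobility[i] = "shared", "tethered"
        tethers.append(Tether(index=i, k=500.0, site=tuple(site)))

    # dual set: stem d0, axis d1-d2, arm d3..
    d = n_shared
    base = np.zeros((n_dual, 3))
    base[0] = (0.25, 0.0, -0.10)                      # stem (chi reference arm)
    base[1] = (0.0, 0.0, 0.0)                         # axis bottom
    base[2] = (0.0, 0.0, 0.15)                        # axis top
    base[3] = (0.25, 0.0, 0.15)                       # arm tip
    for k in range(1, n_dual - 3):
        az = np.radians(25.0 * ((k + 1) // 2) * (1 if k % 2 else -1))
        z = 0.15 + (0.05 if k % 2 else -0.05)
        base[3 + k] = (0.36 * np.cos(az), 0.36 * np.sin(az), z)
    arm = tuple(range(d + 3, d + n_dual))
    chi0 = np.radians(minima_deg[start_minimum])
    coords[d:d + n_dual] = base
    coords[list(arm)] = _rotate_z(base[3:], chi0)

    masses[d:d + n_dual] = [14.0, 12.0, 12.0] + [12.0] * (n_dual - 3)
    masses[d + 3] = 14.0
    charges[d + 3] = -0.10
    eps[d + 3], sig[d + 3] = 0.30, 0.33
    for k in range(1, n_dual - 3):
        eps[d + 3 + k], sig[d + 3 + k] = 0.25, 0.33
    labels[d:d + n_dual] = "dual"
    mobility[d:d + n_dual] = "static"
    mobility[list(arm)] = "rotor"

    quadruple = (d, d + 1, d + 2, d + 3)
    bonds = [BondTerm(d, d + 1, 25000.0, float(np.linalg.norm(coords[d] - coords[d + 1]))),
             BondTerm(d + 1, d + 2, 25000.0, float(np.linalg.norm(coords[d + 1] - coords[d + 2]))),
             BondTerm(d + 2, d + 3, 25000.0, float(np.linalg.norm(coords[d + 2] - coords[d + 3])))]
    for k in range(1, n_dual - 3):
        bonds.append(BondTerm(d + 2 + k, d + 3 + k, 25000.0,
                              float(np.linalg.norm(coords[d + 2 + k] - coords[d + 3 + k]))))
    v1 = coords[d + 1] - coords[d + 2]
    v2 = coords[d + 3] - coords[d + 2]
    theta0 = float(np.arccos(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))))
    angles = [AngleTerm((d + 1, d + 2, d + 3), 400.0, theta0)]

    topo = ToyTopology(
        masses=masses, charges=charges, lj_epsilon=eps, lj_sigma=sig,
        set_labels=labels, mobility=mobility, tethers=tethers,
        bonds=bonds, angles=angles,
        profiles=[ProfileTerm(replace(profile, quadruple=quadruple), owner="dual")],
        rotors={"dual": RotorSpec(axis=(d + 1, d + 2), moving=arm, quadruple=quadruple)},
    )
    return topo, coords


def _shared_block_equal(a: ToyTopology, b: ToyTopology, ca, cb) -> bool:
    ia, ib = a.indices("shared"), b.indices("shared")
    if len(ia) != len(ib):
        return False
    for arr_a, arr_b in ((a.masses, b.masses), (a.charges, b.charges),
                         (a.lj_epsilon, b.lj_epsilon), (a.lj_sigma, b.lj_sigma)):
        if not np.array_equal(arr_a[ia], arr_b[ib]):
            return False
    if not (np.array_equal(a.mobility[ia], b.mobility[ib])
            and np.array_equal(ca[ia], cb[ib])):
        return False
    return True


def _remap_terms(topo: ToyTopology, offset: int, owner: str):
    """Shift a single-state topology's dual-set bonded terms by ``offset``."""
    def sh(i):
        return i + offset if topo.set_labels[i] != "shared" else i
    bonds = [BondTerm(sh(b.i), sh(b.j), b.k, b.r0) for b in topo.bonds]
    angles = [AngleTerm(tuple(sh(i) for i in a.triple), a.k, a.theta0)
              for a in topo.angles]
    dihedrals = [replace(t, quadruple=tuple(sh(i) for i in t.quadruple),
                         always_on=True) for t in topo.dihedrals]
    profiles = [ProfileTerm(replace(t.profile,
                                    quadruple=tuple(sh(i) for i in t.profile.quadruple)),
                            owner=owner, always_on=True) for t in topo.profiles]
    rotors = {}
    for _, spec in topo.rotors.items():
        rotors[owner] = RotorSpec(axis=tuple(sh(i) for i in spec.axis),
                                  moving=tuple(sh(i) for i in spec.moving),
                                  quadruple=tuple(sh(i) for i in spec.quadruple))
    return bonds, angles, dihedrals, profiles, rotors


def build_hybrid_topology(topo_anti: ToyTopology, topo_syn: ToyTopology,
                          coords_anti: np.ndarray, coords_syn: np.ndarray):
    """Merge two single-state conformers into a dual-topology hybrid.

    The shared set appears once; the anti conformer's dual set becomes
    ``dual-RV`` (real -> virtual during FEP) and the syn conformer's becomes
    ``dual-VR`` (virtual -> real).  The two dual copies are mutually
    non-interacting (all cross pairs excluded) and the torsion profiles of
    both copies are flagged always-on, so only van der Waals and Coulomb
    interactions are switched by lambda.

    Returns ``(hybrid_topology, hybrid_coords)``.
    """
    for t in (topo_anti, topo_syn):
        if t.is_hybrid or "dual" not in set(t.set_labels):
            raise InconsistentTopologyError("inputs must be single-state topologies")
    if not _shared_block_equal(topo_anti, topo_syn, coords_anti, coords_syn):
        raise InconsistentTopologyError("shared sets of the two conformers differ")
    ida, ids = topo_anti.indices("dual"), topo_syn.indices("dual")
    if len(ida) != len(ids):
        raise InconsistentTopologyError("dual sets differ in size")
    for arr_a, arr_b in ((topo_anti.masses, topo_syn.masses),
                         (topo_anti.charges, topo_syn.charges),
                         (topo_anti.lj_epsilon, topo_syn.lj_epsilon),
                         (topo_anti.lj_sigma, topo_syn.lj_sigma)):
        if not np.array_equal(arr_a[ida], arr_b[ids]):
            raise InconsistentTopologyError(
                "dual-set particle parameters differ between conformers")

    ns, nd = len(topo_anti.indices("shared")), len(ida)
    n = ns + 2 * nd
    masses = np.concatenate([topo_anti.masses[:ns], topo_anti.masses[ida],
                             topo_syn.masses[ids]])
    charges = np.concatenate([topo_anti.charges[:ns], topo_anti.charges[ida],
                              topo_syn.charges[ids]])
    eps = np.concatenate([topo_anti.lj_epsilon[:ns], topo_anti.lj_epsilon[ida],
                          topo_syn.lj_epsilon[ids]])
    sig = np.concatenate([topo_anti.lj_sigma[:ns], topo_anti.lj_sigma[ida],
                          topo_syn.lj_sigma[ids]])
    labels = np.array(["shared"] * ns + ["dual-RV"] * nd + ["dual-VR"] * nd,
                      dtype=object)
    mobility = np.concatenate([topo_anti.mobility[:ns], topo_anti.mobility[ida],
                               topo_syn.mobility[ids]])
    coords = np.concatenate([coords_anti[:ns], coords_anti[ida], coords_syn[ids]])

    b_rv, a_rv, d_rv, p_rv, r_rv = _remap_terms(topo_anti, 0, "dual-RV")
    b_vr, a_vr, d_vr, p_vr, r_vr = _remap_terms(topo_syn, nd, "dual-VR")
    exclusions = {(int(i), int(j)) for i in range(ns, ns + nd)
                  for j in range(ns + nd, n)}
    hybrid = ToyTopology(
        masses=masses, charges=charges, lj_epsilon=eps, lj_sigma=sig,
        set_labels=labels, mobility=mobility,
        tethers=list(topo_anti.tethers),
        bonds=b_rv + b_vr, angles=a_rv + a_vr, dihedrals=d_rv + d_vr,
        profiles=p_rv + p_vr, exclusions=exclusions,
        rotors={**r_rv, **r_vr},
    )
    return hybrid, coords


def standard_profile() -> TorsionProfile:
    """The default two-well glycosyl-like torsion profile.

    Minima sit at the anti (-105 deg) and syn (+64 deg) orientations.  The
    two wells are identical in depth (40 kJ/mol, a ~16 kT barrier at 300 K
    that blocks spontaneous interconversion) and curvature (200 kJ/mol/rad^2,
    basin fluctuations of ~6 deg); the anti/syn free-energy asymmetry of the
    standard toy comes from the rotor's interactions with the static frame,
    not from the bare profile.
    """
    return TorsionProfile(minima=((-105.0, 40.0, 200.0), (64.0, 40.0, 200.0)))


# ---------------------------------------------------------------------------
# brute-force references
# ---------------------------------------------------------------------------

def torsion_energy_function(topo: ToyTopology, coords: np.ndarray, set_label: str,
                            include_nonbonded: bool = True,
                            restraints=None,
                            restraint_scale: float = 1.0) -> Callable:
    """Potential energy of one dual set as a function of its torsion angle.

    Returns ``U(chi_rad) -> kJ/mol`` accepting scalars or arrays.  The
    function rotates the set's rigid arm about its axis and accumulates the
    torsion profile, (optionally) the fully coupled nonbonded interactions
    with static shared particles, and (optionally) the restraints whose
    subject is this set scaled by ``restraint_scale``.

    Exactness guard: every nonbonded partner of the set must be a *static*
    shared particle, otherwise the energy is not a function of chi alone and
    an :class:`OracleFailureError` is raised.
    """
    from .alchemy import build_pair_table, plain_pair_energy  # local: avoid cycle

    spec = topo.rotors[set_label]
    term = topo.profile_for(set_label)
    quad = term.profile.quadruple
    axis_pt = coords[spec.axis[0]]
    axis_dir = coords[spec.axis[1]] - coords[spec.axis[0]]
    axis_dir = axis_dir / np.linalg.norm(axis_dir)
    moving = np.asarray(spec.moving, dtype=int)
    rel = coords[moving] - axis_pt
    chi_ref = np.radians(torsion(*(coords[i] for i in quad)))

    table = build_pair_table(topo, set_label) if include_nonbonded else None
    if table is not None and len(table.i_idx):
        partner_static = topo.mobility[table.j_idx] == "static"
        if not np.all(partner_static):
            raise OracleFailureError(
                "nonbonded partners of the rotor must be static for the 1D oracle")

    sub_restraints = None
    if restraints is not None:
        sub_restraints = restraints.for_subject(_subject_of(set_label))

    def rotate(delta):
        delta = np.atleast_1d(np.asarray(delta, dtype=float))
        c = np.cos(delta)[:, None, None]
        s = np.sin(delta)[:, None, None]
        k = axis_dir
        kxr = np.cross(k, rel)
        kdr = rel @ k
        rot = rel[None] * c + kxr[None] * s + np.outer(kdr, k)[None] * (1 - c)
        return rot + axis_pt

    def energy(chi_rad):
        chi = np.atleast_1d(np.asarray(chi_rad, dtype=float))
        u = np.asarray(term.profile.energy(chi), dtype=float).copy()
        pts = rotate(chi - chi_ref)                       # (F, m, 3)
        if table is not None and len(table.i_idx):
            pos = np.repeat(coords[None], len(chi), axis=0)
            pos[:, moving] = pts
            r = np.linalg.norm(pos[:, table.i_idx] - pos[:, table.j_idx], axis=-1)
            u += plain_pair_energy(r, table.qq, table.epsilon, table.sigma).sum(axis=-1)
        if sub_restraints is not None and len(sub_restraints):
            from .alchemy import restraint_energy
            pos = np.repeat(coords[None], len(chi), axis=0)
            pos[:, moving] = pts
            u += restraint_scale * np.asarray(
                restraint_energy(pos, sub_restraints, 1.0, masses=topo.masses))
        if not np.all(np.isfinite(u)):
            raise OracleFailureError("non-finite potential in torsion energy function")
        return u if np.ndim(chi_rad) else float(u[0])

    return energy


def _subject_of(set_label: str) -> str:
    return {"dual-RV": "rv", "dual-VR": "vr", "dual": "dual"}[set_label]


def _simpson_log_partition(u_fn, lo: float, hi: float, thermo: ThermoState,
                           tol_kcal: float = 1e-8, max_doublings: int = 14):
    """log integral of exp(-U/RT) over [lo, hi] with Richardson refinement."""
    from scipy.integrate import simpson
    from scipy.special import logsumexp

    beta = 1.0 / thermo.rt_kj
    prev = None
    n = 2 ** 10
    for _ in range(max_doublings):
        x = np.linspace(lo, hi, n + 1)
        u = np.asarray(u_fn(x), dtype=float)
        if not np.all(np.isfinite(u)):
            raise OracleFailureError("non-finite potential during quadrature")
        shift = u.min()
        z = simpson(np.exp(-beta * (u - shift)), x=x)
        logz = np.log(z) - beta * shift
        if prev is not None and abs(logz - prev) / beta / 4.184 < tol_kcal:
            return logz
        prev = logz
        n *= 2
    raise OracleFailureError("quadrature failed to converge to tolerance")


def exact_free_energy_1d(potential, thermo: ThermoState,
                         minima_deg: Sequence[float] | None = None,
                         basin_boundary: Sequence[float] | None = None,
                         tol_kcal: float = 1e-8) -> float:
    """Exact basin-to-basin free-energy difference by quadrature, kcal/mol.

    ``potential`` is a :class:`TorsionProfile` or any callable
    ``U(chi_rad) -> kJ/mol`` that is integrable over the torsion circle (for
    a callable, ``minima_deg`` must name the two basin minima).  Returns
    ``-RT ln(Z_2 / Z_1)`` where ``Z_i`` is the configurational integral of
    ``exp(-U/RT)`` over the basin containing the i-th minimum; for the
    standard anti/syn labelling this is the anti -> syn free energy.  Basin
    edges default to the circular midpoints between the minima but can be
    overridden via ``basin_boundary`` (two angles in degrees).
    """
    if isinstance(potential, TorsionProfile):
        if minima_deg is None:
            minima_deg = potential.locations_deg
        u_fn = potential.energy
    else:
        u_fn = potential
        if minima_deg is None:
            raise ValueError("callable potentials require explicit minima_deg")
    minima_deg = np.asarray(minima_deg, dtype=float)
    if len(minima_deg) != 2:
        raise ValueError("the two-state oracle requires exactly two minima")
    bounds = (np.sort(np.asarray(basin_boundary, dtype=float))
              if basin_boundary is not None else np.sort(basin_boundaries(minima_deg)))
    if len(bounds) != 2:
        raise ValueError("need exactly two basin boundaries")

    c0, c1 = np.radians(bounds)
    arcs = [(c0, c1), (c1, c0 + 2.0 * np.pi)]

    def arc_of(minimum_deg):
        m = np.radians(minimum_deg)
        for lo, hi in arcs:
            if lo <= m < hi or lo <= m + 2 * np.pi < hi:
                return (lo, hi)
        raise OracleFailureError("minimum not contained in any basin arc")

    logz = [_simpson_log_partition(u_fn, *arc_of(m), thermo, tol_kcal=tol_kcal)
            for m in minima_deg]
    return kj_to_kcal(-thermo.rt_kj * (logz[1] - logz[0]))


def exact_cycle_reference(hybrid: ToyTopology, coords: np.ndarray,
                          restraints, thermo: ThermoState,
                          return_details: bool = False):
    """Exact value of the full restrain-FEP-release total for a toy hybrid.

    The cycle total decomposes into the conformational term
    ``-RT ln(Z_syn / Z_anti)`` of the fully coupled rotor in its environment
    plus a ghost term ``-RT ln(z_RV,restr / z_VR,restr)`` from the decoupled,
    restrained copies (whose always-on internal terms do not cancel between
    the two end states in general).  Both terms are one-dimensional
    quadratures for the rigid-rotor toys.  With the standard profile the
    ghost term vanishes to machine precision because the two wells are
    congruent.  Returns kcal/mol.
    """
    if not hybrid.is_hybrid:
        raise InvalidTopologyError("cycle reference requires a hybrid topology")
    u_eff = torsion_energy_function(hybrid, coords, "dual-RV",
                                    include_nonbonded=True)
    prof = hybrid.profile_for("dual-RV").profile
    # orient the reference along the cycle: from the RV copy's starting
    # basin towards the other basin
    chi_rv = torsion(*(coords[i] for i in prof.quadruple))
    locs = prof.locations_deg
    start = int(np.argmin(np.abs(wrap_deg(locs - chi_rv))))
    minima = np.array([locs[start], locs[1 - start]])
    conf = exact_free_energy_1d(u_eff, thermo, minima_deg=minima)

    ghosts = {}
    for label in ("dual-RV", "dual-VR"):
        u_ghost = torsion_energy_function(hybrid, coords, label,
                                          include_nonbonded=False,
                                          restraints=restraints,
                                          restraint_scale=1.0)
        ghosts[label] = _simpson_log_partition(u_ghost, -np.pi, np.pi, thermo)
    ghost_term = kj_to_kcal(-thermo.rt_kj * (ghosts["dual-RV"] - ghosts["dual-VR"]))
    total = conf + ghost_term
    if return_details:
        return total, {"conformational_kcal": conf, "ghost_kcal": ghost_term}
    return total


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def topology_to_dict(topo: ToyTopology, coords: np.ndarray | None = None) -> dict:
    """Plain-JSON representation of a topology (documented schema v1)."""
    d = {
        "schema": "rfepr-toy-topology/1",
        "masses": topo.masses.tolist(),
        "charges": topo.charges.tolist(),
        "lj_epsilon": topo.lj_epsilon.tolist(),
        "lj_sigma": topo.lj_sigma.tolist(),
        "set_labels": topo.set_labels.tolist(),
        "mobility": topo.mobility.tolist(),
        "tethers": [{"index": t.index, "k": t.k, "site": list(t.site)}
                    for t in topo.tethers],
        "bonds": [{"i": b.i, "j": b.j, "k": b.k, "r0": b.r0} for b in topo.bonds],
        "angles": [{"triple": list(a.triple), "k": a.k, "theta0": a.theta0}
                   for a in topo.angles],
        "dihedrals": [{"quadruple": list(t.quadruple), "periodicity": t.periodicity,
                       "barrier": t.barrier, "phase": t.phase,
                       "always_on": t.always_on} for t in topo.dihedrals],
        "profiles": [{"owner": p.owner, "always_on": p.always_on,
                      "quadruple": list(p.profile.quadruple),
                      "minima": [list(m) for m in p.profile.minima]}
                     for p in topo.profiles],
        "exclusions": sorted([list(e) for e in topo.exclusions]),
        "rotors": {lab: {"axis": list(s.axis), "moving": list(s.moving),
                         "quadruple": list(s.quadruple)}
                   for lab, s in topo.rotors.items()},
    }
    if coords is not None:
        d["coords"] = np.asarray(coords, dtype=float).tolist()
    return d


def topology_from_dict(d: dict):
    """Inverse of :func:`topology_to_dict`; returns ``(topo, coords_or_None)``."""
    if d.get("schema") != "rfepr-toy-topology/1":
        raise ValueError("unrecognized topology schema")
    topo = ToyTopology(
        masses=np.array(d["masses"]), charges=np.array(d["charges"]),
        lj_epsilon=np.array(d["lj_epsilon"]), lj_sigma=np.array(d["lj_sigma"]),
        set_labels=np.array(d["set_labels"], dtype=object),
        mobility=np.array(d["mobility"], dtype=object),
        tethers=[Tether(t["index"], t["k"], tuple(t["site"])) for t in d["tethers"]],
        bonds=[BondTerm(b["i"], b["j"], b["k"], b["r0"]) for b in d["bonds"]],
        angles=[AngleTerm(tuple(a["triple"]), a["k"], a["theta0"])
                for a in d["angles"]],
        dihedrals=[DihedralTerm(tuple(t["quadruple"]), t["periodicity"], t["barrier"],
                                t["phase"], t["always_on"]) for t in d["dihedrals"]],
        profiles=[ProfileTerm(TorsionProfile(minima=tuple(tuple(m) for m in p["minima"]),
                                             quadruple=tuple(p["quadruple"])),
                              owner=p["owner"], always_on=p["always_on"])
                  for p in d["profiles"]],
        exclusions={tuple(e) for e in d["exclusions"]},
        rotors={lab: RotorSpec(tuple(s["axis"]), tuple(s["moving"]),
                               tuple(s["quadruple"]))
                for lab, s in d["rotors"].items()},
    )
    coords = np.array(d["coords"]) if "coords" in d else None
    return topo, coords


def save_topology(path, topo: ToyTopology, coords: np.ndarray | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(topology_to_dict(topo, coords), fh, indent=1)


def load_topology(path):
    with open(path) as fh:
        return topology_from_dict(json.load(fh))
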