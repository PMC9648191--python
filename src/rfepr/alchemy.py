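"""Lambda-coupled Hamiltonian: soft-core nonbonded switching of the dual
sets, lambda-scaled harmonic restraints, and reduced potentials.

The coupling follows the three-stage restrain-FEP-release convention:

* **restrain** — the harmonic restraints on the initial (dual-RV) conformer
  ramp up with ``lambda_restraint`` while the final (dual-VR) conformer stays
  fully restrained and decoupled;
* **fep** — both copies stay restrained while the RV copy's van der Waals and
  Coulomb interactions switch off and the VR copy's switch on, through
  Beutler-style soft-core potentials (defaults alpha=0.5, power=1,
  sigma=0.3 nm shared by LJ and Coulomb);
* **release** — the restraints on the now-real VR conformer ramp down.

Proper dihedral terms (including the two-well torsion profiles) of both dual
sets are always on; only vdW and Coulomb interactions are switched.
Restraint lambda-coupling is a linear multiplication of the harmonic energy,
matching GROMACS restraint-lambdas semantics.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np

from .geometry import PseudoDihedralSpec, pseudodihedral, torsion, wrap_rad
from .toy_systems import ToyTopology
from .units import COULOMB_CONSTANT, ThermoState

__all__ = [
    "EvaluationError",
    "SoftCoreParams",
    "LambdaState",
    "TorsionRestraint",
    "DistanceRestraint",
    "AngleRestraint",
    "PseudoDihedralRestraint",
    "RestraintSet",
    "combine_lj",
    "plain_pair_energy",
    "softcore_pair_energy",
    "build_pair_table",
    "restraint_energy",
    "restraint_weights",
    "potential_energy",
    "reduced_potential",
]


class EvaluationError(RuntimeError):
    """An energy term evaluated to a non-finite value."""


@dataclass(frozen=True)
class SoftCoreParams:
    """Beutler soft-core parameters (GROMACS sc-alpha / sc-power / sc-sigma)."""

    alpha: float = 0.5
    power: int = 1
    sigma: float = 0.3

    def __post_init__(self):
        if self.alpha < 0:
            raise ValueError("sc-alpha must be >= 0")
        if self.power < 1 or int(self.power) != self.power:
            raise ValueError("sc-power must be a positive integer")
        if self.sigma <= 0:
            raise ValueError("sc-sigma must be > 0")


_STAGES = ("restrain", "fep", "release")


@dataclass(frozen=True)
class LambdaState:
    """One point of the coupling schedule."""

    stage: str
    lambda_restraint: float
    lambda_coul: float
    lambda_vdw: float
    index: int = 0

    def __post_init__(self):
        if self.stage not in _STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        for name in ("lambda_restraint", "lambda_coul", "lambda_vdw"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")

    @staticmethod
    def restrain_states(values: Iterable[float]) -> list:
        return [LambdaState("restrain", v, 0.0, 0.0, i)
                for i, v in enumerate(values)]

    @staticmethod
    def fep_states(values: Iterable[float]) -> list:
        return [LambdaState("fep", 1.0, v, v, i) for i, v in enumerate(values)]

    @staticmethod
    def release_states(values: Iterable[float]) -> list:
        return [LambdaState("release", v, 1.0, 1.0, i)
                for i, v in enumerate(values)]


def restraint_weights(state: LambdaState) -> dict:
    """Restraint scaling per subject copy for one lambda-state.

    The restrain stage ramps the initial (rv) copy's restraints up; the
    release stage ramps the final (vr) copy's down; during FEP both are held
    at full strength.  Single-state topologies ("dual" subject) scale
    directly with lambda_restraint.
    """
    lr = state.lambda_restraint
    if state.stage == "restrain":
        return {"rv": lr, "vr": 1.0, "dual": lr}
    if state.stage == "fep":
        return {"rv": 1.0, "vr": 1.0, "dual": 1.0}
    return {"rv": 1.0, "vr": lr, "dual": lr}


# ---------------------------------------------------------------------------
# restraints
# ---------------------------------------------------------------------------

def _wrapped(eq: float) -> float:
    return float(wrap_rad(eq))


@dataclass(frozen=True)
class TorsionRestraint:
    quadruple: tuple
    equilibrium: float          # rad
    k: float                    # kJ/mol/rad^2
    subject: str = "dual"

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("restraint force constant must be >= 0")
        object.__setattr__(self, "equilibrium", _wrapped(self.equilibrium))


@dataclass(frozen=True)
class DistanceRestraint:
    pair: tuple
    equilibrium: float          # nm
    k: float                    # kJ/mol/nm^2
    subject: str = "dual"

    def __post_init__(self):
        if self.k < 0 or self.equilibrium < 0:
            raise ValueError("distance restraint needs k >= 0 and r0 >= 0")


@dataclass(frozen=True)
class AngleRestraint:
    triple: tuple
    equilibrium: float          # rad
    k: float                    # kJ/mol/rad^2
    subject: str = "dual"

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("restraint force constant must be >= 0")
        object.__setattr__(self, "equilibrium", _wrapped(self.equilibrium))


@dataclass(frozen=True)
class PseudoDihedralRestraint:
    spec: PseudoDihedralSpec
    equilibrium: float          # rad
    k: float                    # kJ/mol/rad^2
    subject: str = "dual"

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("restraint force constant must be >= 0")
        object.__setattr__(self, "equilibrium", _wrapped(self.equilibrium))


@dataclass(frozen=True)
class RestraintSet:
    """Harmonic restraints grouped by type; default k is 1000 in GROMACS
    units (kJ/mol/rad^2 for angular terms, kJ/mol/nm^2 for distances)."""

    torsions: tuple = ()
    distances: tuple = ()
    angles: tuple = ()
    pseudodihedrals: tuple = ()

    def __iter__(self):
        yield from self.torsions
        yield from self.distances
        yield from self.angles
        yield from self.pseudodihedrals

    def __len__(self):
        return (len(self.torsions) + len(self.distances) + len(self.angles)
                + len(self.pseudodihedrals))

    def for_subject(self, subject: str) -> "RestraintSet":
        return RestraintSet(
            torsions=tuple(r for r in self.torsions if r.subject == subject),
            distances=tuple(r for r in self.distances if r.subject == subject),
            angles=tuple(r for r in self.angles if r.subject == subject),
            pseudodihedrals=tuple(r for r in self.pseudodihedrals
                                  if r.subject == subject),
        )

    @property
    def subjects(self) -> set:
        return {r.subject for r in self}


def _bend_angle(a, b, c):
    """Angle at vertex b, radians, broadcasting over leading axes."""
    v1 = a - b
    v2 = c - b
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    cosang = np.clip(np.sum(v1 * v2, axis=-1) / (n1 * n2), -1.0, 1.0)
    return np.arccos(cosang)


def restraint_energy(coords, restraints: RestraintSet, lambda_restraint: float,
                     masses=None):
    """lambda-scaled harmonic restraint energy, kJ/mol.

    ``coords`` has shape ``(..., n, 3)`` and the result broadcasts over the
    leading axes.  Angular deviations are wrapped to (-pi, pi] (minimal image
    on the circle).  At ``lambda_restraint == 0`` the energy is identically
    zero and the geometry is not evaluated; otherwise degenerate geometry
    raises :class:`~rfepr.geometry.UndefinedAngleError` rather than being
    silently ignored.
    """
    coords = np.asarray(coords, dtype=float)
    lead = coords.shape[:-2]
    if lambda_restraint == 0.0 or len(restraints) == 0:
        return np.zeros(lead) if lead else 0.0
    e = np.zeros(lead) if lead else 0.0
    for r in restraints.torsions:
        i, j, k, l = r.quadruple
        phi = np.radians(torsion(coords[..., i, :], coords[..., j, :],
                                 coords[..., k, :], coords[..., l, :]))
        e = e + 0.5 * r.k * np.square(wrap_rad(phi - r.equilibrium))
    for r in restraints.distances:
        i, j = r.pair
        d = np.linalg.norm(coords[..., i, :] - coords[..., j, :], axis=-1)
        e = e + 0.5 * r.k * np.square(d - r.equilibrium)
    for r in restraints.angles:
        i, j, k = r.triple
        th = _bend_angle(coords[..., i, :], coords[..., j, :], coords[..., k, :])
        e = e + 0.5 * r.k * np.square(wrap_rad(th - r.equilibrium))
    for r in restraints.pseudodihedrals:
        phi = np.radians(pseudodihedral(r.spec, coords, masses))
        e = e + 0.5 * r.k * np.square(wrap_rad(phi - r.equilibrium))
    e = lambda_restraint * e
    return e if lead else float(e)


# ---------------------------------------------------------------------------
# nonbonded
# ---------------------------------------------------------------------------

def combine_lj(eps_i, eps_j, sig_i, sig_j):
    """Lorentz-Berthelot combination: geometric epsilon, arithmetic sigma."""
    return np.sqrt(eps_i * eps_j), 0.5 * (sig_i + sig_j)


def plain_pair_energy(r, qq, epsilon, sigma):
    """Unsoftened LJ 12-6 plus Coulomb energy, kJ/mol (broadcasting)."""
    r = np.asarray(r, dtype=float)
    sr6 = np.power(sigma / r, 6)
    return 4.0 * epsilon * (sr6 * sr6 - sr6) + COULOMB_CONSTANT * qq / r


class PairEndState(NamedTuple):
    """Combined pair parameters of one alchemical end state."""

    qq: float
    epsilon: float
    sigma: float


GHOST = PairEndState(0.0, 0.0, 0.3)


def _soft_r(r, r6, lam, sc: SoftCoreParams):
    shift = sc.alpha * sc.sigma ** 6 * lam ** sc.power
    if shift == 0.0:
        # endpoint: return r itself so the unsoftened potential is
        # recovered bit-exactly (no (r^6)^(1/6) round trip)
        return r
    return np.power(shift + r6, 1.0 / 6.0)


def softcore_pair_energy(r, lambda_coul, lambda_vdw,
                         params_a: PairEndState, params_b: PairEndState,
                         sc: SoftCoreParams = SoftCoreParams()):
    """Beutler soft-core interpolated pair energy, kJ/mol.

    The A end state vanishes as lambda -> 1 and sees the shifted radius
    ``r_A = (alpha sigma^6 lambda^p + r^6)^(1/6)``; the B end state vanishes
    as lambda -> 0 with the mirrored shift.  The same shifted radius form is
    applied to both the LJ and Coulomb parts, each with its own coupling
    parameter.  Finite at r = 0 for any lambda strictly inside (0, 1); at the
    endpoints the unsoftened end-state potentials are recovered exactly.
    """
    r = np.asarray(r, dtype=float)
    r6 = np.power(r, 6)
    pa, pb = PairEndState(*params_a), PairEndState(*params_b)
    e = np.zeros_like(r)

    def lj(reff, p):
        sr6 = np.power(p.sigma / reff, 6)      # same form as the plain kernel
        return 4.0 * p.epsilon * (sr6 * sr6 - sr6)

    def coul(reff, p):
        return COULOMB_CONSTANT * p.qq / reff

    with np.errstate(divide="ignore", invalid="ignore"):
        if lambda_vdw < 1.0 and pa.epsilon != 0.0:
            e = e + (1.0 - lambda_vdw) * lj(_soft_r(r, r6, lambda_vdw, sc), pa)
        if lambda_vdw > 0.0 and pb.epsilon != 0.0:
            e = e + lambda_vdw * lj(_soft_r(r, r6, 1.0 - lambda_vdw, sc), pb)
        if lambda_coul < 1.0 and pa.qq != 0.0:
            e = e + (1.0 - lambda_coul) * coul(_soft_r(r, r6, lambda_coul, sc), pa)
        if lambda_coul > 0.0 and pb.qq != 0.0:
            e = e + lambda_coul * coul(_soft_r(r, r6, 1.0 - lambda_coul, sc), pb)
    return e if e.ndim else float(e)


@dataclass(frozen=True)
class PairTable:
    """Precomputed dual-set/shared-set interacting pair list."""

    set_label: str
    i_idx: np.ndarray
    j_idx: np.ndarray
    qq: np.ndarray
    epsilon: np.ndarray
    sigma: np.ndarray


def build_pair_table(topo: ToyTopology, set_label: str) -> PairTable:
    """All nonbonded pairs between one dual set and the shared set.

    The toy nonbonded model is exact pairwise between dual and shared
    particles only (no cutoff, no intra-set terms); excluded and
    zero-parameter pairs are dropped.
    """
    di = topo.indices(set_label)
    sj = topo.indices("shared")
    ii, jj, qq, ee, ss = [], [], [], [], []
    for i in di:
        for j in sj:
            key = (int(min(i, j)), int(max(i, j)))
            if key in topo.exclusions or (int(i), int(j)) in topo.exclusions:
                continue
            q = topo.charges[i] * topo.charges[j]
            eps, sig = combine_lj(topo.lj_epsilon[i], topo.lj_epsilon[j],
                                  topo.lj_sigma[i], topo.lj_sigma[j])
            if q == 0.0 and eps == 0.0:
                continue
            ii.append(int(i)); jj.append(int(j))
            qq.append(q); ee.append(eps); ss.append(sig)
    return PairTable(set_label, np.array(ii, dtype=int), np.array(jj, dtype=int),
                     np.array(qq), np.array(ee), np.array(ss))


def set_coupling(state: LambdaState, set_label: str) -> tuple:
    """(lambda_coul, lambda_vdw, a_is_real) for one dual set.

    dual-RV is real at lambda=0 (A end state real, B ghost); dual-VR is the
    mirror image; a plain "dual" set is always fully coupled.
    """
    if set_label == "dual-RV":
        return state.lambda_coul, state.lambda_vdw, True
    if set_label == "dual-VR":
        return state.lambda_coul, state.lambda_vdw, False
    return 0.0, 0.0, True


def _set_nonbonded(coords, table: PairTable, state: LambdaState,
                   sc: SoftCoreParams):
    if len(table.i_idx) == 0:
        lead = np.asarray(coords).shape[:-2]
        return np.zeros(lead) if lead else 0.0
    coords = np.asarray(coords, dtype=float)
    r = np.linalg.norm(np.take(coords, table.i_idx, axis=-2)
                       - np.take(coords, table.j_idx, axis=-2), axis=-1)
    lc, lv, a_real = set_coupling(state, table.set_label)
    e = np.zeros_like(r)
    for n in range(len(table.i_idx)):
        real = PairEndState(table.qq[n], table.epsilon[n], table.sigma[n])
        pa, pb = (real, GHOST._replace(sigma=table.sigma[n])) if a_real \
            else (GHOST._replace(sigma=table.sigma[n]), real)
        e[..., n] = softcore_pair_energy(r[..., n], lc, lv, pa, pb, sc)
    return e.sum(axis=-1)


def _set_nonbonded_fast(coords, table: PairTable, state: LambdaState,
                        sc: SoftCoreParams):
    """Vectorized over pairs for the common real<->ghost switching case."""
    if len(table.i_idx) == 0:
        lead = np.asarray(coords).shape[:-2]
        return np.zeros(lead) if lead else 0.0
    coords = np.asarray(coords, dtype=float)
    r = np.linalg.norm(np.take(coords, table.i_idx, axis=-2)
                       - np.take(coords, table.j_idx, axis=-2), axis=-1)
    lc, lv, a_real = set_coupling(state, table.set_label)
    # weight and soft-core shift for the *real* end state
    if a_real:
        w_v, w_c, shift_v, shift_c = 1.0 - lv, 1.0 - lc, lv, lc
    else:
        w_v, w_c, shift_v, shift_c = lv, lc, 1.0 - lv, 1.0 - lc
    r6 = np.power(r, 6)
    e = np.zeros_like(r)
    with np.errstate(divide="ignore", invalid="ignore"):
        if w_v != 0.0:
            ra6 = sc.alpha * sc.sigma ** 6 * shift_v ** sc.power + r6
            sr6 = np.power(table.sigma, 6) / ra6
            e += w_v * 4.0 * table.epsilon * (sr6 * sr6 - sr6)
        if w_c != 0.0:
            shift = sc.alpha * sc.sigma ** 6 * shift_c ** sc.power
            ra = r if shift == 0.0 else np.power(shift + r6, 1.0 / 6.0)
            e += w_c * COULOMB_CONSTANT * table.qq / ra
    return e.sum(axis=-1)


# ---------------------------------------------------------------------------
# full potential
# ---------------------------------------------------------------------------

def _check_finite(e, term: str):
    if not np.all(np.isfinite(e)):
        raise EvaluationError(f"non-finite energy in term: {term}")
    return e


def potential_energy(coords, topo: ToyTopology, restraints: RestraintSet | None,
                     state: LambdaState, sc: SoftCoreParams = SoftCoreParams(),
                     pair_tables: dict | None = None):
    """Total potential energy (kJ/mol) of configuration(s) at a lambda-state.

    ``coords`` has shape ``(..., n, 3)``; the result broadcasts.  Bonded
    terms (bonds, angles, cosine dihedrals, torsion profiles) and tethers are
    lambda-independent; dual-set nonbonded terms scale with the coupling of
    their set; restraints scale per the stage convention of
    :func:`restraint_weights`.
    """
    coords = np.asarray(coords, dtype=float)
    lead = coords.shape[:-2]
    e = np.zeros(lead) if lead else 0.0

    for b in topo.bonds:
        d = np.linalg.norm(coords[..., b.i, :] - coords[..., b.j, :], axis=-1)
        e = e + 0.5 * b.k * np.square(d - b.r0)
    for a in topo.angles:
        i, j, k = a.triple
        th = _bend_angle(coords[..., i, :], coords[..., j, :], coords[..., k, :])
        e = e + 0.5 * a.k * np.square(wrap_rad(th - a.theta0))
    for t in topo.dihedrals:
        i, j, k, l = t.quadruple
        phi = np.radians(torsion(coords[..., i, :], coords[..., j, :],
                                 coords[..., k, :], coords[..., l, :]))
        e = e + t.barrier * (1.0 + np.cos(t.periodicity * phi - t.phase))
    for p in topo.profiles:
        i, j, k, l = p.profile.quadruple
        chi = np.radians(torsion(coords[..., i, :], coords[..., j, :],
                                 coords[..., k, :], coords[..., l, :]))
        e = e + p.profile.energy(chi)
    for t in topo.tethers:
        d2 = np.sum(np.square(coords[..., t.index, :] - np.asarray(t.site)), axis=-1)
        e = e + 0.5 * t.k * d2
    _check_finite(e, "bonded/tether")

    for label in topo.dual_set_labels:
        table = (pair_tables or {}).get(label) or build_pair_table(topo, label)
        e = e + _check_finite(_set_nonbonded_fast(coords, table, state, sc),
                              f"nonbonded[{label}]")

    if restraints is not None and len(restraints):
        weights = restraint_weights(state)
        for subject in sorted(restraints.subjects):
            w = weights.get(subject, state.lambda_restraint)
            e = e + _check_finite(
                restraint_energy(coords, restraints.for_subject(subject), w,
                                 masses=topo.masses),
                f"restraints[{subject}]")
    return e if lead else float(e)


def reduced_potential(coords, topo: ToyTopology, restraints: RestraintSet | None,
                      state: LambdaState, thermo: ThermoState,
                      sc: SoftCoreParams = SoftCoreParams(),
                      pair_tables: dict | None = None):
    """Dimensionless reduced potential u = U / RT (broadcasting)."""
    return potential_energy(coords, topo, restraints, state, sc,
                            pair_tables) / thermo.rt_kj
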