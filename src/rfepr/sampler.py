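"""Metropolis Monte Carlo sampling of the toy lambda-states, cross-state
reduced-potential collection, and time-series decorrelation.

The move set mixes collective torsion rotations of the dual-set rotors with
single-particle Cartesian displacements of the tethered mobile particles.
Monte Carlo replaces molecular dynamics here deliberately: the estimand is a
configurational free-energy difference, which is independent of dynamics, so
a detailed-balance-satisfying chain at each lambda-state's reduced potential
is all the estimators require.  Step sizes are auto-tuned during burn-in to
a 30-50% acceptance window, and the first 10% of sweeps are discarded by
default.  Per-state seeds are derived from a master seed by
``numpy.random.SeedSequence`` spawning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .alchemy import (RestraintSet, LambdaState, SoftCoreParams,
                      _set_nonbonded_fast, build_pair_table, reduced_potential,
                      restraint_energy, restraint_weights)
from .toy_systems import ToyTopology
from .geometry import torsion
from .units import ThermoState

__all__ = [
    "SamplerSetupError",
    "StepAdaptationError",
    "MismatchError",
    "Trajectory",
    "ReducedPotentialMatrix",
    "metropolis_sample",
    "trajectory_coords",
    "collect_u_kn",
    "statistical_inefficiency",
]


class SamplerSetupError(ValueError):
    """The topology violates the assumptions of the rotor/displacement moves."""


class StepAdaptationError(RuntimeError):
    """Step-size adaptation could not reach a usable acceptance rate."""


class MismatchError(ValueError):
    """Trajectory provenance inconsistent with the requested state list."""


def rigid_rotation(rel: np.ndarray, axis_dir: np.ndarray, delta):
    """Rodrigues rotation of vectors ``rel`` about ``axis_dir`` by ``delta``.

    ``rel`` is (m, 3); ``delta`` a scalar or (F,).  Returns (m, 3) or
    (F, m, 3).
    """
    delta_arr = np.atleast_1d(np.asarray(delta, dtype=float))
    c = np.cos(delta_arr)[:, None, None]
    s = np.sin(delta_arr)[:, None, None]
    kxr = np.cross(axis_dir, rel)
    kdr = rel @ axis_dir
    out = rel[None] * c + kxr[None] * s + np.outer(kdr, axis_dir)[None] * (1.0 - c)
    return out if np.ndim(delta) else out[0]


@dataclass
class Trajectory:
    """Stored Monte Carlo configurations for one lambda-state.

    Configurations are equally spaced (every ``thin`` sweeps after burn-in).
    The compressed representation stores each rotor's torsion angle and the
    mobile particles' coordinates; :func:`trajectory_coords` reconstructs
    full coordinate frames.
    """

    state: LambdaState
    seed: object
    n_sweeps: int
    burn_in: int
    thin: int
    chi: dict                      # set label -> (F,) torsion angles, rad
    mobile_indices: np.ndarray
    mobile: np.ndarray             # (F, m, 3)
    sweep_indices: np.ndarray
    acceptance: dict = field(default_factory=dict)
    step_sizes: dict = field(default_factory=dict)
    move_log: list | None = None

    @property
    def n_frames(self) -> int:
        return len(self.sweep_indices)


class _RotorMover:
    """Energy of one rotor set as a function of its torsion angle, at a
    fixed lambda-state, with everything chi-independent dropped."""

    def __init__(self, topo, coords0, label, restraints, state, sc, thermo):
        spec = topo.rotors[label]
        self.label = label
        self.moving = np.asarray(spec.moving, dtype=int)
        self.axis_pt = coords0[spec.axis[0]].copy()
        axis = coords0[spec.axis[1]] - coords0[spec.axis[0]]
        self.axis_dir = axis / np.linalg.norm(axis)
        self.profile = topo.profile_for(label).profile
        quad = self.profile.quadruple
        self.chi0 = np.radians(torsion(*(coords0[i] for i in quad)))
        self.rel = coords0[self.moving] - self.axis_pt
        self.table = build_pair_table(topo, label)
        if len(self.table.i_idx):
            bad = topo.mobility[self.table.j_idx] != "static"
            if np.any(bad):
                raise SamplerSetupError(
                    f"rotor {label}: nonbonded partners must be static particles")
        subject = {"dual-RV": "rv", "dual-VR": "vr"}.get(label, "dual")
        sub = restraints.for_subject(subject) if restraints is not None else None
        self.restraints = sub if sub is not None and len(sub) else None
        self.weight = restraint_weights(state)[subject]
        # fast path: torsion restraints on the rotor's own quadruple are a
        # closed function of chi and need no geometry evaluation
        self.own_torsion_restraints = None
        if (self.restraints is not None
                and len(self.restraints.torsions) == len(self.restraints)
                and all(tuple(r.quadruple) == tuple(quad)
                        for r in self.restraints.torsions)):
            self.own_torsion_restraints = [(r.k, r.equilibrium)
                                           for r in self.restraints.torsions]
            self.restraints = None
        if self.restraints is not None:
            moving_set = set(self.moving.tolist())
            for r in self.restraints:
                idx = _restraint_indices(r)
                for i in idx:
                    if i not in moving_set and topo.mobility[i] != "static":
                        raise SamplerSetupError(
                            f"rotor {label}: restraint references mobile particle {i}")
        self.state = state
        self.sc = sc
        self.masses = topo.masses
        self.pos = coords0.copy()
        self.beta = 1.0 / thermo.rt_kj
        # orientation of the rotation axis relative to the torsion sign
        probe = 0.1
        self.sign = 1.0
        self.pos[self.moving] = rigid_rotation(self.rel, self.axis_dir,
                                               probe) + self.axis_pt
        chi_probe = np.radians(torsion(*(self.pos[i] for i in quad)))
        if abs(float(np.angle(np.exp(1j * (chi_probe - self.chi0 - probe))))) > 1e-6:
            self.sign = -1.0
        self.pos[self.moving] = coords0[self.moving]

    def energy(self, chi: float) -> float:
        """Energy at true torsion angle ``chi`` (rad) of this rotor."""
        pos = self.pos
        pos[self.moving] = rigid_rotation(self.rel, self.axis_dir,
                                          self.sign * (chi - self.chi0)) \
            + self.axis_pt
        e = self.profile.energy(chi)
        e += _set_nonbonded_fast(pos, self.table, self.state, self.sc)
        if self.own_torsion_restraints is not None and self.weight > 0.0:
            for k, eq in self.own_torsion_restraints:
                d = (chi - eq + np.pi) % (2.0 * np.pi) - np.pi
                e += self.weight * 0.5 * k * d * d
        elif self.restraints is not None and self.weight > 0.0:
            e += restraint_energy(pos, self.restraints, self.weight,
                                  masses=self.masses)
        return float(e)


def _restraint_indices(r):
    if hasattr(r, "quadruple"):
        return list(r.quadruple)
    if hasattr(r, "pair"):
        return list(r.pair)
    if hasattr(r, "triple"):
        return list(r.triple)
    return [i for g in r.spec.groups for i in g]


def metropolis_sample(topo: ToyTopology, coords0: np.ndarray,
                      restraints: RestraintSet | None, state: LambdaState,
                      n_sweeps: int, seed, thermo: ThermoState, *,
                      thin: int = 5, burn_in_fraction: float = 0.1,
                      rotor_step_deg: float = 12.0, particle_step: float = 0.06,
                      jump_prob: float = 0.0, adapt: bool = True,
                      sc: SoftCoreParams = SoftCoreParams(),
                      log_moves: bool = False) -> Trajectory:
    """Sample one lambda-state with Metropolis Monte Carlo.

    One sweep attempts one collective rotation per rotor set and one
    displacement per tethered particle.  ``jump_prob`` mixes in uniform
    (basin-hopping) torsion proposals - useful for unbiased population
    studies, off by default so that endpoint states remain confined to their
    starting basin, mirroring the kinetic trapping of the molecular problem.

    Returns a :class:`Trajectory`; identical seeds give bit-identical runs.
    """
    if n_sweeps <= 0:
        raise ValueError("n_sweeps must be positive")
    rng = np.random.default_rng(seed)
    beta = 1.0 / thermo.rt_kj
    coords0 = np.asarray(coords0, dtype=float)

    rotor_labels = [lab for lab in topo.dual_set_labels if lab in topo.rotors]
    movers = {lab: _RotorMover(topo, coords0, lab, restraints, state, sc, thermo)
              for lab in rotor_labels}
    chi_cur = {lab: movers[lab].chi0 for lab in rotor_labels}
    e_cur = {lab: movers[lab].energy(chi_cur[lab]) for lab in rotor_labels}

    mobile_idx = np.flatnonzero(topo.mobility == "tethered")
    tether_map = {t.index: t for t in topo.tethers}
    for i in mobile_idx:
        if int(i) not in tether_map:
            raise SamplerSetupError(f"tethered particle {i} has no tether term")
        if topo.charges[i] != 0.0 or topo.lj_epsilon[i] != 0.0:
            raise SamplerSetupError(
                "mobile particles must carry zero nonbonded parameters")
    mob = coords0[mobile_idx].copy()
    sites = np.array([tether_map[int(i)].site for i in mobile_idx]) \
        if len(mobile_idx) else np.zeros((0, 3))
    tks = np.array([tether_map[int(i)].k for i in mobile_idx])

    burn_in = int(burn_in_fraction * n_sweeps)
    steps = {lab: np.radians(rotor_step_deg) for lab in rotor_labels}
    steps["particle"] = particle_step
    acc = {lab: [0, 0] for lab in rotor_labels}
    acc["particle"] = [0, 0]
    block = {key: [0, 0] for key in steps}
    log: list | None = [] if log_moves else None

    frames_chi = {lab: [] for lab in rotor_labels}
    frames_mob, frames_sweep = [], []

    for sweep in range(n_sweeps):
        in_burn = sweep < burn_in
        for lab in rotor_labels:
            jump = jump_prob > 0.0 and rng.random() < jump_prob
            if jump:
                chi_new = rng.uniform(-np.pi, np.pi)
            else:
                chi_new = chi_cur[lab] + rng.normal(0.0, steps[lab])
            e_new = movers[lab].energy(chi_new)
            du = beta * (e_new - e_cur[lab])
            p_acc = 1.0 if du <= 0 else float(np.exp(-du))
            accepted = rng.random() < p_acc
            if log is not None:
                log.append({"kind": lab, "jump": jump, "du": du,
                            "p_acc": p_acc, "accepted": bool(accepted)})
            if accepted:
                chi_cur[lab], e_cur[lab] = chi_new, e_new
            if not in_burn:
                acc[lab][0] += accepted
                acc[lab][1] += 1
            elif not jump:
                block[lab][0] += accepted
                block[lab][1] += 1
        for mi in range(len(mobile_idx)):
            disp = rng.normal(0.0, steps["particle"], 3)
            x_new = mob[mi] + disp
            du = beta * 0.5 * tks[mi] * (np.sum(np.square(x_new - sites[mi]))
                                         - np.sum(np.square(mob[mi] - sites[mi])))
            p_acc = 1.0 if du <= 0 else float(np.exp(-du))
            accepted = rng.random() < p_acc
            if log is not None:
                log.append({"kind": "particle", "jump": False, "du": du,
                            "p_acc": p_acc, "accepted": bool(accepted)})
            if accepted:
                mob[mi] = x_new
            if not in_burn:
                acc["particle"][0] += accepted
                acc["particle"][1] += 1
            else:
                block["particle"][0] += accepted
                block["particle"][1] += 1

        if adapt and in_burn and (sweep + 1) % 50 == 0:
            for key, (a, n) in block.items():
                if n == 0:
                    continue
                frac = a / n
                if frac > 0.5:
                    steps[key] *= 1.3
                elif frac < 0.3:
                    steps[key] /= 1.3
                block[key] = [0, 0]

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            for lab in rotor_labels:
                frames_chi[lab].append(chi_cur[lab])
            frames_mob.append(mob.copy())
            frames_sweep.append(sweep)

    acceptance = {key: (a / n if n else float("nan")) for key, (a, n) in acc.items()}
    for key, rate in acceptance.items():
        _, n = acc[key]
        if n > 100 and rate == 0.0:
            raise StepAdaptationError(
                f"zero acceptance for move type {key!r} after adaptation")

    return Trajectory(
        state=state, seed=repr(seed), n_sweeps=n_sweeps, burn_in=burn_in,
        thin=thin,
        chi={lab: np.array(v) for lab, v in frames_chi.items()},
        mobile_indices=mobile_idx,
        mobile=(np.array(frames_mob) if frames_mob
                else np.zeros((0, len(mobile_idx), 3))),
        sweep_indices=np.array(frames_sweep, dtype=int),
        acceptance=acceptance,
        step_sizes={k: float(v) for k, v in steps.items()},
        move_log=log,
    )


def trajectory_coords(traj: Trajectory, topo: ToyTopology,
                      coords0: np.ndarray) -> np.ndarray:
    """Reconstruct full (F, n, 3) coordinate frames from a trajectory."""
    coords0 = np.asarray(coords0, dtype=float)
    frames = np.repeat(coords0[None], traj.n_frames, axis=0)
    for lab, chis in traj.chi.items():
        spec = topo.rotors[lab]
        moving = np.asarray(spec.moving, dtype=int)
        axis_pt = coords0[spec.axis[0]]
        axis = coords0[spec.axis[1]] - coords0[spec.axis[0]]
        axis_dir = axis / np.linalg.norm(axis)
        quad = topo.profile_for(lab).profile.quadruple
        chi0 = np.radians(torsion(*(coords0[i] for i in quad)))
        rel = coords0[moving] - axis_pt
        frames[:, moving] = rigid_rotation(rel, axis_dir, chis - chi0) + axis_pt
    if len(traj.mobile_indices):
        frames[:, traj.mobile_indices] = traj.mobile
    return frames


@dataclass
class ReducedPotentialMatrix:
    """u_kn: every stored sample evaluated in every lambda-state of a stage.

    Rows index the K states (in schedule order), columns the N pooled
    samples, grouped by origin state and time-ordered within each group;
    ``n_k`` records the per-state sample counts.
    """

    u_kn: np.ndarray
    n_k: np.ndarray
    states: list | None = None

    def __post_init__(self):
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.n_k = np.asarray(self.n_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be 2-D (K x N)")
        if self.u_kn.shape[1] != int(self.n_k.sum()):
            raise ValueError("sum of n_k must equal the number of samples")
        if len(self.n_k) != self.u_kn.shape[0]:
            raise ValueError("n_k length must equal the number of states")
        if not np.all(np.isfinite(self.u_kn)):
            raise ValueError("u_kn contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]

    def block_slice(self, k: int) -> slice:
        start = int(self.n_k[:k].sum())
        return slice(start, start + int(self.n_k[k]))

    def own_series(self, k: int) -> np.ndarray:
        """Time series u_k(x) over state k's own samples."""
        return self.u_kn[k, self.block_slice(k)]

    def subsample(self, g_values=None) -> "ReducedPotentialMatrix":
        """Decimate each state's block to approximately independent samples.

        ``g_values`` may give per-state statistical inefficiencies; when
        omitted they are estimated from each state's own reduced-potential
        series.
        """
        keep, new_nk = [], []
        for k in range(self.n_states):
            sl = self.block_slice(k)
            if g_values is not None:
                g = float(g_values[k])
            else:
                series = self.own_series(k)
                g = statistical_inefficiency(series) if len(series) >= 10 else 1.0
            stride = max(1, int(np.ceil(g)))
            idx = np.arange(sl.start, sl.stop, stride)
            keep.append(idx)
            new_nk.append(len(idx))
        idx = np.concatenate(keep)
        return ReducedPotentialMatrix(self.u_kn[:, idx], np.array(new_nk),
                                      states=self.states)


def collect_u_kn(trajectories: list, states: list, topo: ToyTopology,
                 restraints: RestraintSet | None, thermo: ThermoState,
                 coords0: np.ndarray,
                 sc: SoftCoreParams = SoftCoreParams()) -> ReducedPotentialMatrix:
    """Cross-evaluate stored configurations under every state of a stage."""
    if len(trajectories) != len(states):
        raise MismatchError(
            f"{len(trajectories)} trajectories for {len(states)} states")
    for traj, st in zip(trajectories, states):
        if traj.state != st:
            raise MismatchError(
                f"trajectory sampled at {traj.state} listed under {st}")
        if traj.n_frames < 1:
            raise MismatchError("every state needs at least one stored sample")

    frames = np.concatenate(
        [trajectory_coords(t, topo, coords0) for t in trajectories])
    n_k = np.array([t.n_frames for t in trajectories], dtype=int)
    tables = {lab: build_pair_table(topo, lab) for lab in topo.dual_set_labels}
    u_kn = np.empty((len(states), len(frames)))
    for k, st in enumerate(states):
        u_kn[k] = reduced_potential(frames, topo, restraints, st, thermo,
                                    sc=sc, pair_tables=tables)
    return ReducedPotentialMatrix(u_kn, n_k, states=list(states))


def statistical_inefficiency(series, max_lag: int | None = None) -> float:
    """Statistical inefficiency g = 1 + 2 * sum of autocorrelations.

    The autocorrelation sum is truncated at the first nonpositive value and
    the result is clamped to g >= 1.  A constant series is fully correlated:
    g is defined as the series length and a warning is emitted.  Series
    shorter than 10 raise ``ValueError``.
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short for inefficiency estimation (need >= 10)")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var == 0.0:
        warnings.warn("constant series: statistical inefficiency set to its length",
                      RuntimeWarning, stacklevel=2)
        return float(n)
    g = 1.0
    upper = max_lag if max_lag is not None else n - 1
    for t in range(1, upper + 1):
        c = float(np.dot(x[:-t], x[t:])) / ((n - t) * var)
        if c <= 0.0:
            break
        g += 2.0 * c
    return max(g, 1.0)
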