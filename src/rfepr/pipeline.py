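"""Orchestration of the full restrain-FEP-release cycle on a toy system.

The cycle follows the three-stage thermodynamic path: the initial conformer
(anti by default) starts real and unrestrained with the final conformer's
copy restrained and decoupled; restraints on the initial copy are switched
on (restrain), the nonbonded interactions are swapped between the copies
(FEP), and the restraints on the final copy are switched off (release).
Stage free energies are estimated by MBAR and summed exactly as estimated
along the arrows, so the total is the initial -> final conformational free
energy with the restraint contributions cancelling across the cycle.

Default lambda schedules: restrain (0.0, 0.05, 0.25, 0.5, 0.75, 1.0);
FEP (0.0, 0.01, 0.025, 0.05, 0.1, 0.2, 0.35, 0.5, 0.65, 0.8, 0.9, 0.95,
0.975, 0.99, 1.0); release (1.0, 0.75, 0.5, 0.25, 0.05, 0.0).
"""

from __future__ import annotations

import json
import logging
import sys
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _version
from .alchemy import (AngleRestraint, DistanceRestraint, LambdaState,
                      PseudoDihedralRestraint, RestraintSet, SoftCoreParams,
                      TorsionRestraint)
from .estimators import (ConvergenceSeries, forward_reverse, mbar_solve,
                         overlap_matrix)
from .geometry import PseudoDihedralSpec, pseudodihedral, torsion
from .sampler import (ReducedPotentialMatrix, collect_u_kn, metropolis_sample,
                      statistical_inefficiency)
from .toy_systems import (TorsionProfile, build_hybrid_topology,
                          build_torsion_toy)
from .units import ThermoState

logger = logging.getLogger("rfepr")

__all__ = [
    "DEFAULT_RESTRAIN_SCHEDULE",
    "DEFAULT_FEP_SCHEDULE",
    "DEFAULT_RELEASE_SCHEDULE",
    "CycleConfig",
    "StageResult",
    "CycleReport",
    "build_standard_system",
    "run_rfepr",
    "report_render",
    "write_dhdl_xvg",
    "read_dhdl_xvg",
    "XvgFormatError",
    "write_u_kn_csv",
    "read_u_kn_csv",
]

DEFAULT_RESTRAIN_SCHEDULE = (0.0, 0.05, 0.25, 0.5, 0.75, 1.0)
DEFAULT_FEP_SCHEDULE = (0.0, 0.01, 0.025, 0.05, 0.1, 0.2, 0.35, 0.5,
                        0.65, 0.8, 0.9, 0.95, 0.975, 0.99, 1.0)
DEFAULT_RELEASE_SCHEDULE = (1.0, 0.75, 0.5, 0.25, 0.05, 0.0)

DEFAULT_PROFILE_MINIMA = ((-105.0, 40.0, 200.0), (64.0, 40.0, 200.0))


@dataclass
class CycleConfig:
    """Full configuration of one restrain-FEP-release toy calculation."""

    master_seed: int = 1
    temperature: float = 300.0
    n_shared: int = 8
    n_dual: int = 6
    profile_minima: tuple = DEFAULT_PROFILE_MINIMA
    direction: str = "anti_to_syn"            # or "syn_to_anti"
    restraint_k_angular: float = 1000.0       # kJ/mol/rad^2
    restraint_k_distance: float = 1000.0      # kJ/mol/nm^2
    restraint_types: tuple = ("torsion",)
    restrain_schedule: tuple = DEFAULT_RESTRAIN_SCHEDULE
    fep_schedule: tuple = DEFAULT_FEP_SCHEDULE
    release_schedule: tuple = DEFAULT_RELEASE_SCHEDULE
    sweeps_per_state: int = 10000
    thin: int = 5
    burn_in_fraction: float = 0.1
    decorrelation: str = "inflate"            # inflate | subsample | none
    estimator: str = "mbar"
    convergence_fractions: tuple = tuple(np.round(np.arange(1, 11) * 0.1, 10))
    sc_alpha: float = 0.5
    sc_power: int = 1
    sc_sigma: float = 0.3

    def __post_init__(self):
        if self.direction not in ("anti_to_syn", "syn_to_anti"):
            raise ValueError("direction must be anti_to_syn or syn_to_anti")
        for name, sched, closed in (("restrain", self.restrain_schedule, (0.0, 1.0)),
                                    ("fep", self.fep_schedule, (0.0, 1.0)),
                                    ("release", self.release_schedule, (1.0, 0.0))):
            sched = tuple(float(v) for v in sched)
            if sched[0] != closed[0] or sched[-1] != closed[1]:
                raise ValueError(f"{name} schedule must span {closed[0]} -> {closed[1]}")
        if self.estimator != "mbar":
            raise ValueError("only the mbar estimator drives the cycle")
        if self.decorrelation not in ("inflate", "subsample", "none"):
            raise ValueError("decorrelation must be inflate, subsample or none")

    @property
    def softcore(self) -> SoftCoreParams:
        return SoftCoreParams(self.sc_alpha, self.sc_power, self.sc_sigma)

    @property
    def thermo(self) -> ThermoState:
        return ThermoState(self.temperature)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["profile_minima"] = [list(m) for m in self.profile_minima]
        for key in ("restrain_schedule", "fep_schedule", "release_schedule",
                    "convergence_fractions"):
            d[key] = [float(v) for v in d[key]]
        d["restraint_types"] = list(self.restraint_types)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CycleConfig":
        d = dict(d)
        if "profile_minima" in d:
            d["profile_minima"] = tuple(tuple(m) for m in d["profile_minima"])
        for key in ("restrain_schedule", "fep_schedule", "release_schedule",
                    "convergence_fractions", "restraint_types"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CycleConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


def build_standard_system(config: CycleConfig):
    """Build the hybrid toy system and its restraints for a cycle run.

    Returns ``(hybrid_topology, coords, restraints)``.  The initial
    conformer (per ``config.direction``) becomes the dual-RV copy.  Each
    copy carries a glycosyl-like torsion restraint at its basin minimum;
    ``config.restraint_types`` can additionally enable a hydrogen-bond-like
    distance restraint, a bend-angle restraint and a center-of-mass
    pseudodihedral (base-flipping) restraint anchored at the built geometry.

    The default is the torsion restraint alone.  The rigid-rotor toy has no
    extrahelical escape mode, so the extra restraints add no confinement;
    what they do add - because the internal terms of the decoupled copies
    are always on - is a basin-asymmetric shift of the ghost free energies
    that no longer cancels between the restrain and release legs, moving
    the cycle total away from the pure conformational difference (the shift
    is quantified exactly by
    :func:`~rfepr.toy_systems.exact_cycle_reference`).
    """
    profile = TorsionProfile(minima=tuple(tuple(m) for m in config.profile_minima))
    start = (0, 1) if config.direction == "anti_to_syn" else (1, 0)
    seed = config.master_seed % 2 ** 31
    topo_a, coords_a = build_torsion_toy(profile, config.n_shared, config.n_dual,
                                         seed=seed, start_minimum=start[0])
    topo_b, coords_b = build_torsion_toy(profile, config.n_shared, config.n_dual,
                                         seed=seed, start_minimum=start[1])
    hybrid, coords = build_hybrid_topology(topo_a, topo_b, coords_a, coords_b)

    ka, kd = config.restraint_k_angular, config.restraint_k_distance
    frame = [int(i) for i in hybrid.indices("shared")
             if hybrid.mobility[i] == "static"]
    torsions, distances, angles, pseudos = [], [], [], []
    for label, subject in (("dual-RV", "rv"), ("dual-VR", "vr")):
        spec = hybrid.rotors[label]
        quad = hybrid.profile_for(label).profile.quadruple
        chi_eq = np.radians(torsion(*(coords[i] for i in quad)))
        torsions.append(TorsionRestraint(quad, chi_eq, ka, subject=subject))
        tip = spec.moving[0]
        if frame and "distance" in config.restraint_types:
            anchor = frame[0]
            r_eq = float(np.linalg.norm(coords[tip] - coords[anchor]))
            distances.append(DistanceRestraint((tip, anchor), r_eq, kd,
                                               subject=subject))
        if frame and "angle" in config.restraint_types:
            anchor = frame[0]
            axis_top = spec.axis[1]
            v1 = coords[anchor] - coords[tip]
            v2 = coords[axis_top] - coords[tip]
            th_eq = float(np.arccos(np.clip(
                np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)),
                -1.0, 1.0)))
            angles.append(AngleRestraint((anchor, tip, axis_top), th_eq, ka,
                                         subject=subject))
        if len(frame) >= 2 and "pseudodihedral" in config.restraint_types:
            pd_spec = PseudoDihedralSpec(groups=(
                tuple(frame[-2:]), (spec.axis[0],), (spec.axis[1],),
                tuple(int(i) for i in spec.moving)))
            phi_eq = np.radians(pseudodihedral(pd_spec, coords, hybrid.masses))
            pseudos.append(PseudoDihedralRestraint(pd_spec, phi_eq, ka,
                                                   subject=subject))
    restraints = RestraintSet(torsions=tuple(torsions),
                              distances=tuple(distances),
                              angles=tuple(angles),
                              pseudodihedrals=tuple(pseudos))
    return hybrid, coords, restraints


@dataclass
class StageResult:
    """MBAR estimate and diagnostics for one cycle stage."""

    stage: str
    schedule: tuple
    delta_g_kcal: float
    error_kcal: float
    n_k: list
    g_k: list
    error_inflation: float
    overlap: object
    convergence: ConvergenceSeries
    min_neighbor_overlap: float
    overlap_ok: bool
    converged: bool


@dataclass
class CycleReport:
    """Per-stage and total free energies for one R-FEP-R cycle.

    The total is the exact signed sum of the three stage estimates (the
    release leg enters as estimated along its 1 -> 0 schedule); its
    uncertainty is the inter-stage propagated (root-sum-square) error, while
    each stage carries its own MBAR asymptotic error.
    """

    stages: dict
    delta_g_total_kcal: float
    error_total_kcal: float
    direction: str
    warnings: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        def conv(series: ConvergenceSeries) -> dict:
            return {"fractions": series.fractions.tolist(),
                    "forward": series.forward.tolist(),
                    "forward_err": series.forward_err.tolist(),
                    "reverse": series.reverse.tolist(),
                    "reverse_err": series.reverse_err.tolist(),
                    "units": series.units}

        return {
            "direction": self.direction,
            "delta_g_total_kcal": self.delta_g_total_kcal,
            "error_total_kcal": self.error_total_kcal,
            "stages": {
                name: {
                    "schedule": list(s.schedule),
                    "delta_g_kcal": s.delta_g_kcal,
                    "error_kcal": s.error_kcal,
                    "n_k": list(map(int, s.n_k)),
                    "statistical_inefficiency": list(map(float, s.g_k)),
                    "error_inflation": s.error_inflation,
                    "overlap_matrix": s.overlap.matrix.tolist(),
                    "min_neighbor_overlap": s.min_neighbor_overlap,
                    "overlap_ok": s.overlap_ok,
                    "converged": s.converged,
                    "convergence": conv(s.convergence),
                } for name, s in self.stages.items()
            },
            "warnings": list(self.warnings),
            "provenance": dict(self.provenance),
        }

    def to_json(self, indent: int = 1) -> str:
        return json.dumps(self.to_dict(), indent=indent)


_STAGE_BUILDERS = {
    "restrain": LambdaState.restrain_states,
    "fep": LambdaState.fep_states,
    "release": LambdaState.release_states,
}


def run_rfepr(config: CycleConfig, progress: bool = False) -> CycleReport:
    """Run the full restrain-FEP-release cycle on the standard toy.

    Every lambda-state is sampled independently by Metropolis Monte Carlo
    (seeds spawned from the master seed), cross-evaluated reduced potentials
    are estimated per stage by MBAR, and the three stage free energies are
    summed.  Failing overlap or convergence checks flags the report but the
    total is still computed.  Deterministic given the master seed.
    """
    thermo = config.thermo
    hybrid, coords, restraints = build_standard_system(config)
    schedules = {"restrain": tuple(config.restrain_schedule),
                 "fep": tuple(config.fep_schedule),
                 "release": tuple(config.release_schedule)}
    root = np.random.SeedSequence(config.master_seed)
    stage_seeds = dict(zip(schedules, root.spawn(len(schedules))))

    stages, warnings_list = {}, []
    total, var_total = 0.0, 0.0
    for name, sched in schedules.items():
        states = _STAGE_BUILDERS[name](sched)
        seeds = stage_seeds[name].spawn(len(states))
        trajs = []
        for st, ss in zip(states, seeds):
            if progress:
                print(f"[rfepr] {name} lambda[{st.index}] sampling "
                      f"{config.sweeps_per_state} sweeps", file=sys.stderr)
            trajs.append(metropolis_sample(
                hybrid, coords, restraints, st, config.sweeps_per_state, ss,
                thermo, thin=config.thin,
                burn_in_fraction=config.burn_in_fraction, sc=config.softcore))
        u = collect_u_kn(trajs, states, hybrid, restraints, thermo, coords,
                         sc=config.softcore)
        g_k = [float(statistical_inefficiency(u.own_series(k)))
               if u.n_k[k] >= 10 else 1.0 for k in range(u.n_states)]
        inflation = 1.0
        if config.decorrelation == "subsample":
            u = u.subsample(g_values=g_k)
        elif config.decorrelation == "inflate":
            # keep every sample for the estimate; widen the asymptotic
            # errors for the residual correlation instead
            inflation = float(np.sqrt(np.mean(g_k)))
        result = mbar_solve(u, stage=name)
        dg, err = result.delta_g_kcal(thermo)
        err *= inflation
        ov = overlap_matrix(u, f_k=result.f_k)
        conv = forward_reverse(u, fractions=config.convergence_fractions)
        conv_kcal = conv.scaled(thermo.rt_kcal, "kcal/mol") \
                        .inflate_errors(inflation)
        stage = StageResult(
            stage=name, schedule=sched, delta_g_kcal=dg, error_kcal=err,
            n_k=list(map(int, u.n_k)), g_k=g_k, error_inflation=inflation,
            overlap=ov, convergence=conv_kcal,
            min_neighbor_overlap=ov.min_neighbor_overlap(),
            overlap_ok=ov.passes_threshold, converged=conv_kcal.converged())
        if not stage.overlap_ok:
            warnings_list.append(
                f"{name}: nearest-neighbor overlap {stage.min_neighbor_overlap:.4f} "
                f"below threshold {ov.threshold}")
        if not stage.converged:
            warnings_list.append(f"{name}: forward/reverse estimates disagree")
        stages[name] = stage
        total += dg
        var_total += err ** 2
        logger.info("stage %s: dG = %.4f +/- %.4f kcal/mol", name, dg, err)

    return CycleReport(
        stages=stages,
        delta_g_total_kcal=total,
        error_total_kcal=float(np.sqrt(var_total)),
        direction=config.direction,
        warnings=warnings_list,
        provenance={
            "master_seed": config.master_seed,
            "config": config.to_dict(),
            "schedules": {k: list(v) for k, v in schedules.items()},
            "rfepr_version": _version,
        },
    )


def report_render(report: CycleReport):
    """Human-readable text plus the machine-readable dict of a report."""
    lines = [f"R-FEP-R cycle ({report.direction})", "-" * 40]
    for name in ("restrain", "fep", "release"):
        if name not in report.stages:
            continue
        s = report.stages[name]
        lines.append(f"{name:>8s}: dG = {s.delta_g_kcal:+.4f} "
                     f"+/- {s.error_kcal:.4f} kcal/mol  "
                     f"(K={len(s.schedule)}, min overlap "
                     f"{s.min_neighbor_overlap:.3f}, "
                     f"{'converged' if s.converged else 'NOT converged'})")
    lines.append(f"{'total':>8s}: dG = {report.delta_g_total_kcal:+.4f} "
                 f"+/- {report.error_total_kcal:.4f} kcal/mol")
    for w in report.warnings:
        lines.append(f"warning: {w}")
    lines.append(f"master seed: {report.provenance.get('master_seed')}")
    return "\n".join(lines), report.to_dict()


def plot_diagnostics(report: CycleReport, out_dir) -> list:
    """Write overlap-matrix and forward/reverse convergence figures.

    Returns the list of files written.  Matplotlib is imported lazily; the
    rest of the package does not need it.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for name, stage in report.stages.items():
        fig, (ax0, ax1) = plt.subplots(1, 2, figsize=(9, 3.6))
        im = ax0.imshow(stage.overlap.matrix, vmin=0, vmax=1, cmap="viridis")
        ax0.set_title(f"{name}: overlap")
        ax0.set_xlabel("state j")
        ax0.set_ylabel("state i")
        fig.colorbar(im, ax=ax0, fraction=0.046)
        c = stage.convergence
        ax1.errorbar(c.fractions, c.forward, yerr=c.forward_err,
                     label="forward", marker="o", capsize=2)
        ax1.errorbar(c.fractions, c.reverse, yerr=c.reverse_err,
                     label="reverse", marker="s", capsize=2)
        ax1.set_title(f"{name}: forward/reverse")
        ax1.set_xlabel("data fraction")
        ax1.set_ylabel(f"dG ({c.units})")
        ax1.legend()
        fig.tight_layout()
        path = out / f"diagnostics_{name}.png"
        fig.savefig(path, dpi=120)
        plt.close(fig)
        written.append(path)
    return written


# ---------------------------------------------------------------------------
# file I/O: GROMACS-dialect XVG and u_kn CSV
# ---------------------------------------------------------------------------

class XvgFormatError(ValueError):
    """Malformed XVG content, carrying the offending line number."""


def write_dhdl_xvg(path, data: np.ndarray, legends: list, title: str = "dH/dl",
                   xaxis: str = "Time (sweep)", comments: list | None = None) -> None:
    """Write a numeric table in the GROMACS dhdl XVG dialect.

    ``data`` is (rows, 1 + len(legends)): the first column is the abscissa,
    the remaining columns carry the legended series.  Values are printed at
    full double precision so a read/write round trip is lossless.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 1 + len(legends):
        raise ValueError("data must have one abscissa plus one column per legend")
    with open(path, "w") as fh:
        for c in comments or []:
            fh.write(f"# {c}\n")
        fh.write(f'@    title "{title}"\n')
        fh.write(f'@    xaxis  label "{xaxis}"\n')
        fh.write('@    yaxis  label "(kT)"\n')
        fh.write('@TYPE xy\n')
        for i, leg in enumerate(legends):
            fh.write(f'@ s{i} legend "{leg}"\n')
        for row in data:
            fh.write(" ".join(f"{v:.17g}" for v in row) + "\n")


def read_dhdl_xvg(path):
    """Parse a dhdl-style XVG file.

    Returns ``(dataframe, metadata)`` where the dataframe's first column is
    the abscissa and the rest are named by the ``s<i> legend`` entries;
    ``metadata`` preserves comment and @-directive lines for provenance.
    Raises :class:`XvgFormatError` with the line number for malformed
    numeric rows or a column count inconsistent with the legends.
    """
    legends, comments, directives, rows = [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                comments.append(line[1:].strip())
                continue
            if line.startswith("@"):
                directives.append(line)
                parts = line.split('"')
                if " legend " in line and len(parts) >= 2:
                    legends.append(parts[-2])
                continue
            try:
                rows.append([float(tok) for tok in line.split()])
            except ValueError as exc:
                raise XvgFormatError(
                    f"{path}: malformed numeric row at line {lineno}") from exc
    if not rows:
        raise XvgFormatError(f"{path}: no numeric data rows found")
    width = len(rows[0])
    for i, row in enumerate(rows):
        if len(row) != width:
            raise XvgFormatError(f"{path}: ragged row at data row {i + 1}")
    if legends and width != len(legends) + 1:
        raise XvgFormatError(
            f"{path}: {width} columns inconsistent with {len(legends)} legends")
    names = ["x"] + (legends if legends
                     else [f"col{i}" for i in range(1, width)])
    df = pd.DataFrame(rows, columns=names)
    meta = {"comments": comments, "directives": directives}
    return df, meta


def write_u_kn_csv(path, u: ReducedPotentialMatrix) -> None:
    """Write a reduced-potential matrix as CSV.

    Columns: ``origin_state`` (the state each sample was generated in),
    ``sample`` (time order within the origin block), and ``u_<k>`` for every
    evaluating state, in kT.
    """
    origin = np.repeat(np.arange(u.n_states), u.n_k)
    sample = np.concatenate([np.arange(n) for n in u.n_k])
    cols = {"origin_state": origin, "sample": sample}
    for k in range(u.n_states):
        cols[f"u_{k}"] = u.u_kn[k]
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.17g")


def read_u_kn_csv(path) -> ReducedPotentialMatrix:
    """Inverse of :func:`write_u_kn_csv`."""
    df = pd.read_csv(path, float_precision="round_trip")
    ucols = [c for c in df.columns if c.startswith("u_")]
    if not ucols or "origin_state" not in df.columns:
        raise ValueError(f"{path}: not a u_kn CSV (missing origin_state/u_* columns)")
    df = df.sort_values(["origin_state", "sample"], kind="stable")
    n_states = len(ucols)
    n_k = np.array([int((df["origin_state"] == k).sum()) for k in range(n_states)])
    u_kn = df[ucols].to_numpy().T
    return ReducedPotentialMatrix(u_kn, n_k)
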