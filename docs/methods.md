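# Methods

## The estimand and the cycle

The target quantity is a conformational free-energy difference
ΔG = −RT ln(Z_B/Z_A) between two torsional basins (labelled *anti*,
χ ≈ −105°, and *syn*, χ ≈ +64°, after the glycosyl torsion of a purine
base) separated by a barrier too high for direct sampling.  The
restrain–FEP–release cycle reaches it alchemically through a dual topology:
the conformer-specific particles exist twice (dual-RV, real→virtual;
dual-VR, virtual→real), the copies never interact with each other, and only
their van der Waals and Coulomb couplings to the shared environment are
λ-switched.  Internal bonded terms — including the two-well torsion profile
— stay on for both copies at all λ.

Stage semantics (fixed sign convention): the restrain stage scales the
restraints of the initial (RV) conformer from 0 to 1; the FEP stage holds
both copies restrained while swapping the nonbonded couplings; the release
stage scales the final (VR) conformer's restraints from 1 to 0.  Each stage
is estimated along its own arrow and the three signed values are added, so
the total is the initial→final conformational ΔG and restraint work cancels
between the restrain and release legs.  The release leg therefore enters
with its 1→0 sign as estimated, not as a positive "removal" free energy.
Cycle-closure (anti→syn plus syn→anti sums to zero) and
restraint-stiffness-invariance tests pin this convention.

### The ghost term

Because the decoupled ("ghost") copy keeps its internal terms, the exact
cycle total is

ΔG_cycle = −RT ln(Z_syn/Z_anti) − RT ln(z_RV,restr / z_VR,restr),

where z are the partition functions of the restrained, fully decoupled
copies over their internal coordinates.  The second term cancels only when
the restrained ghosts are statistically congruent.  With torsion-only
restraints on a profile whose two wells have equal depth and curvature it
vanishes to machine precision; adding distance/angle/pseudodihedral
restraints anchored at basin-dependent geometry makes it material (about
−0.22 kcal/mol for the standard toy with all restraint types, k = 1000).
`exact_cycle_reference` evaluates both terms by quadrature, and a pipeline
test verifies that a cycle run with the full restraint set reproduces the
ghost-aware reference.  The standard configuration restrains the glycosyl
torsion only: the rigid toy has no extrahelical escape mode, so the extra
restraints add no confinement, only the non-cancelling ghost shift.

## The toy systems and what they emulate

A toy consists of a dual set (stem particle, two axis particles, and a
rigid arm of ≥ 1 particles that rotates about the axis) and a shared set
(up to four static "frame" particles carrying charges and LJ parameters
around the rotor, plus harmonically tethered mobile particles with zero
nonbonded parameters).  The torsion quadruple lies entirely inside the dual
set.  The two-well profile is a sum of periodic Gaussian wells
−D·exp(−wrap(χ−χ₀)²/2w²) with w = √(D/c), so the curvature at each minimum
is exactly the requested c and the potential is smooth and integrable.

Standard study conditions (chosen once): T = 300 K; minima at −105° and
+64°, both with depth D = 40 kJ/mol (a ~16 kT barrier, so unrestrained
endpoint states stay kinetically confined to their basin, mirroring the
molecular problem) and curvature c = 200 kJ/mol/rad² (≈ 6° basin
fluctuations); a frame attractor (q = +0.10 e) aligned with the syn
orientation so the environment, not the bare profile, discriminates the
basins by roughly −0.9 kcal/mol; restraint force constants k = 1000
kJ/mol/rad² (angular) and kJ/mol/nm² (distance); soft-core α = 0.5, p = 1,
σ = 0.3 nm applied to both LJ and Coulomb with the component's own λ in the
radial shift r_eff⁶ = ασ⁶λᵖ + r⁶; λ schedules of 6 (restrain), 15 (FEP)
and 6 (release) states as listed in the README.

The rigid-rotor / static-frame design is deliberate: the only degrees of
freedom coupled to the alchemical switch are the two rotor angles, so every
end-state partition function is a one-dimensional integral and the
brute-force reference (`exact_free_energy_1d`, composite Simpson with
interval doubling until the free energy moves by < 10⁻⁸ kcal/mol) is exact
rather than approximate.  The mobile tethered particles exercise the
displacement move set and contribute a multiplicative constant that cancels
in every difference; guards in the sampler and oracle raise if a
configuration would break this separability (e.g. a charged mobile
particle).

What the toys do **not** emulate: solvent and counterions, internal
flexibility of the base and backbone, collective environmental relaxation
upon decoupling, long-range electrostatics, and real kinetics.  Passing
tests therefore demonstrate the correctness of the estimators, coupling
rules, cycle bookkeeping and diagnostics — not force-field accuracy or
convergence behavior of explicit-solvent DNA simulations, whose
microsecond-scale free energies are outside desk scale.

## Sampling

Metropolis Monte Carlo replaces molecular dynamics: the estimand is
configurational, so any detailed-balance-satisfying chain at each
λ-state's reduced potential suffices, and MC removes forces and integrators
entirely.  One sweep proposes one collective rotation per rotor (Gaussian
angular steps) and one Cartesian displacement per tethered particle.  Step
sizes are tuned every 50 sweeps during burn-in to a 30–50% acceptance
window; the first 10% of sweeps are discarded; configurations are stored
every 5 sweeps.  Per-λ-state seeds are spawned from the master seed via
`numpy.random.SeedSequence`, making whole cycles bit-reproducible.  An
optional uniform "jump" proposal (symmetric, so the Metropolis ratio is
unchanged) mixes across basins for unbiased population studies; it is off
during cycle runs, where basin confinement is part of the model.

Correlation is quantified per state with the statistical inefficiency
g = 1 + 2Σ C_t, truncating the autocorrelation sum at the first nonpositive
value, clamping g ≥ 1, and defining g = N (flagged) for a constant series.
By default every stored sample enters the estimate and the MBAR asymptotic
variance is inflated by the mean per-state g (``decorrelation="inflate"``);
traditional ⌈g⌉-stride decimation remains available
(``decorrelation="subsample"``).  The default was chosen after measuring
both on the standard toy against the exact quadrature reference: with
g ≈ 2–3 on frames already thinned to every 5 sweeps, decimation discards
two thirds of the data and the subset-selection noise (offset-dependent, of
order the reported error itself) dominated the total error, while full-data
estimates tracked the reference several times more precisely; inflating the
covariance keeps the uncertainty honest without that loss.

## Estimation and diagnostics

MBAR solves f_k = −ln Σ_n exp(−u_kn)/Σ_l N_l exp(f_l − u_ln), anchored at
f₀ = 0, by self-consistent iteration with a switch to BFGS minimization of
the equivalent convex objective if the residual is still two orders of
magnitude above tolerance after 100 iterations; convergence requires
max|Δf| < 10⁻⁸ per iteration, and failure raises an error carrying the last
residual.  Uncertainties use the standard asymptotic covariance of the
weight matrix (SVD form with a pseudo-inverse; the singular direction is the
anchoring gauge).  BAR solves the Bennett implicit equation by bracketed
Brent root finding (bracket widened from the one-sided exponential
estimates) and reports the equivalent two-state MBAR variance, giving
estimator-consistent error bars.

Each stage reports its MBAR asymptotic error; the cycle total reports the
root-sum-square of the three stage errors, labelled as inter-stage
propagated.  Both are attached to the report because they answer different
questions (per-leg precision vs. total budget).

Overlap matrices are the MBAR-weighted O_ij = Σ_n W_ni N_j W_nj (rows sum
to one by construction; residual round-off is renormalized and validated to
10⁻¹⁰).  Nearest-neighbor entries are compared against the 0.03 reliability
threshold.  Forward/reverse convergence re-solves MBAR on growing
chronological and time-reversed per-state prefixes; a stage is declared
converged when the forward/reverse gap stays within a pointwise 2σ
quadrature-combined band at every retained fraction in the last half of the
data (a 1σ all-points rule false-alarms on ideal stationary data and is
useless as a detector; a drifting series still fails the 2σ rule by a wide
margin).  The "time" axis for these plots is the Monte Carlo sweep index.

## Numerical conventions and degenerate inputs

Angles follow the IUPAC torsion sign convention, pinned by cis = 0°,
trans = 180° tests, with values on (−180°, 180°]; all angular restraint
deviations are wrapped to (−π, π] (minimal image on the circle).  Basin
edges are the circular midpoints between adjacent minima.  Collinear
torsion definitions, coincident hydrogen-bond points, and groups emptied by
hydrogen exclusion raise explicit errors rather than returning silent
zeros — except that a restraint with λ = 0 is identically zero without
evaluating geometry.  Soft-core energies at λ endpoints bypass the
(r⁶)^{1/6} round trip so the end-state potentials are recovered bit-exactly.
Lorentz–Berthelot combination rules generate pair parameters; the toy
nonbonded model is exact pairwise between dual and shared sets only (no
cutoffs, no intra-set terms).  R = 8.31446×10⁻³ kJ/mol/K internally;
1.98720426×10⁻³ kcal/mol/K for reported values; 1 kcal = 4.184 kJ.

## Problem sizes and calibration

The standard cycle uses 10⁴ sweeps per λ-state (27 states), giving total
uncertainties near 0.007 kcal/mol on the standard toy; unit and plumbing
tests use scaled-down cycles (hundreds of sweeps, shortened schedules)
where only bookkeeping, not precision, is at stake.  A ten-seed ensemble
test checks both parameter recovery against the quadrature reference and
that the empirical spread of totals matches the reported uncertainties
within a factor of two.

## Known limitations

* Reported uncertainties are calibrated only to within the ensemble test's
  factor-of-two band; the sqrt(g)-inflated asymptotic errors tend to the
  conservative side on the standard toy.
* Basin fluctuations of the standard toy (~6°) are narrower than the
  ±12–17° observed for real glycosyl torsions; the restraint stages are
  correspondingly cheaper than in the molecular systems.
* No replica exchange between λ-states (per-state sampling is independent,
  matching the method's per-λ simulations) and no thermodynamic-integration
  estimator (the method reports MBAR; TI would need dH/dλ accumulation).
* The dhdl XVG dialect reader/writer covers the comment/@-metadata/numeric
  layout needed for the estimator layer, not every variant GROMACS can emit.
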