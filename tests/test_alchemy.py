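"""Soft-core switching, restraint energetics, and the reduced potential."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from rfepr.alchemy import (EvaluationError, GHOST, LambdaState, PairEndState,
                           RestraintSet, SoftCoreParams, TorsionRestraint,
                           DistanceRestraint, build_pair_table,
                           plain_pair_energy, potential_energy,
                           reduced_potential, restraint_energy,
                           restraint_weights, softcore_pair_energy)
from rfepr.geometry import UndefinedAngleError, torsion, wrap_rad
from rfepr.toy_systems import standard_profile, build_torsion_toy
from rfepr.units import COULOMB_CONSTANT, ThermoState

SC = SoftCoreParams()
PAIR_A = PairEndState(qq=-0.01, epsilon=0.5, sigma=0.33)


class TestSoftCore:
    def test_lambda_zero_recovers_unsoftened_end_state(self):
        r = np.linspace(0.2, 1.5, 40)
        e = softcore_pair_energy(r, 0.0, 0.0, PAIR_A, GHOST, SC)
        assert np.allclose(e, plain_pair_energy(r, *PAIR_A), rtol=0, atol=1e-14)

    def test_full_decoupling_to_ghost_is_zero(self):
        r = np.linspace(0.05, 1.5, 40)
        e = softcore_pair_energy(r, 1.0, 1.0, PAIR_A, GHOST, SC)
        assert np.allclose(e, 0.0, atol=1e-14)

    def test_finite_at_contact_for_intermediate_lambda(self):
        """At r = 0 the soft-core shift keeps both LJ and Coulomb finite;
        the value equals the closed-form expression evaluated directly."""
        lam = 0.5
        e = softcore_pair_energy(0.0, lam, lam, PAIR_A, GHOST, SC)
        assert np.isfinite(e)
        r_eff = (SC.alpha * SC.sigma ** 6 * lam) ** (1.0 / 6.0)
        sr6 = (PAIR_A.sigma / r_eff) ** 6
        expected = (1 - lam) * (4 * PAIR_A.epsilon * (sr6 ** 2 - sr6)
                                + COULOMB_CONSTANT * PAIR_A.qq / r_eff)
        assert e == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("qq", [-0.01, 0.01])
    def test_monotone_decoupling_beyond_sigma(self, qq):
        pair = PairEndState(qq=qq, epsilon=0.4, sigma=0.33)
        for r in (0.35, 0.5, 0.8):
            lams = np.linspace(0.0, 1.0, 21)
            mags = [abs(softcore_pair_energy(r, l, l, pair, GHOST, SC))
                    for l in lams]
            assert all(m1 >= m2 - 1e-12 for m1, m2 in zip(mags, mags[1:]))

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SoftCoreParams(alpha=-0.1)
        with pytest.raises(ValueError):
            SoftCoreParams(power=0)
        with pytest.raises(ValueError):
            SoftCoreParams(sigma=0.0)


class TestRestraintEnergy:
    def _trans_quad(self):
        # planar trans arrangement: torsion = 180 deg
        return np.array([(0, 1, 0), (0, 0, 0), (1, 0, 0), (1, -1, 0)],
                        dtype=float)

    def test_hand_evaluated_wrapped_harmonic(self):
        """Torsion at 180 deg restrained to -105 deg with k = 1000: the
        wrapped deviation is -75 deg and the energy 0.5*1000*(-75 deg)^2
        = 856.7 kJ/mol."""
        coords = self._trans_quad()
        rs = RestraintSet(torsions=(TorsionRestraint(
            (0, 1, 2, 3), np.radians(-105.0), 1000.0, subject="dual"),))
        e = restraint_energy(coords, rs, 1.0)
        assert e == pytest.approx(0.5 * 1000.0 * np.radians(-75.0) ** 2,
                                  rel=1e-12)
        assert e == pytest.approx(856.7, abs=0.05)

    def test_zero_at_equilibrium_for_any_lambda(self):
        coords = self._trans_quad()
        rs = RestraintSet(
            torsions=(TorsionRestraint((0, 1, 2, 3), np.pi, 1000.0),),
            distances=(DistanceRestraint(
                (0, 3), float(np.linalg.norm(coords[0] - coords[3])), 1000.0),))
        for lam in (0.05, 0.5, 1.0):
            assert restraint_energy(coords, rs, lam) == pytest.approx(0.0,
                                                                      abs=1e-18)

    def test_lambda_zero_short_circuits_degenerate_geometry(self):
        bad = np.array([(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)], dtype=float)
        rs = RestraintSet(torsions=(TorsionRestraint((0, 1, 2, 3), 0.0, 1000.0),))
        assert restraint_energy(bad, rs, 0.0) == 0.0
        with pytest.raises(UndefinedAngleError):
            restraint_energy(bad, rs, 1.0)

    @given(st.integers(-2, 2), st.integers(-2, 2))
    def test_wrap_invariance_under_full_turns(self, n_eq, n_probe):
        """Shifting the equilibrium or the probe geometry by full turns
        leaves the harmonic energy unchanged (minimal image on the circle)."""
        coords = self._trans_quad()
        eq = np.radians(-105.0)
        rs = RestraintSet(torsions=(TorsionRestraint(
            (0, 1, 2, 3), eq + 2 * np.pi * n_eq, 1000.0),))
        ref = RestraintSet(torsions=(TorsionRestraint((0, 1, 2, 3), eq, 1000.0),))
        assert restraint_energy(coords, rs, 1.0) == pytest.approx(
            restraint_energy(coords, ref, 1.0), rel=1e-12)

    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError):
            TorsionRestraint((0, 1, 2, 3), 0.0, -1.0)


class TestLambdaStates:
    def test_schedule_constructors_follow_stage_conventions(self):
        restrain = LambdaState.restrain_states((0.0, 0.5, 1.0))
        assert all(s.lambda_coul == 0.0 and s.lambda_vdw == 0.0 for s in restrain)
        fep = LambdaState.fep_states((0.0, 0.5, 1.0))
        assert all(s.lambda_restraint == 1.0 for s in fep)
        release = LambdaState.release_states((1.0, 0.5, 0.0))
        assert all(s.lambda_coul == 1.0 and s.lambda_vdw == 1.0 for s in release)

    def test_restraint_weights_per_stage(self):
        assert restraint_weights(LambdaState("restrain", 0.25, 0, 0)) == \
            {"rv": 0.25, "vr": 1.0, "dual": 0.25}
        assert restraint_weights(LambdaState("fep", 1.0, 0.5, 0.5)) == \
            {"rv": 1.0, "vr": 1.0, "dual": 1.0}
        assert restraint_weights(LambdaState("release", 0.25, 1, 1)) == \
            {"rv": 1.0, "vr": 0.25, "dual": 0.25}

    def test_out_of_range_lambda_rejected(self):
        with pytest.raises(ValueError):
            LambdaState("fep", 1.0, 1.2, 0.0)
        with pytest.raises(ValueError):
            LambdaState("melt", 0.0, 0.0, 0.0)


def _naive_potential(coords, topo, restraints, state, thermo):
    """Independent brute-force evaluator: explicit loops, its own formulas."""
    from math import atan2, cos, sqrt

    def vsub(a, b):
        return [a[0] - b[0], a[1] - b[1], a[2] - b[2]]

    def dot(a, b):
        return sum(x * y for x, y in zip(a, b))

    def cross(a, b):
        return [a[1] * b[2] - a[2] * b[1], a[2] * b[0] - a[0] * b[2],
                a[0] * b[1] - a[1] * b[0]]

    def norm(a):
        return sqrt(dot(a, a))

    def dihedral(p1, p2, p3, p4):
        b1, b2, b3 = vsub(p2, p1), vsub(p3, p2), vsub(p4, p3)
        n1, n2 = cross(b1, b2), cross(b2, b3)
        m = cross(n1, n2)
        y = dot(m, [c / norm(b2) for c in b2])
        x = dot(n1, n2)
        return atan2(y, x)

    e = 0.0
    for b in topo.bonds:
        d = norm(vsub(coords[b.i], coords[b.j]))
        e += 0.5 * b.k * (d - b.r0) ** 2
    for a in topo.angles:
        i, j, k = a.triple
        v1, v2 = vsub(coords[i], coords[j]), vsub(coords[k], coords[j])
        th = np.arccos(np.clip(dot(v1, v2) / (norm(v1) * norm(v2)), -1, 1))
        e += 0.5 * a.k * (th - a.theta0) ** 2
    for p in topo.profiles:
        chi = dihedral(*(coords[i] for i in p.profile.quadruple))
        for loc, depth, curv in p.profile.minima:
            d = chi - np.radians(loc)
            d = atan2(np.sin(d), np.cos(d))
            e += -depth * np.exp(-d * d * curv / (2.0 * depth))
    for t in topo.tethers:
        e += 0.5 * t.k * norm(vsub(coords[t.index], list(t.site))) ** 2
    weights = restraint_weights(state)
    if restraints is not None:
        for r in restraints.torsions:
            chi = dihedral(*(coords[i] for i in r.quadruple))
            d = chi - r.equilibrium
            d = atan2(np.sin(d), np.cos(d))
            e += weights[r.subject] * 0.5 * r.k * d * d
        for r in restraints.distances:
            d = norm(vsub(coords[r.pair[0]], coords[r.pair[1]]))
            e += weights[r.subject] * 0.5 * r.k * (d - r.equilibrium) ** 2
    sc = SoftCoreParams()
    for label in topo.dual_set_labels:
        if label == "dual-RV":
            lam_c, lam_v = state.lambda_coul, state.lambda_vdw
        elif label == "dual-VR":
            lam_c, lam_v = 1.0 - state.lambda_coul, 1.0 - state.lambda_vdw
        else:
            lam_c, lam_v = 0.0, 0.0
        for i in topo.indices(label):
            for j in topo.indices("shared"):
                if (min(i, j), max(i, j)) in topo.exclusions:
                    continue
                qq = topo.charges[i] * topo.charges[j]
                eps = sqrt(topo.lj_epsilon[i] * topo.lj_epsilon[j])
                sig = 0.5 * (topo.lj_sigma[i] + topo.lj_sigma[j])
                if qq == 0.0 and eps == 0.0:
                    continue
                r = norm(vsub(coords[i], coords[j]))
                ra_v = (sc.alpha * sc.sigma ** 6 * lam_v + r ** 6) ** (1 / 6)
                ra_c = (sc.alpha * sc.sigma ** 6 * lam_c + r ** 6) ** (1 / 6)
                sr6 = (sig / ra_v) ** 6
                e += (1 - lam_v) * 4 * eps * (sr6 * sr6 - sr6)
                e += (1 - lam_c) * COULOMB_CONSTANT * qq / ra_c
    return e / thermo.rt_kj


class TestReducedPotential:
    def test_matches_independent_naive_evaluator(self, standard_system,
                                                 thermo300):
        hyb, coords, restr = standard_system
        rng = np.random.default_rng(8)
        states = [LambdaState("restrain", 0.5, 0.0, 0.0),
                  LambdaState("fep", 1.0, 0.35, 0.35),
                  LambdaState("release", 0.25, 1.0, 1.0)]
        for state in states:
            jitter = coords.copy()
            mobile = np.flatnonzero(hyb.mobility == "tethered")
            jitter[mobile] += rng.normal(0, 0.02, (len(mobile), 3))
            u = reduced_potential(jitter, hyb, restr, state, thermo300)
            u_naive = _naive_potential(jitter, hyb, restr, state, thermo300)
            assert u == pytest.approx(u_naive, rel=1e-9)

    def test_restraint_lambda_irrelevant_at_equilibrium(self, standard_system,
                                                        thermo300):
        """With every restrained coordinate exactly at its equilibrium the
        reduced potential is identical across restrain-stage states."""
        hyb, coords, restr = standard_system
        u0 = reduced_potential(coords, hyb, restr,
                               LambdaState("restrain", 0.0, 0, 0), thermo300)
        u1 = reduced_potential(coords, hyb, restr,
                               LambdaState("restrain", 1.0, 0, 0), thermo300)
        assert u0 == pytest.approx(u1, abs=1e-12)

    def test_stage_boundary_consistency(self, standard_system, thermo300):
        """The last state of each stage and the first of the next describe
        the same Hamiltonian."""
        hyb, coords, restr = standard_system
        rng = np.random.default_rng(9)
        jitter = coords + rng.normal(0, 0.003, coords.shape)
        pairs = [(LambdaState("restrain", 1.0, 0.0, 0.0),
                  LambdaState("fep", 1.0, 0.0, 0.0)),
                 (LambdaState("fep", 1.0, 1.0, 1.0),
                  LambdaState("release", 1.0, 1.0, 1.0))]
        for sa, sb in pairs:
            ua = reduced_potential(jitter, hyb, restr, sa, thermo300)
            ub = reduced_potential(jitter, hyb, restr, sb, thermo300)
            assert ua == pytest.approx(ub, rel=1e-12)

    def test_nan_energy_is_reported_with_term(self, thermo300):
        topo, coords = build_torsion_toy(standard_profile(), 8, 6, 2)
        coords = coords.copy()
        coords[topo.indices("shared")[0]] = coords[topo.indices("dual")[3]]
        # coincident nonbonded pair -> infinite Coulomb at lambda 0
        with pytest.raises(EvaluationError, match="nonbonded"):
            potential_energy(coords, topo, None,
                             LambdaState("restrain", 0.0, 0.0, 0.0))

    def test_pair_table_drops_excluded_and_ghost_pairs(self, standard_system):
        hyb, _, _ = standard_system
        table = build_pair_table(hyb, "dual-RV")
        mobile = set(np.flatnonzero(hyb.mobility == "tethered").tolist())
        assert not (set(table.j_idx.tolist()) & mobile)
        assert np.all((table.qq != 0) | (table.epsilon != 0))
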