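"""Toy-system construction, hybrid merging, and the quadrature oracle."""

import numpy as np
import pytest

from rfepr.alchemy import LambdaState, potential_energy
from rfepr.geometry import torsion
from rfepr.sampler import rigid_rotation
from rfepr.toy_systems import (InconsistentTopologyError, InvalidTopologyError,
                               OracleFailureError, TorsionProfile,
                               build_hybrid_topology, build_torsion_toy,
                               exact_cycle_reference, exact_free_energy_1d,
                               standard_profile, topology_from_dict,
                               topology_to_dict, torsion_energy_function)
from rfepr.units import ThermoState, kj_to_kcal


def _build_pair(seed=3, n_shared=8, n_dual=6, profile=None):
    profile = profile or standard_profile()
    a = build_torsion_toy(profile, n_shared, n_dual, seed, start_minimum=0)
    s = build_torsion_toy(profile, n_shared, n_dual, seed, start_minimum=1)
    return a, s


class TestBuildTorsionToy:
    def test_particle_counts_and_partition(self):
        (topo, coords), _ = _build_pair()
        assert topo.n_particles == 14
        assert len(topo.indices("dual")) == 6
        assert len(topo.indices("shared")) == 8
        quad = topo.profile_for("dual").profile.quadruple
        assert all(topo.set_labels[i] == "dual" for i in quad)
        assert coords.shape == (14, 3)

    def test_coordinates_start_in_requested_basin(self):
        (topo_a, ca), (topo_s, cs) = _build_pair()
        quad = topo_a.profile_for("dual").profile.quadruple
        assert torsion(*(ca[i] for i in quad)) == pytest.approx(-105.0, abs=1e-6)
        assert torsion(*(cs[i] for i in quad)) == pytest.approx(64.0, abs=1e-6)

    def test_same_seed_is_bit_identical(self):
        t1, c1 = build_torsion_toy(standard_profile(), 8, 6, 99)
        t2, c2 = build_torsion_toy(standard_profile(), 8, 6, 99)
        assert np.array_equal(c1, c2)
        assert np.array_equal(t1.masses, t2.masses)
        assert np.array_equal(t1.charges, t2.charges)
        assert [t.site for t in t1.tethers] == [t.site for t in t2.tethers]

    def test_single_minimum_profile_rejected(self):
        one_well = TorsionProfile(minima=((0.0, 10.0, 100.0),))
        with pytest.raises(InvalidTopologyError):
            build_torsion_toy(one_well, 8, 6, 1)

    def test_too_few_dual_particles_rejected(self):
        with pytest.raises(InvalidTopologyError):
            build_torsion_toy(standard_profile(), 8, 3, 1)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            TorsionProfile(minima=((200.0, 10.0, 100.0),))
        with pytest.raises(ValueError):
            TorsionProfile(minima=((0.0, -1.0, 100.0),))


class TestHybridTopology:
    def test_counting_and_exclusions(self):
        (ta, ca), (ts, cs) = _build_pair()
        hyb, coords = build_hybrid_topology(ta, ts, ca, cs)
        assert hyb.n_particles == 8 + 6 + 6
        assert len(hyb.exclusions) == 36
        rv = set(hyb.indices("dual-RV").tolist())
        vr = set(hyb.indices("dual-VR").tolist())
        assert {tuple(sorted(p)) for p in hyb.exclusions} == \
            {tuple(sorted((i, j))) for i in rv for j in vr}

    def test_dual_profiles_present_and_always_on(self):
        (ta, ca), (ts, cs) = _build_pair()
        hyb, _ = build_hybrid_topology(ta, ts, ca, cs)
        owners = {p.owner for p in hyb.profiles}
        assert owners == {"dual-RV", "dual-VR"}
        assert all(p.always_on for p in hyb.profiles)

    def test_mismatched_shared_sets_rejected(self):
        (ta, ca), (ts, cs) = _build_pair()
        ts.charges[0] += 0.05
        with pytest.raises(InconsistentTopologyError):
            build_hybrid_topology(ta, ts, ca, cs)
        (ta, ca), (ts, cs) = _build_pair()
        cs[0] += 0.01
        with pytest.raises(InconsistentTopologyError):
            build_hybrid_topology(ta, ts, ca, cs)

    def test_swapping_inputs_preserves_end_state_energies(self):
        (ta, ca), (ts, cs) = _build_pair()
        h1, c1 = build_hybrid_topology(ta, ts, ca, cs)
        h2, c2 = build_hybrid_topology(ts, ta, cs, ca)
        assert h1.n_particles == h2.n_particles
        # the initial end state of one ordering is the final end state of
        # the swapped ordering: anti coupled, syn ghost in both cases
        s_init = LambdaState("restrain", 0.0, 0.0, 0.0)
        s_final = LambdaState("release", 0.0, 1.0, 1.0)
        e1 = potential_energy(c1, h1, None, s_init)
        e2 = potential_energy(c2, h2, None, s_final)
        assert e1 == pytest.approx(e2, abs=1e-9)

    def test_decoupled_hybrid_matches_single_state_plus_constant(self):
        """With dual-VR fully decoupled, the hybrid energy differs from the
        anti single-state energy only by the ghost set's internal terms,
        configuration by configuration."""
        (ta, ca), (ts, cs) = _build_pair()
        hyb, ch = build_hybrid_topology(ta, ts, ca, cs)
        state_h = LambdaState("restrain", 0.0, 0.0, 0.0)
        state_s = LambdaState("restrain", 0.0, 0.0, 0.0)
        spec = hyb.rotors["dual-RV"]
        spec_s = ta.rotors["dual"]
        offsets = []
        for delta in np.radians([0.0, 5.0, -8.0, 12.0]):
            c_h = ch.copy()
            axis = ch[spec.axis[1]] - ch[spec.axis[0]]
            axis /= np.linalg.norm(axis)
            c_h[list(spec.moving)] = rigid_rotation(
                ch[list(spec.moving)] - ch[spec.axis[0]], axis, delta) \
                + ch[spec.axis[0]]
            c_s = ca.copy()
            c_s[list(spec_s.moving)] = rigid_rotation(
                ca[list(spec_s.moving)] - ca[spec_s.axis[0]], axis, delta) \
                + ca[spec_s.axis[0]]
            offsets.append(potential_energy(c_h, hyb, None, state_h)
                           - potential_energy(c_s, ta, None, state_s))
        assert np.ptp(offsets) < 1e-9


class TestExactFreeEnergy1d:
    def test_symmetric_double_well_is_zero(self, thermo300):
        prof = TorsionProfile(minima=((-90.0, 20.0, 150.0), (90.0, 20.0, 150.0)))
        assert exact_free_energy_1d(prof, thermo300) == pytest.approx(0.0,
                                                                      abs=1e-10)

    def test_narrow_offset_wells_approach_depth_difference(self, thermo300):
        """Equal-curvature wells offset by 1 kcal/mol: the Gaussian-integral
        closed form gives dG -> -1.0 kcal/mol as the wells narrow."""
        eps_kj = 4.184
        errors = []
        for depth, c in ((25.0, 500.0), (100.0, 4000.0), (400.0, 32000.0)):
            prof = TorsionProfile(minima=((-90.0, depth, c),
                                          (90.0, depth + eps_kj, c)))
            dg = exact_free_energy_1d(prof, thermo300)
            errors.append(abs(dg - (-1.0)))
        assert errors[0] > errors[1] > errors[2]
        assert errors[-1] < 1e-3

    def test_quadrature_refinement_is_converged(self, thermo300):
        prof = standard_profile()
        coarse = exact_free_energy_1d(prof, thermo300, tol_kcal=1e-7)
        fine = exact_free_energy_1d(prof, thermo300, tol_kcal=1e-10)
        assert abs(coarse - fine) < 1e-6

    def test_non_finite_potential_raises(self, thermo300):
        def bad(chi):
            chi = np.asarray(chi)
            return np.full(chi.shape, np.inf)
        with pytest.raises(OracleFailureError):
            exact_free_energy_1d(bad, thermo300, minima_deg=[-90.0, 90.0])

    def test_callable_requires_minima(self, thermo300):
        with pytest.raises(ValueError):
            exact_free_energy_1d(lambda c: np.zeros_like(c), thermo300)


class TestEffectivePotentialAndCycleReference:
    def test_effective_potential_includes_environment(self, standard_system,
                                                      thermo300):
        hyb, coords, _ = standard_system
        u_eff = torsion_energy_function(hyb, coords, "dual-RV")
        prof = hyb.profile_for("dual-RV").profile
        chi = np.radians(np.array([-105.0, 64.0]))
        bare = prof.energy(chi)
        dressed = u_eff(chi)
        # the frame attractor sits on the syn side
        assert dressed[1] - bare[1] < dressed[0] - bare[0]

    def test_cycle_reference_is_antisymmetric(self, thermo300):
        from rfepr.pipeline import CycleConfig, build_standard_system
        fwd = build_standard_system(CycleConfig(master_seed=4))
        rev = build_standard_system(CycleConfig(master_seed=4,
                                                direction="syn_to_anti"))
        g_f = exact_cycle_reference(fwd[0], fwd[1], fwd[2], thermo300)
        g_r = exact_cycle_reference(rev[0], rev[1], rev[2], thermo300)
        assert g_f + g_r == pytest.approx(0.0, abs=1e-8)

    def test_ghost_term_vanishes_for_torsion_only_restraints(self, thermo300,
                                                             standard_system):
        hyb, coords, restr = standard_system
        _, details = exact_cycle_reference(hyb, coords, restr, thermo300,
                                           return_details=True)
        assert details["ghost_kcal"] == pytest.approx(0.0, abs=1e-6)

    def test_mobile_nonbonded_partner_breaks_oracle(self, thermo300):
        (ta, ca), _ = _build_pair()
        mobile = np.flatnonzero(ta.mobility == "tethered")
        ta.charges[mobile[0]] = 0.2     # couples a fluctuating particle
        with pytest.raises(OracleFailureError):
            torsion_energy_function(ta, ca, "dual")


class TestSerialization:
    def test_round_trip_preserves_everything(self, tmp_path):
        (ta, ca), _ = _build_pair()
        d = topology_to_dict(ta, ca)
        tb, cb = topology_from_dict(d)
        assert np.array_equal(ta.masses, tb.masses)
        assert np.array_equal(ta.charges, tb.charges)
        assert np.array_equal(ca, cb)
        assert ta.bonds == tb.bonds
        assert ta.rotors == tb.rotors
        assert [p.profile.minima for p in ta.profiles] == \
            [p.profile.minima for p in tb.profiles]
        state = LambdaState("restrain", 0.5, 0.0, 0.0)
        assert potential_energy(ca, ta, None, state) == \
            pytest.approx(potential_energy(cb, tb, None, state), abs=1e-12)

    def test_unknown_schema_rejected(self):
        with pytest.raises(ValueError):
            topology_from_dict({"schema": "something-else"})
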