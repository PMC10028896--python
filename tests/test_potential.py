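"""Alchemical potential: interpolation rules, softcore, REST scaling,
forces, and dU/dlambda."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import alchex as ax
from alchex.constants import COULOMB_KCAL_NM, kT
from tests.conftest import random_configuration


class TestInterpolatedCharge:
    def test_unique_old_decouples_at_lambda_one(self, insertion_hybrid):
        uo = sorted(insertion_hybrid.atom_classes.unique_old)[0]
        assert ax.interpolated_charge(uo, insertion_hybrid, 1.0) == 0.0

    def test_core_linear_midpoint(self):
        base = ax.make_lj_mutation(3, 0.0, 0.0, -1.0, seed=0)
        pair = ax.make_charge_change_mutation(base, 1.0)
        hybrid = ax.build_hybrid(pair)
        q0 = ax.interpolated_charge(0, hybrid, 0.0)
        q1 = ax.interpolated_charge(0, hybrid, 1.0)
        assert ax.interpolated_charge(0, hybrid, 0.5) == pytest.approx(0.5 * (q0 + q1))

    def test_environment_charge_untouched(self, insertion_hybrid):
        env = sorted(insertion_hybrid.atom_classes.environment)[0]
        q_ref = insertion_hybrid.q_old[env]
        for lam in (0.0, 0.3, 1.0):
            assert ax.interpolated_charge(env, insertion_hybrid, lam) == q_ref

    def test_lambda_out_of_range_rejected(self, insertion_hybrid):
        with pytest.raises(ValueError, match="lambda"):
            ax.interpolated_charge(0, insertion_hybrid, 1.5)


class TestEffectiveDistance:
    def test_no_lifting_for_mapped_pairs(self):
        p = ax.AlchemicalParams(w_lifting=0.4)
        for lam in (0.0, 0.5, 1.0):
            assert ax.effective_distance(0.3, lam, (0, 0), p) == 0.3

    def test_old_pair_unlifted_at_endstate_zero(self):
        p = ax.AlchemicalParams(w_lifting=0.4)
        assert ax.effective_distance(0.3, 0.0, (1, 0), p) == 0.3

    def test_pythagorean_lift(self):
        p = ax.AlchemicalParams(w_lifting=0.4)
        # unique-new pair at lambda=0: w = 0.4, r=0.3 -> r_eff = 0.5
        assert ax.effective_distance(0.3, 0.0, (0, 1), p) == pytest.approx(0.5)


class TestElectrostatics:
    def test_all_charges_zero(self, harmonic_hybrid):
        x = harmonic_hybrid.positions0
        assert ax.electrostatics_energy(harmonic_hybrid, x, 0.5) == 0.0

    def test_unit_charges_textbook_coulomb(self):
        pair = ax.make_lj_mutation(2, 0.0, 0.0, 0.0, seed=0)
        pair.old_system.charges[:] = [1.0, -1.0]
        pair.new_system.charges[:] = [1.0, -1.0]
        pair.old_system.lj_epsilon[:] = 0.0
        pair.new_system.lj_epsilon[:] = 0.0
        hybrid = ax.build_hybrid(pair)
        x = np.array([[0.0, 0.0, 0.0], [0.3, 0.0, 0.0]])
        e = ax.electrostatics_energy(hybrid, x, 0.0)
        assert e == pytest.approx(-COULOMB_KCAL_NM / 0.3, rel=1e-12)
        assert e == pytest.approx(-110.688, abs=2e-3)

    def test_unique_old_pair_silent_at_lambda_one(self, insertion_hybrid):
        x = insertion_hybrid.positions0
        ev = ax.HybridEvaluator(insertion_hybrid)
        uo = sorted(insertion_hybrid.atom_classes.unique_old)[0]
        assert ev.charges(1.0)[uo] == 0.0


class TestSterics:
    def _dimer(self, lam=0.0):
        pair = ax.make_lj_mutation(2, 0.0, 0.1, 0.0, seed=0)
        return ax.build_hybrid(pair)

    def test_zero_crossing_at_sigma(self):
        hybrid = self._dimer()
        sig = 0.5 * (hybrid.sigma_old[0] + hybrid.sigma_old[1])
        x = np.array([[0.0, 0.0, 0.0], [sig, 0.0, 0.0]])
        assert ax.sterics_energy(hybrid, x, 0.0) == pytest.approx(0.0, abs=1e-12)

    def test_minimum_depth_is_minus_epsilon(self):
        hybrid = self._dimer()
        sig = 0.5 * (hybrid.sigma_old[0] + hybrid.sigma_old[1])
        eps = math.sqrt(hybrid.eps_old[0] * hybrid.eps_old[1])
        x = np.array([[0.0, 0.0, 0.0], [2 ** (1 / 6) * sig, 0.0, 0.0]])
        assert ax.sterics_energy(hybrid, x, 0.0) == pytest.approx(-eps, rel=1e-12)

    def test_coincident_unique_atom_finite_through_softcore(self, insertion_hybrid):
        x = insertion_hybrid.positions0.copy()
        un = sorted(insertion_hybrid.atom_classes.unique_new)[0]
        env = sorted(insertion_hybrid.atom_classes.environment)[0]
        x[un] = x[env]
        e = ax.sterics_energy(insertion_hybrid, x, 0.0)
        assert np.isfinite(e)


class TestValence:
    def test_bond_at_rest_length_contributes_zero(self):
        pair = ax.make_lj_mutation(2, 0.0, 0.0, 0.0, seed=0)
        r0 = 0.25
        pair.old_system.bonds.append((0, 1, 100.0, r0))
        pair.new_system.bonds.append((0, 1, 100.0, r0))
        hybrid = ax.build_hybrid(pair)
        x = np.array([[0.0, 0.0, 0.0], [r0, 0.0, 0.0]])
        no_bond = ax.build_hybrid(ax.make_lj_mutation(2, 0.0, 0.0, 0.0, seed=0))
        assert ax.valence_energy(hybrid, x, 0.0) == pytest.approx(
            ax.valence_energy(no_bond, x, 0.0), abs=1e-12)

    def test_dummy_atom_displacement_only_moves_valence(self, insertion_hybrid):
        rng = np.random.default_rng(0)
        x = random_configuration(insertion_hybrid, rng)
        un = sorted(insertion_hybrid.atom_classes.unique_new)[0]
        x2 = x.copy()
        x2[un] += 0.11
        # at lambda=0 the unique-new atom is a dummy: nonbonded silent
        assert ax.electrostatics_energy(insertion_hybrid, x2, 0.0) == pytest.approx(
            ax.electrostatics_energy(insertion_hybrid, x, 0.0), abs=1e-12)
        assert ax.sterics_energy(insertion_hybrid, x2, 0.0) == pytest.approx(
            ax.sterics_energy(insertion_hybrid, x, 0.0), abs=1e-12)
        assert ax.valence_energy(insertion_hybrid, x2, 0.0) != pytest.approx(
            ax.valence_energy(insertion_hybrid, x, 0.0), abs=1e-9)


class TestTotalPotentialAndREST:
    def test_rest_unscaled_at_endstates(self, double_well_pair):
        hybrid = ax.build_hybrid(double_well_pair)
        hybrid = ax.assign_rest_region(hybrid, hybrid.positions0, 0.5)
        rest = ax.RESTParams(T0=300.0, Tmax=600.0)
        rng = np.random.default_rng(1)
        x = random_configuration(hybrid, rng)
        for lam in (0.0, 1.0):
            assert ax.total_potential(hybrid, x, lam, rest=rest) == pytest.approx(
                ax.total_potential(hybrid, x, lam), abs=0.0)

    def test_tmax_equal_t0_never_scales(self, double_well_pair):
        hybrid = ax.build_hybrid(double_well_pair)
        hybrid = ax.assign_rest_region(hybrid, hybrid.positions0, 0.5)
        rest = ax.RESTParams(T0=300.0, Tmax=300.0)
        rng = np.random.default_rng(2)
        x = random_configuration(hybrid, rng)
        for lam in (0.0, 0.25, 0.7, 1.0):
            assert ax.total_potential(hybrid, x, lam, rest=rest) == \
                ax.total_potential(hybrid, x, lam)

    def test_alpha_half_at_midpoint_halves_rest_interaction(self):
        rest = ax.RESTParams(T0=300.0, Tmax=600.0)
        assert rest.alpha(0.5) == pytest.approx(0.5)
        assert rest.alpha(0.0) == 1.0 and rest.alpha(1.0) == 1.0

    def test_pure_rest_term_halved(self, double_well_pair):
        hybrid = ax.build_hybrid(double_well_pair)
        hybrid = ax.assign_rest_region(hybrid, hybrid.positions0, 0.0)
        rest = ax.RESTParams(T0=300.0, Tmax=600.0)
        rng = np.random.default_rng(3)
        x = random_configuration(hybrid, rng)
        ev_rest = ax.HybridEvaluator(hybrid, rest=rest)
        ev_plain = ax.HybridEvaluator(hybrid)
        comp_r = ev_rest.energy_components(x, 0.5)
        comp_p = ev_plain.energy_components(x, 0.5)
        # all valence terms of this fixture touch only rest-region atoms or
        # only non-rest atoms; the well term (pure rest) must be halved
        well_r = comp_r["valence"]
        well_p = comp_p["valence"]
        assert well_r < well_p  # strictly reduced at alpha = 0.5


class TestContinuityAndConservation:
    def test_potential_continuous_in_lambda(self, insertion_hybrid):
        rng = np.random.default_rng(5)
        x = random_configuration(insertion_hybrid, rng)
        lams = np.linspace(0, 1, 101)
        ev = ax.HybridEvaluator(insertion_hybrid)
        e = np.array([ev.energy(x, lam) for lam in lams])
        jumps = np.abs(np.diff(e))
        assert jumps.max() < 0.5  # no discontinuities on a smooth fixture

    @given(lam=st.floats(0.0, 1.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_total_charge_linear_in_lambda(self, lam):
        base = ax.make_lj_mutation(3, 0.0, 0.0, -1.0, seed=4)
        hybrid = ax.build_hybrid(base)
        ev = ax.HybridEvaluator(hybrid)
        q0 = ev.charges(0.0).sum()
        q1 = ev.charges(1.0).sum()
        assert ev.charges(lam).sum() == pytest.approx((1 - lam) * q0 + lam * q1,
                                                      abs=1e-12)


class TestForcesAndDuDl:
    @pytest.mark.parametrize("fixture_name", ["insertion_hybrid", "harmonic_hybrid"])
    def test_forces_match_numerical_gradient(self, fixture_name, request):
        hybrid = request.getfixturevalue(fixture_name)
        ev = ax.HybridEvaluator(hybrid)
        rng = np.random.default_rng(6)
        x = random_configuration(hybrid, rng)
        f = ev.forces(x, 0.37)
        h = 1e-6
        for i in (0, hybrid.n_atoms - 1):
            for axis in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, axis] += h
                xm[i, axis] -= h
                num = -(ev.energy(xp, 0.37) - ev.energy(xm, 0.37)) / (2 * h)
                assert f[i, axis] == pytest.approx(num, rel=1e-4, abs=1e-5)

    def test_angle_torsion_forces_match_numerical_gradient(self):
        pair = ax.make_lj_mutation(4, 0.0, 0.0, 0.0, seed=0)
        for sys_ in (pair.old_system, pair.new_system):
            sys_.angles.append((0, 1, 2, 30.0, 1.9))
            sys_.torsions.append((0, 1, 2, 3, 2.0, 3, 0.4))
        hybrid = ax.build_hybrid(pair)
        ev = ax.HybridEvaluator(hybrid)
        rng = np.random.default_rng(7)
        x = random_configuration(hybrid, rng, scale=0.15)
        f = ev.forces(x, 0.5)
        h = 1e-6
        for i in range(4):
            for axis in range(3):
                xp, xm = x.copy(), x.copy()
                xp[i, axis] += h
                xm[i, axis] -= h
                num = -(ev.energy(xp, 0.5) - ev.energy(xm, 0.5)) / (2 * h)
                assert f[i, axis] == pytest.approx(num, rel=2e-4, abs=1e-4)

    def test_identity_mutation_du_dl_zero(self):
        pair = ax.make_lj_mutation(3, 0.0, 0.0, 0.0, seed=1)
        hybrid = ax.build_hybrid(pair)
        rng = np.random.default_rng(8)
        x = random_configuration(hybrid, rng)
        assert ax.du_dlambda(hybrid, x, 0.5) == pytest.approx(0.0, abs=1e-9)

    def test_core_charge_growth_du_dl_analytic(self):
        # core charge 0 -> 1 against a fixed unit environment charge:
        # dU/dl = C q_env / r, independent of lambda
        pair = ax.make_lj_mutation(2, 0.0, 0.0, 1.0, seed=0)
        pair.old_system.charges[1] = 1.0
        pair.new_system.charges[1] = 1.0
        pair.old_system.lj_epsilon[:] = 0.0
        pair.new_system.lj_epsilon[:] = 0.0
        hybrid = ax.build_hybrid(pair)
        r = 0.42
        x = np.array([[0.0, 0.0, 0.0], [r, 0.0, 0.0]])
        expected = COULOMB_KCAL_NM / r
        for lam in (0.1, 0.5, 0.9):
            assert ax.du_dlambda(hybrid, x, lam) == pytest.approx(expected, rel=1e-6)

    def test_finite_difference_second_order(self, insertion_hybrid):
        # Richardson: error(h) ~ h^2, so err(h)/err(h/2) ~ 4
        ev = ax.HybridEvaluator(insertion_hybrid)
        rng = np.random.default_rng(9)
        x = random_configuration(insertion_hybrid, rng)
        ref = ev.du_dlambda(x, 0.5, h=1e-7)
        e1 = abs(ev.du_dlambda(x, 0.5, h=1e-2) - ref)
        e2 = abs(ev.du_dlambda(x, 0.5, h=5e-3) - ref)
        assert e1 / max(e2, 1e-15) == pytest.approx(4.0, rel=0.5)


class TestReducedPotential:
    def test_kt_scaling(self):
        assert ax.reduced_potential(0.0, 300.0) == 0.0
        assert ax.reduced_potential(kT(300.0), 300.0) == pytest.approx(1.0)
        # kT(300) = 0.59616 kcal/mol to 5 digits
        assert ax.reduced_potential(0.5961, 300.0) == pytest.approx(1.0, abs=2e-4)

    def test_nonpositive_temperature_rejected(self):
        with pytest.raises(ValueError):
            ax.reduced_potential(1.0, 0.0)
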