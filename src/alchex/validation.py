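"""Oracle-backed validation experiments.

Each function runs one self-contained experiment of the validation suite
— estimator calibration against analytic fixtures, potential-function
invariants, sampler correctness against exact enumeration, and the
diagnostics workflow on planted pathologies — and returns a flat dict of
measured quantities.  The acceptance tests and the acceptance script
both drive these functions; problem sizes are the package's desk-scale
study conditions (see docs/methods.md).
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats

from .constants import kT
from .diagnostics import (convergence_slope_test, dof_catalog,
                          dudl_dof_correlation,
                          internal_consistency, replica_mixing_report,
                          restrained_comparison)
from .estimation import (bootstrap_delta_g, decorrelate, dg_time_series,
                         statistical_inefficiency)
from .hybrid import assign_rest_region, build_hybrid
from .potential import (AlchemicalParams, HybridEvaluator, LambdaProtocol,
                        RESTParams, effective_distance)
from .reference import (DiscreteModel, enumerate_joint_density,
                        gibbs_sample_discrete, system_energy, total_variation,
                        valence_term_energy)
from .sampling import add_positional_restraints, run_arest, run_arex
from .systems import (make_charge_change_mutation, make_double_well_mutation,
                      make_harmonic_ladder, make_insertion_mutation,
                      make_lj_mutation)

E2 = math.e ** 2


# ---------------------------------------------------------------------------
# 1. MBAR vs analytic free energy on the harmonic ladder
# ---------------------------------------------------------------------------

def _harmonic_state_samples(pair, protocol, n_per_state, temperature, rng):
    """Exact Boltzmann samples of the harmonic-ladder hybrid at every
    state: the energy-interpolated restraint is harmonic at each lambda,
    so displacements are Gaussian with k(l) = (1-l)k_old + l*k_new."""
    old = pair.old_system
    centers = np.array([r[2] for r in old.restraints])
    k_old = np.array([np.broadcast_to(np.asarray(r[1]), (3,))[0]
                      for r in old.restraints])
    k_new = np.array([np.broadcast_to(np.asarray(r[1]), (3,))[0]
                      for r in pair.new_system.restraints])
    kt = kT(temperature)
    xs, states = [], []
    for s, lam in enumerate(protocol.lambdas):
        k_lam = (1.0 - lam) * k_old + lam * k_new
        sd = np.sqrt(kt / k_lam)
        disp = rng.normal(0.0, 1.0, size=(n_per_state, old.n_particles, 3)) * sd[:, None]
        xs.append(centers[None] + disp)
        states.append(np.full(n_per_state, s))
    return np.concatenate(xs), np.concatenate(states)


def harmonic_mbar_trials(seed: int, n_trials: int = 20, K: int = 12,
                         n_samples: int = 20000, n_bootstrap: int = 100,
                         temperature: float = 300.0) -> dict:
    """n_trials seeded repeats of: exact-sample the K-state harmonic
    ladder, solve MBAR, bootstrap the uncertainty, and compare with the
    closed-form Gaussian free energy difference."""
    from .estimation import ReducedPotentialMatrix
    protocol = LambdaProtocol.linear(K)
    n_per_state = n_samples // K
    successes, abs_errors, sigmas = 0, [], []
    for trial in range(n_trials):
        trial_seed = seed + trial
        pair = make_harmonic_ladder(3, 1.0, E2, temperature, seed=trial_seed)
        ev = HybridEvaluator(build_hybrid(pair))
        rng = np.random.default_rng(trial_seed)
        x, states = _harmonic_state_samples(pair, protocol, n_per_state,
                                            temperature, rng)
        u = ev.u_matrix(x, protocol.lambdas, temperature)
        matrix = ReducedPotentialMatrix(
            u=u, N_k=np.full(K, n_per_state), state_of_sample=states,
            temperature=temperature, provenance={"exact_sampling": True})
        res = bootstrap_delta_g(matrix, n_bootstrap=n_bootstrap, seed=trial_seed)
        err = abs(res.delta_g - pair.analytic_delta_g)
        successes += err < 3.0 * res.sigma
        abs_errors.append(err)
        sigmas.append(res.sigma)
    return {
        "success_fraction": successes / n_trials,
        "n_trials": n_trials,
        "mean_abs_error_kcal_mol": float(np.mean(abs_errors)),
        "mean_bootstrap_sigma_kcal_mol": float(np.mean(sigmas)),
        "analytic_delta_g_kcal_mol": 3.0 * kT(temperature),
    }


# ---------------------------------------------------------------------------
# 2. endstate equivalence on randomized fixtures
# ---------------------------------------------------------------------------

def _fixture_zoo(seed: int, n_fixtures: int):
    makers = [
        lambda s: make_harmonic_ladder(3, 1.0, 4.0, 300.0, seed=s),
        lambda s: make_lj_mutation(4, 0.05, 0.05, 0.0, seed=s),
        lambda s: make_charge_change_mutation(
            make_lj_mutation(3, 0.0, 0.0, -1.0, seed=s), 1.0),
        lambda s: make_double_well_mutation(4.5, 5.0, 300.0, seed=s),
        lambda s: make_insertion_mutation(3, seed=s),
    ]
    for i in range(n_fixtures):
        yield makers[i % len(makers)](seed + i)


def _dummy_valence(hybrid, x, side: str) -> float:
    """Valence energy of the dummy atoms at one endstate: terms owned
    solely by the opposite endstate's unique atoms."""
    e = 0.0
    for t in hybrid.terms:
        if side == "new" and t.params_old is None:
            params = t.params_new
        elif side == "old" and t.params_new is None:
            params = t.params_old
        else:
            continue
        if t.kind == "well":
            i, axis = int(t.atoms[0]), int(t.atoms[1])
            coords = np.array([[x[i, axis], 0.0, 0.0]])
        else:
            coords = x[[int(a) for a in t.atoms]]
        e += valence_term_energy(t.kind, params, coords)
    return e


def endstate_equivalence(seed: int, n_fixtures: int = 50,
                         n_configs: int = 20) -> dict:
    """|U(x; 0) - (U_old(x) + dummy-new valence)| and the symmetric check
    at lambda = 1, maximized over randomized fixtures and configurations.
    The plain-system oracle is an independent double-loop evaluation.

    Configurations are random jitters of the reference geometry;
    sterically clashed draws (|U| > 1e4 kcal/mol, deep inside the LJ
    wall) are redrawn, since an absolute comparison at the 1e-9 level is
    only meaningful where the summands are not astronomically large —
    the invariant itself holds to relative machine precision everywhere.
    """
    rng = np.random.default_rng(seed)
    worst = 0.0
    for pair in _fixture_zoo(seed, n_fixtures):
        hybrid = build_hybrid(pair)
        ev = HybridEvaluator(hybrid)
        for _ in range(n_configs):
            scale = 0.08
            for _attempt in range(50):
                x = hybrid.positions0 + rng.normal(0.0, scale,
                                                   size=(hybrid.n_atoms, 3))
                if max(abs(ev.energy(x, 0.0)), abs(ev.energy(x, 1.0))) < 1e4:
                    break
                scale *= 0.8
            x_old = np.zeros((pair.old_system.n_particles, 3))
            x_new = np.zeros((pair.new_system.n_particles, 3))
            for h in range(hybrid.n_atoms):
                if hybrid.old_index[h] >= 0:
                    x_old[hybrid.old_index[h]] = x[h]
                if hybrid.new_index[h] >= 0:
                    x_new[hybrid.new_index[h]] = x[h]
            d0 = abs(ev.energy(x, 0.0)
                     - (system_energy(pair.old_system, x_old)
                        + _dummy_valence(hybrid, x, "new")))
            d1 = abs(ev.energy(x, 1.0)
                     - (system_energy(pair.new_system, x_new)
                        + _dummy_valence(hybrid, x, "old")))
            worst = max(worst, d0, d1)
    return {"max_abs_endstate_error_kcal_mol": float(worst),
            "n_fixtures": n_fixtures, "n_configs": n_configs}


# ---------------------------------------------------------------------------
# 3. charge conservation
# ---------------------------------------------------------------------------

def charge_conservation(seed: int, n_lambdas: int = 41) -> dict:
    lams = np.linspace(0.0, 1.0, n_lambdas)
    base = make_lj_mutation(3, 0.0, 0.0, -1.0, seed=seed)
    balanced = make_charge_change_mutation(base, 1.0)
    ev_b = HybridEvaluator(build_hybrid(balanced))
    q_b = ev_b.charges(lams).sum(axis=1)
    max_const_dev = float(np.abs(q_b - q_b[0]).max())
    ev_u = HybridEvaluator(build_hybrid(base))
    q_u = ev_u.charges(lams).sum(axis=1)
    q_old = base.old_system.total_charge()
    q_new = base.new_system.total_charge()
    expected = (1.0 - lams) * q_old + lams * q_new
    max_linear_dev = float(np.abs(q_u - expected).max())
    return {"max_total_charge_deviation_e": max_const_dev,
            "max_linearity_deviation_e": max_linear_dev}


# ---------------------------------------------------------------------------
# 4. softcore regularity
# ---------------------------------------------------------------------------

def softcore_regularity(seed: int) -> dict:
    pair = make_insertion_mutation(3, seed=seed)
    hybrid = build_hybrid(pair)
    ev = HybridEvaluator(hybrid)
    uo = sorted(hybrid.atom_classes.unique_old)[0]
    un = sorted(hybrid.atom_classes.unique_new)[0]
    env = sorted(hybrid.atom_classes.environment)[0]
    finite = True
    worst = 0.0
    for coincident, lams in ((un, np.linspace(0.0, 0.95, 12)),
                             (uo, np.linspace(0.05, 1.0, 12))):
        x = hybrid.positions0.copy()
        x[coincident] = x[env]          # exactly on top of an interacting atom
        for lam in lams:
            e = ev.energy(x, float(lam))
            finite &= bool(np.isfinite(e))
            worst = max(worst, abs(e))
    params = AlchemicalParams()
    r = 0.37
    reff_dev = max(abs(effective_distance(r, lam, (0, 0), params) - r)
                   for lam in np.linspace(0, 1, 11))
    return {"finite_at_coincidence": float(finite),
            "max_abs_energy_kcal_mol": float(worst),
            "non_unique_reff_deviation_nm": float(reff_dev)}


# ---------------------------------------------------------------------------
# 5. REST endstate invariance + Tmax=T0 reproduces AREX bitwise
# ---------------------------------------------------------------------------

def rest_endstate_invariance(seed: int, n_configs: int = 25) -> dict:
    pair = make_double_well_mutation(4.5, 5.0, 300.0, seed=seed)
    hybrid = assign_rest_region(build_hybrid(pair),
                                build_hybrid(pair).positions0, 0.5)
    params = AlchemicalParams()
    rest = RESTParams(T0=300.0, Tmax=600.0)
    ev_plain = HybridEvaluator(hybrid, params, rest=None)
    ev_rest = HybridEvaluator(hybrid, params, rest=rest)
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        x = hybrid.positions0 + rng.normal(0.0, 0.1, size=(hybrid.n_atoms, 3))
        for lam in (0.0, 1.0):
            worst = max(worst, abs(ev_rest.energy(x, lam) - ev_plain.energy(x, lam)))
    protocol = LambdaProtocol.linear(6)
    common = dict(n_iterations=30, steps_per_iteration=10, temperature=300.0,
                  seed=seed)
    rec_arex = run_arex(hybrid, protocol, params, **common)
    rec_tmax0 = run_arest(hybrid, protocol, params, RESTParams(300.0, 300.0),
                          **common)
    bitwise = (np.array_equal(rec_arex.u_kn, rec_tmax0.u_kn)
               and np.array_equal(rec_arex.state_history, rec_tmax0.state_history)
               and np.array_equal(rec_arex.dudl, rec_tmax0.dudl))
    return {"max_endstate_potential_diff_kcal_mol": float(worst),
            "tmax_equals_t0_bitwise_identical": float(bitwise)}


# ---------------------------------------------------------------------------
# 6. swap-kernel correctness on the enumerable 2x2 model
# ---------------------------------------------------------------------------

def swap_kernel_check(seed: int, n_sweeps: int = 100000) -> dict:
    model = DiscreteModel(u=np.array([[0.0, 1.3], [0.9, 0.2]]))
    exact = enumerate_joint_density(model)
    empirical = gibbs_sample_discrete(model, n_sweeps, seed=seed)
    return {"total_variation_distance": float(total_variation(exact, empirical)),
            "n_sweeps": n_sweeps}


# ---------------------------------------------------------------------------
# 7. replica random walk through all states
# ---------------------------------------------------------------------------

def replica_random_walk(seed: int, K: int = 12, n_iterations: int = 600,
                        steps_per_iteration: int = 20) -> dict:
    """Chi-square uniformity of per-replica state occupancy (computed on
    inefficiency-thinned state sequences, since the raw series is
    autocorrelated) and the minimum round-trip count."""
    pair = make_harmonic_ladder(3, 1.0, E2, 300.0, seed=seed)
    hybrid = build_hybrid(pair)
    record = run_arex(hybrid, LambdaProtocol.linear(K), AlchemicalParams(),
                      n_iterations=n_iterations,
                      steps_per_iteration=steps_per_iteration,
                      temperature=300.0, seed=seed)
    mix = replica_mixing_report(record)
    p_values = []
    for r in range(record.n_replicas):
        s = record.state_history[:, r].astype(float)
        g = statistical_inefficiency(s).g if np.std(s) > 0 else 1.0
        thin = record.state_history[::max(1, math.ceil(g)), r]
        counts = np.bincount(thin, minlength=K)
        p_values.append(float(stats.chisquare(counts).pvalue))
    return {"min_occupancy_pvalue": float(min(p_values)),
            "min_round_trips": int(mix.round_trips.min()),
            "bottleneck": float(mix.bottleneck),
            "subdominant_eigenvalue": mix.subdominant_eigenvalue}


# ---------------------------------------------------------------------------
# 8. statistical-inefficiency calibration
# ---------------------------------------------------------------------------

def inefficiency_calibration(seed: int, n: int = 100000, phi: float = 0.9) -> dict:
    rng = np.random.default_rng(seed)
    g_iid = statistical_inefficiency(rng.normal(size=n)).g
    eps = rng.normal(size=n)
    ar = np.empty(n)
    ar[0] = eps[0] / math.sqrt(1 - phi * phi)
    for t in range(1, n):
        ar[t] = phi * ar[t - 1] + eps[t]
    g_ar1 = statistical_inefficiency(ar).g
    expected = (1 + phi) / (1 - phi)
    return {"g_iid": float(g_iid), "g_ar1": float(g_ar1),
            "g_ar1_expected": expected,
            "g_ar1_relative_error": float(abs(g_ar1 - expected) / expected)}


# ---------------------------------------------------------------------------
# 9. forward/reverse internal consistency
# ---------------------------------------------------------------------------

def forward_reverse_trials(seed: int, n_trials: int = 20, K: int = 12,
                           n_iterations: int = 250,
                           steps_per_iteration: int = 20,
                           n_bootstrap: int = 100) -> dict:
    protocol = LambdaProtocol.linear(K)
    params = AlchemicalParams()
    consistent = 0
    discrepancies = []
    for trial in range(n_trials):
        s = seed + trial
        fwd_pair = make_lj_mutation(2, 0.03, 0.0, 0.0, seed=s)
        results = {}
        for label, pair in (("fwd", fwd_pair), ("rev", fwd_pair.reversed())):
            hybrid = build_hybrid(pair)
            rec = run_arex(hybrid, protocol, params, n_iterations=n_iterations,
                           steps_per_iteration=steps_per_iteration,
                           temperature=300.0, seed=s + (0 if label == "fwd" else 10000))
            results[label] = bootstrap_delta_g(decorrelate(rec),
                                               n_bootstrap=n_bootstrap, seed=s)
        report = internal_consistency(results["fwd"], results["rev"])
        consistent += report.consistent
        discrepancies.append(report.discrepancy)
    return {"consistent_fraction": consistent / n_trials,
            "n_trials": n_trials,
            "mean_abs_discrepancy_kcal_mol": float(np.mean(np.abs(discrepancies))),
            "rmse_discrepancy_kcal_mol": float(np.sqrt(np.mean(np.square(discrepancies))))}


# ---------------------------------------------------------------------------
# 10 + 12. slow-DOF detection and the restrained diagnosis
# ---------------------------------------------------------------------------

_DOF_SPECS = [
    {"name": "slow_dof", "kind": "coordinate", "particle": 1, "axis": 0,
     "category": "sidechain_torsion"},
    {"name": "contact_0_2", "kind": "distance", "i": 0, "j": 2,
     "category": "intra_contact"},
    {"name": "contact_0_3", "kind": "distance", "i": 0, "j": 3,
     "category": "inter_contact"},
    {"name": "torsion_0123", "kind": "torsion", "quadruple": (0, 1, 2, 3),
     "category": "backbone_torsion"},
    {"name": "neighbors", "kind": "neighbor_count", "radius": 0.8,
     "category": "neighbor_waters"},
]


def slow_dof_and_restrained(seed: int, n_seeds: int = 5, K: int = 12,
                            n_iterations: int = 100,
                            steps_per_iteration: int = 100) -> dict:
    """Planted-pathology workflow on the double-well fixture: the
    correlation table must rank the slow coordinate as the max-|PCC|
    entry, the slope test must flag the short run as unconverged, and the
    restrained-vs-unrestrained comparison must return the
    conformational-sampling verdict.  A harmonic control pair must come
    back clean."""
    protocol = LambdaProtocol.linear(K)
    params = AlchemicalParams()
    detect = unconverged = conf_verdicts = 0
    for i in range(1, n_seeds + 1):
        pair = make_double_well_mutation(4.5, 5.0, 300.0, seed=i)
        hybrid = build_hybrid(pair)
        rec = run_arex(hybrid, protocol, params, n_iterations=n_iterations,
                       steps_per_iteration=steps_per_iteration,
                       temperature=300.0, seed=seed + i,
                       observables=list(_DOF_SPECS))
        catalog = dof_catalog(rec, hybrid, _DOF_SPECS)
        table = dudl_dof_correlation(rec, catalog, n_bootstrap=200, seed=seed)
        valid = table.table[~table.table["degenerate"]]
        top = valid["pcc"].abs().idxmax()
        detect += (top == "slow_dof")
        # a finely resolved series (one point per few recording intervals)
        # gives the trailing-window regression enough points to resolve
        # slopes near the threshold
        series = dg_time_series(rec, n_points=20, n_bootstrap=20, seed=seed)
        verdict = convergence_slope_test(series)
        unconverged += (not verdict.converged)
        restrained = add_positional_restraints(hybrid, "slow_dof", 50.0)
        rec_r = run_arex(restrained, protocol, params, n_iterations=n_iterations,
                         steps_per_iteration=steps_per_iteration,
                         temperature=300.0, seed=seed + i)
        series_r = dg_time_series(rec_r, n_points=20, n_bootstrap=20, seed=seed)
        comparison = restrained_comparison(series, series_r)
        conf_verdicts += (comparison["verdict"] == "conformational-sampling problem")
    # harmonic control: both series converge, no problem detected
    pair = make_harmonic_ladder(3, 1.0, E2, 300.0, seed=seed)
    hybrid = build_hybrid(pair)
    rec = run_arex(hybrid, protocol, params, n_iterations=n_iterations,
                   steps_per_iteration=25, temperature=300.0, seed=seed)
    rec_r = run_arex(add_positional_restraints(hybrid, "mutating", 50.0),
                     protocol, params, n_iterations=n_iterations,
                     steps_per_iteration=25, temperature=300.0, seed=seed)
    control = restrained_comparison(
        dg_time_series(rec, n_points=8, n_bootstrap=20, seed=seed),
        dg_time_series(rec_r, n_points=8, n_bootstrap=20, seed=seed))
    return {"slow_dof_top_ranked_fraction": detect / n_seeds,
            "unconverged_fraction": unconverged / n_seeds,
            "conformational_verdict_fraction": conf_verdicts / n_seeds,
            "harmonic_control_verdict": control["verdict"],
            "n_seeds": n_seeds}


# ---------------------------------------------------------------------------
# 11. AREST benefit on the planted slow degree of freedom
# ---------------------------------------------------------------------------

def arest_benefit(seed: int, n_seeds: int = 5, K: int = 12,
                  n_iterations: int = 200, steps_per_iteration: int = 100,
                  tmax: float = 600.0, radius: float = 0.5) -> dict:
    """Paired AREX/AREST runs on the double-well fixture: mean-over-replica
    statistical inefficiency of the slow coordinate must be strictly
    smaller under solute tempering."""
    protocol = LambdaProtocol.linear(K)
    params = AlchemicalParams()
    wins = 0
    g_pairs = []
    for i in range(1, n_seeds + 1):
        pair = make_double_well_mutation(4.5, 5.0, 300.0, seed=i)
        hybrid = build_hybrid(pair)
        rec_x = run_arex(hybrid, protocol, params, n_iterations=n_iterations,
                         steps_per_iteration=steps_per_iteration,
                         temperature=300.0, seed=seed + i)
        hybrid_r = assign_rest_region(build_hybrid(pair), hybrid.positions0, radius)
        rec_t = run_arest(hybrid_r, protocol, params, RESTParams(300.0, tmax),
                          n_iterations=n_iterations,
                          steps_per_iteration=steps_per_iteration,
                          temperature=300.0, seed=seed + i)

        def g_mean(rec):
            return float(np.mean([statistical_inefficiency(
                rec.observables["slow_dof"][:, r]).g
                for r in range(rec.n_replicas)]))

        gx, gt = g_mean(rec_x), g_mean(rec_t)
        wins += gt < gx
        g_pairs.append((gx, gt))
    return {"arest_better_fraction": wins / n_seeds,
            "mean_g_arex": float(np.mean([p[0] for p in g_pairs])),
            "mean_g_arest": float(np.mean([p[1] for p in g_pairs])),
            "n_seeds": n_seeds}
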