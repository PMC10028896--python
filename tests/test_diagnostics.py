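"""Convergence slope test, mixing report, DOF correlations, consistency."""

import numpy as np
import pandas as pd
import pytest

import alchex as ax
from alchex.diagnostics import CorrelationTable, correlation_summary
from alchex.estimation import FreeEnergyResult
from alchex.sampling import RunRecord


def _series(times, values):
    return [(t, v, 0.05) for t, v in zip(times, values)]


def _result(dg, lo, hi, sigma=0.1):
    return FreeEnergyResult(f_k=np.array([0.0]), delta_g=dg, sigma=sigma,
                            n_bootstrap=100, ci95=(lo, hi), temperature=300.0)


class TestConvergenceSlopeTest:
    def test_flat_series_converges(self):
        v = ax.convergence_slope_test(_series(range(10), [2.0] * 10))
        assert v.converged and v.slope == 0.0

    def test_noiseless_drift_fails(self):
        t = np.arange(20, dtype=float)
        v = ax.convergence_slope_test(_series(t, 0.3 * t))
        assert v.slope == pytest.approx(0.3, abs=1e-12)
        assert not v.converged

    def test_type_one_error_near_nominal(self):
        # flat + noise calibrated so SE(slope) ~ threshold/2: the 2*SE rule
        # should wrongly reject only a few percent of the time
        rng = np.random.default_rng(0)
        t = np.arange(50, dtype=float)
        false_rejects = 0
        n_rep = 500
        for _ in range(n_rep):
            noise_sd = 0.05 * np.sqrt(np.sum((t[25:] - t[25:].mean()) ** 2))
            y = rng.normal(0.0, noise_sd, size=50)
            v = ax.convergence_slope_test(_series(t, y), threshold=0.0)
            false_rejects += not v.converged
        assert 0.02 <= false_rejects / n_rep <= 0.10

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="window"):
            ax.convergence_slope_test(_series(range(5), range(5)), window=100.0)


class TestMixingReport:
    def test_single_state_trivially_unbottlenecked(self):
        rec = RunRecord(lambdas=(0.0,), temperature=300.0,
                        u_kn=np.zeros((10, 1, 1)),
                        state_history=np.zeros((10, 1), dtype=int),
                        dudl=np.zeros((10, 1)))
        mix = ax.replica_mixing_report(rec)
        assert not mix.bottleneck
        assert mix.occupancy[0, 0] == 1.0

    def test_pinned_replica_flags_bottleneck(self):
        T, K = 60, 3
        rng = np.random.default_rng(1)
        hist = np.empty((T, K), dtype=int)
        for t in range(T):
            hist[t] = np.roll([0, 1, 2], t % 2)  # replicas 1,2 swap; 0 cycles
        hist[:, 0] = 0  # replica 0 pinned to state 0
        hist[:, 1] = np.where(np.arange(T) % 2 == 0, 1, 2)
        hist[:, 2] = np.where(np.arange(T) % 2 == 0, 2, 1)
        rec = RunRecord(lambdas=(0.0, 0.5, 1.0), temperature=300.0,
                        u_kn=np.zeros((T, K, K)), state_history=hist,
                        dudl=np.zeros((T, K)))
        mix = ax.replica_mixing_report(rec)
        assert mix.bottleneck
        assert mix.states_visited[0] == 1

    def test_uniform_permutation_process_mixes(self):
        rng = np.random.default_rng(2)
        T, K = 3000, 4
        hist = np.array([rng.permutation(K) for _ in range(T)])
        rec = RunRecord(lambdas=tuple(np.linspace(0, 1, K)), temperature=300.0,
                        u_kn=np.zeros((T, K, K)), state_history=hist,
                        dudl=np.zeros((T, K)))
        mix = ax.replica_mixing_report(rec)
        assert not mix.bottleneck
        # iid uniform states: transition matrix ~ 1/K everywhere, subdominant
        # eigenvalue near zero
        assert mix.subdominant_eigenvalue < 0.1
        assert mix.round_trips.min() >= 1


@pytest.fixture(scope="module")
def record_with_positions():
    pair = ax.make_double_well_mutation(4.5, 5.0, 300.0, seed=2)
    hybrid = ax.build_hybrid(pair)
    rec = ax.run_arex(hybrid, ax.LambdaProtocol.linear(3),
                      ax.AlchemicalParams(), n_iterations=40,
                      steps_per_iteration=5, temperature=300.0, seed=3,
                      store_positions=True)
    return rec, hybrid


class TestDofCatalog:

    def test_catalog_from_stored_positions(self, record_with_positions):
        rec, hybrid = record_with_positions
        specs = [{"name": "d02", "kind": "distance", "i": 0, "j": 2,
                  "category": "intra_contact"},
                 {"name": "phi", "kind": "torsion", "quadruple": (0, 1, 2, 3),
                  "category": "backbone_torsion"}]
        cat = ax.dof_catalog(rec, hybrid, specs)
        assert cat["series"]["d02"].shape == (40, 3)
        assert cat["category"]["phi"] == "backbone_torsion"
        phi = cat["series"]["phi"]
        finite = phi[np.isfinite(phi)]
        assert np.all((finite > -180.0) & (finite <= 180.0))

    def test_unknown_category_rejected(self, record_with_positions):
        rec, hybrid = record_with_positions
        with pytest.raises(ValueError, match="category"):
            ax.dof_catalog(rec, hybrid, [{"name": "x", "kind": "distance",
                                          "i": 0, "j": 1, "category": "bogus"}])

    def test_zero_radius_neighbor_count_is_zero(self, record_with_positions):
        rec, hybrid = record_with_positions
        cat = ax.dof_catalog(rec, hybrid, [{"name": "n", "kind": "neighbor_count",
                                            "radius": 0.0,
                                            "category": "neighbor_waters"}])
        assert np.all(cat["series"]["n"] == 0.0)


class TestDudlDofCorrelation:
    def _record(self, T=400, R=4, rho=0.7, seed=0):
        rng = np.random.default_rng(seed)
        dudl = rng.normal(size=(T, R))
        corr = rho * dudl + np.sqrt(1 - rho ** 2) * rng.normal(size=(T, R))
        indep = rng.normal(size=(T, R))
        rec = RunRecord(lambdas=(0.0, 1.0), temperature=300.0,
                        u_kn=np.zeros((T, 2, R)),
                        state_history=np.tile([0, 1, 0, 1], (T, 1)),
                        dudl=dudl,
                        observables={"coupled": corr, "decoy": indep,
                                     "flat": np.ones((T, R))})
        catalog = {"series": rec.observables,
                   "category": {"coupled": "sidechain_torsion",
                                "decoy": "intra_contact",
                                "flat": "inter_contact"}}
        return rec, catalog

    def test_self_correlation_is_unity(self):
        rec, catalog = self._record()
        catalog["series"]["self"] = rec.dudl
        catalog["category"]["self"] = "backbone_torsion"
        table = ax.dudl_dof_correlation(rec, catalog, n_bootstrap=50)
        assert table.table.loc["self", "pcc"] == pytest.approx(1.0)

    def test_planted_rho_recovered_within_ci(self):
        rec, catalog = self._record(rho=0.7, seed=1)
        table = ax.dudl_dof_correlation(rec, catalog, n_bootstrap=400)
        row = table.table.loc["coupled"]
        assert row["ci_lo"] - 0.05 <= 0.7 <= row["ci_hi"] + 0.05
        decoy = table.table.loc["decoy"]
        assert abs(decoy["pcc"]) < 0.2

    def test_zero_variance_observable_flagged(self):
        rec, catalog = self._record()
        table = ax.dudl_dof_correlation(rec, catalog, n_bootstrap=20)
        assert bool(table.table.loc["flat", "degenerate"])

    def test_planted_correlations_recovered_across_signs(self):
        hits = 0
        trials = 20
        for s in range(trials):
            for rho in (-0.7, 0.0, 0.7):
                rec, catalog = self._record(T=300, rho=rho, seed=100 + s)
                table = ax.dudl_dof_correlation(rec, catalog, n_bootstrap=100,
                                                seed=s)
                row = table.table.loc["coupled"]
                if row["ci_lo"] - 0.06 <= rho <= row["ci_hi"] + 0.06:
                    hits += 1
        assert hits / (3 * trials) >= 0.9


class TestCorrelationSummary:
    def _table(self, entries, g):
        df = pd.DataFrame(entries, columns=["dof", "category", "pcc", "ci_lo",
                                            "ci_hi", "degenerate"]).set_index("dof")
        return CorrelationTable(table=df, per_replica=pd.DataFrame(), dudl_g=g)

    def test_single_entry_category(self):
        t = self._table([("a", "intra_contact", 0.5, 0.4, 0.6, False)], 1.0)
        s = correlation_summary(t)
        assert s.iloc[0]["intra_contact"] == 0.5

    def test_max_abs_with_sign_preserved(self):
        t = self._table([("a", "intra_contact", 0.3, 0.2, 0.4, False),
                         ("b", "intra_contact", -0.8, -0.9, -0.7, False)], 1.0)
        s = correlation_summary(t)
        assert s.iloc[0]["intra_contact"] == pytest.approx(0.8)
        assert s.iloc[0]["intra_contact_pcc_signed"] == pytest.approx(-0.8)

    def test_rows_ordered_by_dudl_inefficiency(self):
        tables = {"fast": self._table([("a", "intra_contact", 0.2, 0.1, 0.3,
                                        False)], 0.5),
                  "slow": self._table([("a", "intra_contact", 0.9, 0.8, 1.0,
                                        False)], 6.4)}
        s = correlation_summary(tables)
        assert list(s.index) == ["slow", "fast"]
        assert s["dudl_g"].is_monotonic_decreasing


class TestInternalConsistency:
    def test_matching_pair_consistent(self):
        r = ax.internal_consistency(_result(2.0, 1.8, 2.2),
                                    _result(-2.0, -2.2, -1.8))
        assert r.consistent and r.discrepancy == pytest.approx(0.0)

    def test_mutual_ci_rule_failure(self):
        r = ax.internal_consistency(_result(2.0, 1.8, 2.2),
                                    _result(-4.0, -4.2, -3.8))
        assert not r.consistent
        assert r.discrepancy == pytest.approx(-2.0)

    def test_rule_symmetric_under_direction_exchange(self):
        for fwd, rev in [((2.0, 1.8, 2.2), (-4.0, -4.2, -3.8)),
                         ((1.0, 0.5, 1.5), (-1.2, -1.4, -1.0))]:
            a = ax.internal_consistency(_result(*fwd), _result(*rev))
            b = ax.internal_consistency(_result(*rev), _result(*fwd))
            assert a.consistent == b.consistent

    def test_rmse_mue_of_zero_set(self):
        m = ax.consistency_metrics([0.0, 0.0, 0.0], n_bootstrap=100)
        assert m["rmse"] == 0.0 and m["mue"] == 0.0
        assert m["rmse_ci95"] == (0.0, 0.0)


class TestRestrainedComparison:
    def test_restrained_flat_unrestrained_drifting(self):
        t = np.arange(20, dtype=float)
        out = ax.restrained_comparison(_series(t, 0.5 * t), _series(t, [1.0] * 20))
        assert out["verdict"] == "conformational-sampling problem"

    def test_both_flat_is_clean(self):
        t = np.arange(20, dtype=float)
        out = ax.restrained_comparison(_series(t, [1.0] * 20), _series(t, [0.3] * 20))
        assert out["verdict"] == "no detected problem"

    def test_both_drifting_not_solely_conformational(self):
        t = np.arange(20, dtype=float)
        out = ax.restrained_comparison(_series(t, 0.5 * t), _series(t, 0.4 * t))
        assert out["verdict"] == "not solely conformational"
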