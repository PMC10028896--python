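"""Statistical inefficiency, decorrelation, MBAR, bootstrap, DG(t)."""

import math

import numpy as np
import pytest

import alchex as ax
from alchex.constants import kT
from alchex.estimation import ReducedPotentialMatrix
from alchex.reference import bar_solve


def _gaussian_two_state_matrix(k1, k2, n, seed, temperature=300.0):
    """Exact samples from two 1-D harmonic states; u in kT units."""
    rng = np.random.default_rng(seed)
    kt = kT(temperature)
    x1 = rng.normal(0.0, math.sqrt(kt / k1), n)
    x2 = rng.normal(0.0, math.sqrt(kt / k2), n)
    xs = np.concatenate([x1, x2])
    u = np.stack([0.5 * k1 * xs ** 2, 0.5 * k2 * xs ** 2]) / kt
    return ReducedPotentialMatrix(
        u=u, N_k=np.array([n, n]),
        state_of_sample=np.repeat([0, 1], n), temperature=temperature)


class TestStatisticalInefficiency:
    def test_iid_series_has_unit_g(self):
        rng = np.random.default_rng(0)
        g = ax.statistical_inefficiency(rng.normal(size=100000))
        assert 0.9 <= g.g <= 1.2

    def test_ar1_matches_closed_form(self):
        phi, n = 0.9, 100000
        rng = np.random.default_rng(1)
        x = np.empty(n)
        x[0] = rng.normal()
        eps = rng.normal(size=n)
        for t in range(1, n):
            x[t] = phi * x[t - 1] + eps[t]
        g = ax.statistical_inefficiency(x).g
        assert abs(g - 19.0) / 19.0 < 0.2

    def test_pointwise_duplication_doubles_g(self):
        rng = np.random.default_rng(2)
        base = rng.normal(size=30000)
        g1 = ax.statistical_inefficiency(base).g
        g2 = ax.statistical_inefficiency(np.repeat(base, 2)).g
        assert g2 / g1 == pytest.approx(2.0, rel=0.15)

    def test_constant_series_degenerate(self):
        g = ax.statistical_inefficiency(np.ones(100))
        assert g.g == 1.0 and g.degenerate

    def test_time_units_scale(self):
        rng = np.random.default_rng(3)
        g = ax.statistical_inefficiency(rng.normal(size=1000), sampling_interval=0.1)
        assert g.g_time == pytest.approx(0.1 * g.g)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError, match="short"):
            ax.statistical_inefficiency(np.arange(5))


class TestDecorrelate:
    def test_burn_in_counting(self, harmonic_record):
        m = ax.decorrelate(harmonic_record, burn_in=0.5, stride=1)
        kept = harmonic_record.n_iterations - harmonic_record.n_iterations // 2
        assert m.N_total == kept * harmonic_record.n_replicas

    def test_unit_stride_is_identity_after_burn_in(self, harmonic_record):
        m = ax.decorrelate(harmonic_record, burn_in=0.0, stride=1)
        assert m.N_total == harmonic_record.n_iterations * harmonic_record.n_replicas

    def test_planted_ar1_dudl_sets_stride(self, harmonic_record):
        import copy
        rec = copy.copy(harmonic_record)
        phi = 0.9
        rng = np.random.default_rng(4)
        T, R = rec.dudl.shape
        dudl = np.empty((T, R))
        dudl[0] = rng.normal(size=R)
        eps = rng.normal(size=(T, R))
        for t in range(1, T):
            dudl[t] = phi * dudl[t - 1] + eps[t]
        rec.dudl = dudl
        m = ax.decorrelate(rec, burn_in=0.0)
        # integrated AR(1) inefficiency ~19, but short series truncate low;
        # the stride must at least reflect strong correlation
        assert m.provenance["stride"] >= 5

    def test_too_few_samples_raises(self, harmonic_record):
        import copy
        rec = copy.copy(harmonic_record)
        rec.u_kn = rec.u_kn[:6]
        rec.state_history = rec.state_history[:6]
        rec.dudl = rec.dudl[:6]
        rec.observables = {}
        with pytest.raises(ValueError, match="decorrelated samples"):
            ax.decorrelate(rec, burn_in=0.0, stride=2)


class TestMBAR:
    def test_identical_states_zero_difference(self):
        rng = np.random.default_rng(5)
        u = np.tile(rng.normal(size=2000), (2, 1))
        f = ax.mbar_solve(u, np.array([1000, 1000]))
        assert f[1] == pytest.approx(0.0, abs=1e-10)

    def test_two_state_harmonic_analytic(self):
        n = 50000
        m = _gaussian_two_state_matrix(1.0, 4.0, n, seed=6)
        f = ax.mbar_solve(m)
        expected = 0.5 * math.log(4.0)
        # asymptotic SE of BAR/MBAR for this overlap is ~1/sqrt(n)
        assert f[1] == pytest.approx(expected, abs=3 * 2.0 / math.sqrt(n))

    def test_mbar_reduces_to_bar_for_two_states(self):
        m = _gaussian_two_state_matrix(1.0, 3.0, 4000, seed=7)
        f = ax.mbar_solve(m)
        w_f = m.u[1, :4000] - m.u[0, :4000]
        w_r = m.u[0, 4000:] - m.u[1, 4000:]
        df_bar = bar_solve(w_f, w_r)
        assert f[1] == pytest.approx(df_bar, abs=1e-6)

    def test_zero_sample_perturbation_state_consistent(self):
        n = 20000
        rng = np.random.default_rng(8)
        kt = kT(300.0)
        k1, k2, kmid = 1.0, 4.0, 2.0
        x1 = rng.normal(0, math.sqrt(kt / k1), n)
        x2 = rng.normal(0, math.sqrt(kt / k2), n)
        xs = np.concatenate([x1, x2])
        u3 = np.stack([0.5 * k1 * xs ** 2, 0.5 * kmid * xs ** 2,
                       0.5 * k2 * xs ** 2]) / kt
        f3 = ax.mbar_solve(u3, np.array([n, 0, n]))
        u2 = u3[[0, 2]]
        f2 = ax.mbar_solve(u2, np.array([n, n]))
        assert f3[2] == pytest.approx(f2[1], abs=1e-8)
        assert f3[1] == pytest.approx(0.5 * math.log(kmid / k1), abs=0.05)

    def test_gauge_invariance_per_sample_shift(self):
        m = _gaussian_two_state_matrix(1.0, 2.5, 3000, seed=9)
        f_ref = ax.mbar_solve(m)
        shifted = m.u.copy()
        shifted[:, 100] += 7.3   # same constant added to one sample at all states
        f_shift = ax.mbar_solve(shifted, m.N_k)
        assert f_shift[1] == pytest.approx(f_ref[1], abs=1e-9)

    def test_estimator_consistency_with_sample_size(self):
        expected = 0.5 * math.log(4.0)
        errs = []
        for n in (1000, 10000, 50000):
            m = _gaussian_two_state_matrix(1.0, 4.0, n, seed=10)
            errs.append(abs(ax.mbar_solve(m)[1] - expected))
        assert errs[2] < errs[0]


class TestBootstrap:
    def test_degenerate_matrix_zero_sigma(self):
        u = np.zeros((2, 100))
        m = ReducedPotentialMatrix(u=u, N_k=np.array([50, 50]),
                                   state_of_sample=np.repeat([0, 1], 50),
                                   temperature=300.0)
        res = ax.bootstrap_delta_g(m, n_bootstrap=20, seed=0)
        assert res.sigma == pytest.approx(0.0, abs=1e-12)
        assert res.delta_g == pytest.approx(0.0)

    def test_bootstrap_sigma_tracks_replication_sd(self):
        # repeated-experiment oracle: SD of delta-G over independent
        # realizations vs the bootstrap sigma of one realization
        expected_sd = []
        for s in range(25):
            m = _gaussian_two_state_matrix(1.0, 4.0, 2000, seed=100 + s)
            expected_sd.append(ax.mbar_solve(m)[1] * kT(300.0))
        sd_true = np.std(expected_sd, ddof=1)
        m = _gaussian_two_state_matrix(1.0, 4.0, 2000, seed=100)
        res = ax.bootstrap_delta_g(m, n_bootstrap=100, seed=1)
        assert res.sigma == pytest.approx(sd_true, rel=0.5)

    def test_seed_determinism(self):
        m = _gaussian_two_state_matrix(1.0, 4.0, 1500, seed=11)
        a = ax.bootstrap_delta_g(m, n_bootstrap=30, seed=5)
        b = ax.bootstrap_delta_g(m, n_bootstrap=30, seed=5)
        assert a.delta_g == b.delta_g and a.sigma == b.sigma
        c = ax.bootstrap_delta_g(m, n_bootstrap=30, seed=6)
        assert c.sigma == pytest.approx(a.sigma, rel=0.5)

    def test_ci_contains_point_estimate(self):
        m = _gaussian_two_state_matrix(1.0, 2.0, 2000, seed=12)
        res = ax.bootstrap_delta_g(m, n_bootstrap=50, seed=2)
        assert res.ci95[0] <= res.delta_g <= res.ci95[1]


class TestDeltaDeltaG:
    def _result(self, dg, sigma):
        from alchex.estimation import FreeEnergyResult
        return FreeEnergyResult(f_k=np.array([0.0]), delta_g=dg, sigma=sigma,
                                n_bootstrap=100, ci95=(dg - 2 * sigma, dg + 2 * sigma),
                                temperature=300.0)

    def test_identical_phases_cancel(self):
        r = ax.delta_delta_g(self._result(1.0, 0.1), self._result(1.0, 0.1))
        assert r.delta_g == 0.0
        assert r.sigma == pytest.approx(math.sqrt(2) * 0.1)

    def test_quadrature_combination(self):
        r = ax.delta_delta_g(self._result(1.0, 0.1), self._result(3.0, 0.1))
        assert r.delta_g == pytest.approx(2.0)
        assert r.sigma == pytest.approx(0.141, abs=1e-3)

    def test_antisymmetry(self):
        a, b = self._result(1.0, 0.1), self._result(3.0, 0.2)
        assert ax.delta_delta_g(a, b).delta_g == -ax.delta_delta_g(b, a).delta_g


class TestDgTimeSeries:
    def test_flat_for_stationary_harmonic(self, harmonic_record, harmonic_pair):
        series = ax.dg_time_series(harmonic_record, n_points=6, n_bootstrap=20, seed=0)
        assert len(series) >= 3
        final_t, final_dg, final_sigma = series[-1]
        assert final_dg == pytest.approx(harmonic_pair.analytic_delta_g,
                                         abs=max(4 * final_sigma, 0.15))

    def test_last_point_matches_full_record_estimate(self, harmonic_record):
        series = ax.dg_time_series(harmonic_record, n_points=5, n_bootstrap=25, seed=3)
        full = ax.bootstrap_delta_g(ax.decorrelate(harmonic_record),
                                    n_bootstrap=25, seed=3)
        assert series[-1][1] == pytest.approx(full.delta_g, abs=1e-9)

    def test_too_few_points_rejected(self, harmonic_record):
        with pytest.raises(ValueError, match="3 time points"):
            ax.dg_time_series(harmonic_record, n_points=2)
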