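"""Free energy estimation from replica-exchange records.

Pipeline: discard burn-in, estimate the statistical inefficiency
g = 2*tau + 1 of a driver time series (per-replica dU/dlambda by
default, as the convergence-limiting quantity), subsample at stride
ceil(g), assemble the decorrelated reduced potential matrix u[k][n], and
solve the MBAR self-consistent equations for the dimensionless state
free energies f_k.  Uncertainties come from bootstrapping the
decorrelated matrix within each state.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .constants import kT
from .sampling import RunRecord


@dataclass
class StatisticalInefficiency:
    g: float            # samples
    g_time: float       # same quantity in nominal time units
    degenerate: bool = False

    def __float__(self):
        return float(self.g)


def statistical_inefficiency(series, sampling_interval: float = 1.0) -> StatisticalInefficiency:
    """g = 1 + 2 * sum_t (1 - t/N) C(t) with the normalized autocorrelation
    C(t) truncated at its first crossing below zero."""
    a = np.asarray(series, dtype=float).ravel()
    n = a.size
    if n < 10:
        raise ValueError(f"series too short for autocorrelation analysis (n={n})")
    if not np.all(np.isfinite(a)):
        raise ValueError("series contains non-finite values")
    a = a - a.mean()
    var = np.dot(a, a) / n
    if var <= 0 or var < 1e-15 * max(1.0, np.abs(series).max() ** 2):
        return StatisticalInefficiency(1.0, sampling_interval, degenerate=True)
    # FFT autocovariance
    m = 1 << (2 * n - 1).bit_length()
    fa = np.fft.rfft(a, m)
    acov = np.fft.irfft(fa * np.conjugate(fa), m)[:n].real / n
    c = acov / acov[0]
    g = 1.0
    for t in range(1, n):
        if c[t] < 0:
            break
        g += 2.0 * (1.0 - t / n) * c[t]
    return StatisticalInefficiency(float(g), float(g) * sampling_interval)


@dataclass
class ReducedPotentialMatrix:
    """u[k][n]: reduced potential of decorrelated sample n at state k."""
    u: np.ndarray                 # (K, N_total), kT
    N_k: np.ndarray               # samples drawn from each state
    state_of_sample: np.ndarray   # (N_total,)
    temperature: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if int(self.N_k.sum()) != self.u.shape[1]:
            raise ValueError("sum(N_k) must equal the number of samples")
        if not np.all(np.isfinite(self.u)):
            raise ValueError("reduced potential matrix contains non-finite entries")

    @property
    def K(self) -> int:
        return self.u.shape[0]

    @property
    def N_total(self) -> int:
        return self.u.shape[1]


def decorrelate(record: RunRecord, burn_in: float = 0.1,
                stride: int | None = None) -> ReducedPotentialMatrix:
    """Burn-in discard + inefficiency-based subsampling of a RunRecord.

    The subsampling stride is ceil(g) where g is the largest per-replica
    statistical inefficiency of dU/dlambda (overridable via ``stride``).
    """
    n_iter = record.n_iterations
    n_burn = int(math.floor(burn_in * n_iter))
    if stride is None:
        gmax = 1.0
        for r in range(record.n_replicas):
            s = record.dudl[n_burn:, r]
            if s.size >= 10 and np.std(s) > 0:
                gmax = max(gmax, statistical_inefficiency(s).g)
        stride = max(1, math.ceil(gmax))
    else:
        gmax = float(stride)
    keep = np.arange(n_burn, n_iter, stride)
    K = record.n_states
    cols, states = [], []
    for t in keep:
        for r in range(record.n_replicas):
            states.append(record.state_history[t, r])
            cols.append(record.u_kn[t, :, r])
    states = np.asarray(states)
    u = np.asarray(cols).T if cols else np.empty((K, 0))
    order = np.argsort(states, kind="stable")
    u = u[:, order]
    states = states[order]
    N_k = np.bincount(states, minlength=K)
    if u.shape[1] < 5 * K:
        raise ValueError(
            f"only {u.shape[1]} decorrelated samples for {K} states "
            f"(stride {stride}); run longer before estimating")
    return ReducedPotentialMatrix(
        u=u, N_k=N_k, state_of_sample=states, temperature=record.temperature,
        provenance={"burn_in": burn_in, "stride": int(stride), "g_max": float(gmax),
                    "n_iterations": n_iter, "seed": record.seed})


# ---------------------------------------------------------------------------
# MBAR
# ---------------------------------------------------------------------------

def _mbar_objective(f, u, N_k):
    """Convex MBAR negative log-likelihood and gradient (gauge-free)."""
    N = N_k.sum()
    logN = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
    log_denom = logsumexp(logN[:, None] + f[:, None] - u, axis=0)   # (N,)
    obj = log_denom.sum() / N - np.dot(N_k, f) / N
    logW = f[:, None] - u - log_denom                               # (K, N)
    grad = (N_k * np.exp(logsumexp(logW, axis=1)) - N_k) / N
    return obj, grad


def _self_consistent_update(f, u, N_k):
    logN = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
    log_denom = logsumexp(logN[:, None] + f[:, None] - u, axis=0)
    f_new = -logsumexp(-u - log_denom, axis=1)
    return f_new - f_new[0]


def _newton_step(f, u, N_k):
    """One Newton-Raphson step on the sampled-state free energies (state 0
    gauge-fixed).  The K x K Hessian of the MBAR objective is cheap, and
    quadratic convergence makes warm-started (bootstrap) solves fast."""
    logN = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
    log_denom = logsumexp(logN[:, None] + f[:, None] - u, axis=0)
    W = np.exp(f[:, None] - u - log_denom)          # (K, N), rows sum to N/N_k-ish
    NW = N_k[:, None] * W
    grad = NW.sum(axis=1) - N_k
    H = np.diag(NW.sum(axis=1)) - NW @ W.T * N_k[None, :]
    # gauge: drop state 0
    try:
        delta = np.linalg.solve(H[1:, 1:], grad[1:])
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(delta)):
        return None
    f_new = f.copy()
    f_new[1:] -= delta
    return f_new - f_new[0]


def mbar_solve(matrix: ReducedPotentialMatrix | np.ndarray,
               N_k: np.ndarray | None = None,
               tolerance: float = 1e-10, max_iterations: int = 10000,
               f_init: np.ndarray | None = None) -> np.ndarray:
    """Solve the MBAR self-consistent equations.

    f_k = -ln sum_n exp(-u_k(x_n)) / sum_l N_l exp(f_l - u_l(x_n)),
    gauge-fixed to f_0 = 0.  A quasi-Newton minimization of the convex
    MBAR objective provides the starting point, followed by
    self-consistent iteration to the requested tolerance.  States with
    N_k = 0 are pure perturbation states.
    """
    if isinstance(matrix, ReducedPotentialMatrix):
        u, N_k = matrix.u, matrix.N_k
    else:
        u = np.asarray(matrix, dtype=float)
        if N_k is None:
            raise ValueError("N_k required when passing a bare matrix")
    N_k = np.asarray(N_k, dtype=float)
    K = u.shape[0]
    if u.shape[1] != int(N_k.sum()):
        raise ValueError("matrix width inconsistent with N_k")
    f = np.zeros(K) if f_init is None else np.array(f_init, dtype=float)

    sampled = N_k > 0
    if f_init is None and sampled.sum() > 1:
        us, Ns = u[sampled], N_k[sampled]
        fs = f[sampled]
        res = minimize(lambda g: _mbar_objective(g, us, Ns), fs, jac=True,
                       method="L-BFGS-B", options={"maxiter": max_iterations,
                                                   "ftol": 1e-14, "gtol": 1e-9})
        f[sampled] = res.x - res.x[0] if sampled[0] else res.x
    # Newton on the sampled states (self-consistent fallback), then a
    # final self-consistent pass that also fills in zero-sample states
    us, Ns = u[sampled], N_k[sampled]
    fs = f[sampled] - f[sampled][0]
    converged = False
    use_newton = True
    prev_delta = np.inf
    stagnant = 0
    for it in range(max_iterations):
        f_new = _newton_step(fs, us, Ns) if use_newton else None
        if f_new is None:
            f_new = _self_consistent_update(fs, us, Ns)
        delta = np.max(np.abs(f_new - fs))
        if use_newton:
            # an ill-conditioned Hessian (near-total state overlap) makes
            # Newton stagnate above round-off; self-consistent iteration
            # is a contraction and always finishes the job
            stagnant = stagnant + 1 if delta > 0.5 * prev_delta else 0
            if stagnant >= 3:
                use_newton = False
        prev_delta = delta
        fs = f_new
        if delta < tolerance:
            converged = True
            break
    if not converged:
        raise RuntimeError(
            f"MBAR did not converge in {max_iterations} iterations "
            f"(last residual {delta:.3e})")
    f[sampled] = fs
    if not sampled.all():
        f = _self_consistent_update_perturbation(f, u, N_k, sampled)
    return f - f[0]


def _self_consistent_update_perturbation(f, u, N_k, sampled):
    """Fill in zero-sample (perturbation) states without moving the
    sampled-state solution."""
    logN = np.where(N_k > 0, np.log(np.maximum(N_k, 1)), -np.inf)
    log_denom = logsumexp(logN[sampled, None] + f[sampled, None] - u[sampled], axis=0)
    out = f.copy()
    out[~sampled] = -logsumexp(-u[~sampled] - log_denom, axis=1)
    return out


@dataclass
class FreeEnergyResult:
    f_k: np.ndarray               # dimensionless, f_0 = 0
    delta_g: float                # kcal/mol, endstate difference
    sigma: float                  # bootstrap SD, kcal/mol
    n_bootstrap: int
    ci95: tuple                   # (lo, hi), kcal/mol
    temperature: float

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")


def bootstrap_delta_g(matrix: ReducedPotentialMatrix, n_bootstrap: int = 200,
                      seed: int = 0) -> FreeEnergyResult:
    """MBAR endstate free energy difference with bootstrap uncertainty.

    Decorrelated samples are resampled with replacement within each state
    (preserving N_k); sigma is the SD of the resampled delta-G values and
    the 95% CI the 2.5/97.5 percentiles."""
    f = mbar_solve(matrix)
    kt = kT(matrix.temperature)
    dg = float((f[-1] - f[0]) * kt)
    rng = np.random.default_rng(seed)
    state_cols = [np.flatnonzero(matrix.state_of_sample == k) for k in range(matrix.K)]
    draws = []
    failures = 0
    while len(draws) < n_bootstrap:
        cols = np.concatenate([rng.choice(c, size=c.size, replace=True)
                               for c in state_cols if c.size])
        try:
            # resamples are warm-started and solved to a tolerance well
            # below the statistical scale of sigma itself
            fb = mbar_solve(matrix.u[:, cols], matrix.N_k, f_init=f,
                            tolerance=1e-8, max_iterations=5000)
        except RuntimeError:
            failures += 1
            if failures > max(10, n_bootstrap // 10):
                warnings.warn("excessive bootstrap non-convergence; "
                              "sigma computed from converged resamples only")
                break
            continue
        draws.append((fb[-1] - fb[0]) * kt)
    draws = np.asarray(draws)
    if draws.size == 0:
        raise RuntimeError("no bootstrap resample converged")
    return FreeEnergyResult(
        f_k=f, delta_g=dg, sigma=float(draws.std(ddof=1)) if draws.size > 1 else 0.0,
        n_bootstrap=int(draws.size),
        ci95=(float(np.percentile(draws, 2.5)), float(np.percentile(draws, 97.5))),
        temperature=matrix.temperature)


def delta_delta_g(phase1: FreeEnergyResult, phase2: FreeEnergyResult) -> FreeEnergyResult:
    """DDG = DG_phase2 - DG_phase1 with errors combined in quadrature."""
    if abs(phase1.temperature - phase2.temperature) > 1e-9:
        raise ValueError("phases were run at different temperatures")
    ddg = phase2.delta_g - phase1.delta_g
    sigma = math.hypot(phase1.sigma, phase2.sigma)
    return FreeEnergyResult(
        f_k=np.array([0.0]), delta_g=float(ddg), sigma=float(sigma),
        n_bootstrap=min(phase1.n_bootstrap, phase2.n_bootstrap),
        ci95=(ddg - 1.96 * sigma, ddg + 1.96 * sigma),
        temperature=phase1.temperature)


def dg_time_series(record: RunRecord, n_points: int = 10, burn_in: float = 0.1,
                   n_bootstrap: int = 50, seed: int = 0) -> list:
    """Free energy estimate as a function of included simulation time.

    Returns [(t, dg, sigma), ...] with t in nominal time units; each point
    re-runs decorrelation + MBAR + bootstrap on the record truncated at t.
    Early truncations with too few decorrelated samples are skipped.
    """
    n_iter = record.n_iterations
    if n_points < 3:
        raise ValueError("need at least 3 time points")
    ends = np.unique(np.linspace(max(record.n_states, n_iter // n_points),
                                 n_iter, n_points).astype(int))
    out = []
    for stop in ends:
        trunc = RunRecord(
            lambdas=record.lambdas, temperature=record.temperature,
            u_kn=record.u_kn[:stop], state_history=record.state_history[:stop],
            dudl=record.dudl[:stop],
            observables={k: v[:stop] for k, v in record.observables.items()},
            sampling_interval=record.sampling_interval, seed=record.seed)
        try:
            matrix = decorrelate(trunc, burn_in=burn_in)
        except ValueError:
            # stride from g leaves too few samples at this truncation; cap
            # it so every time point still yields an estimate (its error
            # bar is then optimistic, which the drifting series exposes)
            n_kept = stop - int(math.floor(burn_in * stop))
            need = max(1, -(-5 * record.n_states // record.n_replicas))
            cap = max(1, n_kept // need)
            try:
                matrix = decorrelate(trunc, burn_in=burn_in, stride=cap)
            except ValueError:
                continue
        res = bootstrap_delta_g(matrix, n_bootstrap=n_bootstrap, seed=seed)
        out.append((float(stop * record.sampling_interval), res.delta_g, res.sigma))
    if len(out) < 3:
        raise ValueError("record too short for a free energy time series")
    return out
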