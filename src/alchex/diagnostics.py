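"""Sampling-problem identification workflow.

Given a replica-exchange record and its free energy time series, these
diagnostics answer, in order: (1) has the free energy converged
(trailing-window slope test)?  (2) are replicas mixing through all
alchemical states (occupancy, transition matrix, round trips)?  (3) which
conformational degree of freedom is implicated in slow convergence
(Pearson correlation of each monitored degree of freedom with
dU/dlambda)?  (4) is the problem conformational at all
(restrained-vs-unrestrained comparison)?  Forward/reverse internal
consistency provides an orthogonal accuracy check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimation import FreeEnergyResult, statistical_inefficiency
from .hybrid import HybridSystem
from .sampling import RunRecord, compute_observables

DOF_CATEGORIES = ("backbone_torsion", "sidechain_torsion", "intra_contact",
                  "inter_contact", "neighbor_waters")


@dataclass
class ConvergenceVerdict:
    slope: float          # kcal/mol per time unit
    slope_2sd: float      # 2 * OLS standard error
    window: tuple         # (t_start, t_end)
    converged: bool
    threshold: float = 0.1
    n_points: int = 0


def convergence_slope_test(series, window: float | None = None,
                           threshold: float = 0.1) -> ConvergenceVerdict:
    """OLS slope of the trailing window of a free energy time series.

    series: [(t, dg, sigma), ...].  Converged if |slope| <= threshold or
    if 0 lies within slope +/- 2*SE — i.e. the trailing stretch is flat
    with a close-to-zero slope (0 +/- threshold kcal/mol per time unit).
    """
    arr = np.asarray([(p[0], p[1]) for p in series], dtype=float)
    if arr.shape[0] < 3:
        raise ValueError("need at least 3 time points")
    t_end = arr[-1, 0]
    if window is None:
        window = (t_end - arr[0, 0]) / 2.0
    if window > t_end - arr[0, 0] + 1e-12:
        raise ValueError("window longer than the series span")
    mask = arr[:, 0] >= t_end - window - 1e-12
    pts = arr[mask]
    if pts.shape[0] < 3:
        raise ValueError("fewer than 3 points in the trailing window")
    if np.allclose(pts[:, 1], pts[0, 1]):
        return ConvergenceVerdict(0.0, 0.0, (float(pts[0, 0]), float(t_end)),
                                  True, threshold, pts.shape[0])
    res = stats.linregress(pts[:, 0], pts[:, 1])
    slope, se = float(res.slope), float(res.stderr)
    converged = abs(slope) <= threshold or (slope - 2 * se) <= 0.0 <= (slope + 2 * se)
    return ConvergenceVerdict(slope, 2 * se, (float(pts[0, 0]), float(t_end)),
                              bool(converged), threshold, pts.shape[0])


# ---------------------------------------------------------------------------
# replica mixing
# ---------------------------------------------------------------------------

@dataclass
class MixingReport:
    occupancy: np.ndarray           # (R, K) fraction of time replica in state
    transition_matrix: np.ndarray   # (K, K) pooled empirical row-stochastic
    subdominant_eigenvalue: float
    round_trips: np.ndarray         # per replica, 0 -> K-1 -> 0 excursions
    states_visited: np.ndarray      # per replica
    bottleneck: bool
    eigen_threshold: float


def replica_mixing_report(record: RunRecord,
                          eigen_threshold: float = 0.995) -> MixingReport:
    """Occupancy histograms, pooled state-transition matrix with its
    subdominant eigenvalue, round-trip counts, and a bottleneck flag (any
    replica visiting fewer than K states, or a subdominant eigenvalue
    above the threshold)."""
    hist = record.state_history
    if hist.size == 0:
        raise ValueError("empty state history")
    T, R = hist.shape
    K = record.n_states
    occupancy = np.stack([np.bincount(hist[:, r], minlength=K) / T for r in range(R)])
    counts = np.zeros((K, K))
    for r in range(R):
        np.add.at(counts, (hist[:-1, r], hist[1:, r]), 1.0)
    rowsum = counts.sum(axis=1, keepdims=True)
    P = np.divide(counts, rowsum, out=np.full_like(counts, 1.0 / K), where=rowsum > 0)
    if K == 1:
        sub = 0.0
    else:
        eig = np.sort(np.abs(np.linalg.eigvals(P)))[::-1]
        sub = float(eig[1])
    round_trips = np.zeros(R, dtype=int)
    for r in range(R):
        phase = 0  # 0: waiting for state 0; 1: climbing to K-1; 2: returning
        for s in hist[:, r]:
            if phase == 0 and s == 0:
                phase = 1
            elif phase == 1 and s == K - 1:
                phase = 2
            elif phase == 2 and s == 0:
                round_trips[r] += 1
                phase = 1
    visited = (occupancy > 0).sum(axis=1)
    bottleneck = bool(np.any(visited < K) or (K > 1 and sub > eigen_threshold))
    return MixingReport(occupancy=occupancy, transition_matrix=P,
                        subdominant_eigenvalue=sub, round_trips=round_trips,
                        states_visited=visited, bottleneck=bottleneck,
                        eigen_threshold=eigen_threshold)


# ---------------------------------------------------------------------------
# degree-of-freedom catalog and correlation with dU/dlambda
# ---------------------------------------------------------------------------

def dof_catalog(record: RunRecord, hybrid: HybridSystem, specs: list) -> dict:
    """Evaluate registered degree-of-freedom observables per replica.

    Each spec is {"name", "kind", "category", ...} with kinds as in
    :func:`alchex.sampling.compute_observables` (torsion angles in
    degrees, pair distances in nm, neighbor counts within a radius).
    Series already recorded during the run are reused; anything else
    requires stored positions.  Returns {"series": name -> (T, R),
    "category": name -> category}.
    """
    series, category = {}, {}
    todo = []
    for spec in specs:
        cat = spec.get("category", "intra_contact")
        if cat not in DOF_CATEGORIES:
            raise ValueError(f"unknown category {cat!r} for observable {spec['name']!r}")
        category[spec["name"]] = cat
        if spec["name"] in record.observables:
            series[spec["name"]] = record.observables[spec["name"]]
        else:
            todo.append(spec)
    if todo:
        if record.positions is None:
            missing = [s["name"] for s in todo]
            raise ValueError(f"observables {missing} not recorded and no stored "
                             "positions to compute them from")
        T, R = record.positions.shape[:2]
        flat = record.positions.reshape(T * R, hybrid.n_atoms, 3)
        for name, vals in compute_observables(hybrid, flat, todo).items():
            series[name] = vals.reshape(T, R)
    return {"series": series, "category": category}


@dataclass
class CorrelationTable:
    table: pd.DataFrame       # rows: dof; cols: category, pcc, ci_lo, ci_hi
    per_replica: pd.DataFrame
    dudl_g: float             # statistical inefficiency of dU/dl, time units


def dudl_dof_correlation(record: RunRecord, catalog: dict,
                         n_bootstrap: int = 1000, seed: int = 0) -> CorrelationTable:
    """Pearson correlation of dU/dlambda with each degree of freedom.

    The PCC is computed per replica (frames with undefined geometry
    excluded) and averaged over replicas; the 95% CI comes from
    bootstrapping over replicas.  Zero-variance observables are flagged
    with NaN."""
    rng = np.random.default_rng(seed)
    R = record.n_replicas
    rows, per_rep = [], []
    g = max(statistical_inefficiency(record.dudl[:, r],
                                     record.sampling_interval).g_time
            for r in range(R))
    for name, obs in catalog["series"].items():
        pccs = np.full(R, np.nan)
        for r in range(R):
            y = obs[:, r]
            m = np.isfinite(y)
            if m.sum() >= 3 and np.std(y[m]) > 0 and np.std(record.dudl[m, r]) > 0:
                pccs[r] = stats.pearsonr(record.dudl[m, r], y[m])[0]
        valid = pccs[np.isfinite(pccs)]
        if valid.size == 0:
            rows.append((name, catalog["category"][name], np.nan, np.nan, np.nan, True))
            continue
        boot = np.array([valid[rng.integers(0, valid.size, valid.size)].mean()
                         for _ in range(n_bootstrap)])
        rows.append((name, catalog["category"][name], float(valid.mean()),
                     float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)),
                     False))
        per_rep.extend((name, r, float(pccs[r])) for r in range(R))
    table = pd.DataFrame(rows, columns=["dof", "category", "pcc", "ci_lo",
                                        "ci_hi", "degenerate"]).set_index("dof")
    per_replica = pd.DataFrame(per_rep, columns=["dof", "replica", "pcc"])
    return CorrelationTable(table=table, per_replica=per_replica, dudl_g=float(g))


def correlation_summary(tables) -> pd.DataFrame:
    """Per-category max-|PCC| summary, one row per mutation/table, ordered
    from highest to lowest dU/dlambda statistical inefficiency (the
    machine-readable analog of a correlation heatmap)."""
    if isinstance(tables, CorrelationTable):
        tables = {"run": tables}
    if not tables:
        raise ValueError("no correlation tables given")
    rows = []
    for label, ct in tables.items():
        row = {"mutation": label, "dudl_g": ct.dudl_g}
        for cat in DOF_CATEGORIES:
            sub = ct.table[(ct.table["category"] == cat) & (~ct.table["degenerate"])]
            if sub.empty:
                continue
            best = sub["pcc"].abs().idxmax()
            row[cat] = float(abs(sub.loc[best, "pcc"]))
            row[f"{cat}_dof"] = best
            row[f"{cat}_pcc_signed"] = float(sub.loc[best, "pcc"])
            row[f"{cat}_ci"] = (float(sub.loc[best, "ci_lo"]), float(sub.loc[best, "ci_hi"]))
        rows.append(row)
    df = pd.DataFrame(rows).set_index("mutation")
    return df.sort_values("dudl_g", ascending=False)


# ---------------------------------------------------------------------------
# internal consistency and the restrained diagnosis
# ---------------------------------------------------------------------------

def _within(point: float, ci: tuple, slack: float) -> bool:
    lo, hi = min(ci), max(ci)
    return lo - slack <= point <= hi + slack


@dataclass
class ConsistencyReport:
    discrepancy: float       # DDG_fwd - (-DDG_rev), kcal/mol
    consistent: bool
    forward: FreeEnergyResult
    reverse: FreeEnergyResult


def internal_consistency(forward: FreeEnergyResult,
                         reverse: FreeEnergyResult,
                         slack: float = 1.0) -> ConsistencyReport:
    """Forward/reverse agreement check: the pair is inconsistent only if
    neither the forward value is within ``slack`` kcal/mol of the negated
    reverse 95% CI, nor the negated reverse value within ``slack`` of the
    forward 95% CI."""
    neg_rev = -reverse.delta_g
    neg_rev_ci = (-reverse.ci95[1], -reverse.ci95[0])
    ok_fwd = _within(forward.delta_g, neg_rev_ci, slack)
    ok_rev = _within(neg_rev, forward.ci95, slack)
    return ConsistencyReport(
        discrepancy=float(forward.delta_g - neg_rev),
        consistent=bool(ok_fwd or ok_rev),
        forward=forward, reverse=reverse)


def consistency_metrics(discrepancies, n_bootstrap: int = 1000,
                        seed: int = 0) -> dict:
    """RMSE and MUE of a set of forward-vs-negated-reverse discrepancies,
    with bootstrap 95% CIs."""
    d = np.asarray(discrepancies, dtype=float)
    if d.size == 0:
        raise ValueError("empty discrepancy set")
    rng = np.random.default_rng(seed)
    rmse = float(np.sqrt(np.mean(d ** 2)))
    mue = float(np.mean(np.abs(d)))
    boots = np.array([[np.sqrt(np.mean(s ** 2)), np.mean(np.abs(s))]
                      for s in (d[rng.integers(0, d.size, d.size)]
                                for _ in range(n_bootstrap))])
    return {
        "rmse": rmse, "rmse_ci95": (float(np.percentile(boots[:, 0], 2.5)),
                                    float(np.percentile(boots[:, 0], 97.5))),
        "mue": mue, "mue_ci95": (float(np.percentile(boots[:, 1], 2.5)),
                                 float(np.percentile(boots[:, 1], 97.5))),
        "n": int(d.size),
    }


def restrained_comparison(unrestrained_series, restrained_series,
                          window: float | None = None,
                          threshold: float = 0.1) -> dict:
    """Diagnose whether slow convergence is conformational: if heavy-atom
    restraints make the free energy time series converge while the
    unrestrained series does not, a conformational-sampling problem is
    implicated; if both fail, the problem is not solely conformational."""
    v_un = convergence_slope_test(unrestrained_series, window, threshold)
    v_re = convergence_slope_test(restrained_series, window, threshold)
    if v_re.converged and not v_un.converged:
        verdict = "conformational-sampling problem"
    elif not v_re.converged and not v_un.converged:
        verdict = "not solely conformational"
    else:
        verdict = "no detected problem"
    return {"verdict": verdict, "unrestrained": v_un, "restrained": v_re}
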