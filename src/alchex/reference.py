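"""Independent brute-force oracles.

Nothing here shares code with the estimators it is meant to check:
free energies come from direct numerical quadrature of configurational
integrals, exact enumeration of small discrete replica-exchange models,
or long high-budget reference simulations.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad
from scipy.optimize import brentq

from .constants import kT
from .systems import ParticleSystem, ToyMutationPair


@dataclass
class OracleResult:
    value: float
    method: str                       # quadrature | enumeration | long_reference
    tolerance: float
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")


# ---------------------------------------------------------------------------
# quadrature of separable toy partition functions
# ---------------------------------------------------------------------------

def _axis_restraint_k(system: ParticleSystem, i: int) -> np.ndarray:
    k = np.zeros(3)
    for (j, ks, _c) in system.restraints:
        if int(j) == i:
            k += np.broadcast_to(np.asarray(ks, dtype=float), (3,))
    return k


def _log_z_onsite(system: ParticleSystem, i: int, beta: float,
                  points: int) -> float:
    """log configurational integral of one particle governed solely by
    on-site terms (per-axis restraints and wells); separable per axis."""
    kvec = _axis_restraint_k(system, i)
    wells = [w for w in system.wells if int(w[0]) == i]
    log_z = 0.0
    for axis in range(3):
        k = kvec[axis]
        well = next((w for w in wells if int(w[1]) == axis), None)
        if well is None:
            if k <= 0:
                raise ValueError(
                    f"particle {i} axis {axis} is unbound; integral diverges")
            # numerical 1-D quadrature of the Gaussian integral (the
            # closed form is precisely what this oracle verifies)
            width = math.sqrt(1.0 / (beta * k))
            z, _err = quad(lambda x: math.exp(-0.5 * beta * k * x * x),
                           -10 * width, 10 * width, limit=points)
            log_z += math.log(z)
            continue
        _, _, barrier, a, tilt, center = well

        def u(x):
            v = (x - center) / a
            e = barrier * (v * v - 1.0) ** 2 + tilt * (x - center) / (2 * a)
            e += 0.5 * k * x * x  # restraint center along a well axis is 0 by fixture convention
            return e

        lo, hi = center - 8 * a, center + 8 * a
        z, _err = quad(lambda x: math.exp(-beta * u(x)), lo, hi, limit=points)
        log_z += math.log(z)
    return log_z


def _pair_radial_log_z(sigma: float, eps: float, q1q2: float, coulomb: float,
                       k_c: float, beta: float, r_max: float = 4.0) -> float:
    """log of the radial configurational integral of one mobile particle
    interacting with a fixed particle at the origin plus a central
    harmonic anchor: int 4 pi r^2 exp(-beta U(r)) dr."""

    def u(r):
        x6 = (sigma / r) ** 6
        e = 4.0 * eps * x6 * (x6 - 1.0)
        if q1q2 != 0.0:
            e += coulomb * q1q2 / r
        return e + 0.5 * k_c * r * r

    z, _err = quad(lambda r: 4.0 * math.pi * r * r * math.exp(-beta * min(u(r), 500.0)),
                   1e-6, r_max, limit=400)
    return math.log(z)


def quadrature_delta_g(pair: ToyMutationPair, temperature: float,
                       points: int = 400) -> OracleResult:
    """Free energy change old -> new by direct numerical integration.

    Supported fixtures (separable configurational integrals): the
    harmonic ladder and the double-well fixture (per-particle on-site
    terms only), and the two-particle LJ mutation (radial integral with a
    frozen partner).  Tolerance is taken from a grid-refinement /
    quadrature error budget.
    """
    beta = 1.0 / kT(temperature)
    kind = pair.meta.get("kind")
    old, new = pair.old_system, pair.new_system
    if kind in ("harmonic_ladder", "double_well"):
        # strictly on-site fixtures: charges and epsilons must vanish
        if np.any(old.charges != 0) or np.any(old.lj_epsilon != 0) \
                or np.any(new.charges != 0) or np.any(new.lj_epsilon != 0):
            raise ValueError("fixture has nonbonded couplings; not separable")
        log_z_old = sum(_log_z_onsite(old, i, beta, points)
                        for i in range(old.n_particles))
        log_z_new = sum(_log_z_onsite(new, i, beta, points)
                        for i in range(new.n_particles))
        dg = -(log_z_new - log_z_old) / beta
        return OracleResult(value=float(dg), method="quadrature", tolerance=1e-8,
                            provenance={"kind": kind, "temperature": temperature})
    if kind == "lj_mutation" and old.n_particles == 2 and "frozen" in old.tags[1]:
        from .constants import COULOMB_KCAL_NM
        k_c = float(np.broadcast_to(np.asarray(old.restraints[0][1]), (3,))[0])

        def logz(sys_):
            sig = 0.5 * (sys_.lj_sigma[0] + sys_.lj_sigma[1])
            eps = math.sqrt(sys_.lj_epsilon[0] * sys_.lj_epsilon[1])
            return _pair_radial_log_z(sig, eps, sys_.charges[0] * sys_.charges[1],
                                      COULOMB_KCAL_NM, k_c, beta)

        dg = -(logz(new) - logz(old)) / beta
        return OracleResult(value=float(dg), method="quadrature", tolerance=1e-6,
                            provenance={"kind": kind, "temperature": temperature})
    raise ValueError(f"fixture kind {kind!r} is not separable; "
                     "use long_reference_delta_g")


# ---------------------------------------------------------------------------
# plain-system energy (independent of the alchemical evaluator)
# ---------------------------------------------------------------------------

def valence_term_energy(kind: str, params: tuple, coords: np.ndarray) -> float:
    """Energy of one valence-class term given the coordinates of its atoms."""
    if kind == "bond":
        k, r0 = params
        return 0.5 * k * (np.linalg.norm(coords[1] - coords[0]) - r0) ** 2
    if kind == "angle":
        k, t0 = params
        u = coords[0] - coords[1]
        v = coords[2] - coords[1]
        cos = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return 0.5 * k * (math.acos(max(-1.0, min(1.0, cos))) - t0) ** 2
    if kind == "torsion":
        bar, per, ph = params
        b1, b2, b3 = coords[1] - coords[0], coords[2] - coords[1], coords[3] - coords[2]
        n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
        m1 = np.cross(n1, b2 / np.linalg.norm(b2))
        phi = math.atan2(np.dot(m1, n2), np.dot(n1, n2))
        return bar * (1.0 + math.cos(per * phi - ph))
    if kind == "restraint":
        kvec, center = params
        d = coords[0] - np.asarray(center)
        return 0.5 * float(np.dot(np.asarray(kvec), d * d))
    if kind == "well":
        bar, a, tilt, center = params
        u = coords[0][0] if coords.ndim > 1 else coords[0]
        v = (u - center) / a
        return bar * (v * v - 1.0) ** 2 + tilt * (u - center) / (2 * a)
    raise ValueError(f"unknown term kind {kind!r}")


def system_energy(system: ParticleSystem, x: np.ndarray,
                  coulomb: float | None = None) -> float:
    """Total energy of a plain (non-alchemical) system: full Coulomb + LJ
    over all pairs plus every valence-class term.  Deliberately written as
    straightforward double loops, independent of the hybrid evaluator."""
    from .constants import COULOMB_KCAL_NM
    if coulomb is None:
        coulomb = COULOMB_KCAL_NM
    x = np.asarray(x, dtype=float).reshape(system.n_particles, 3)
    e = 0.0
    for i in range(system.n_particles):
        for j in range(i + 1, system.n_particles):
            r = float(np.linalg.norm(x[j] - x[i]))
            qq = system.charges[i] * system.charges[j]
            if qq != 0.0:
                e += coulomb * qq / r
            eps = math.sqrt(system.lj_epsilon[i] * system.lj_epsilon[j])
            if eps > 0.0:
                sig = 0.5 * (system.lj_sigma[i] + system.lj_sigma[j])
                x6 = (sig / r) ** 6
                e += 4.0 * eps * x6 * (x6 - 1.0)
    for (i, j, k, r0) in system.bonds:
        e += valence_term_energy("bond", (k, r0), x[[int(i), int(j)]])
    for (i, j, k, ka, t0) in system.angles:
        e += valence_term_energy("angle", (ka, t0), x[[int(i), int(j), int(k)]])
    for (i, j, k, l, bar, per, ph) in system.torsions:
        e += valence_term_energy("torsion", (bar, per, ph),
                                 x[[int(i), int(j), int(k), int(l)]])
    for (i, ks, center) in system.restraints:
        kvec = np.broadcast_to(np.asarray(ks, dtype=float), (3,))
        e += valence_term_energy("restraint", (kvec, center), x[[int(i)]])
    for (i, axis, bar, a, tilt, center) in system.wells:
        e += valence_term_energy("well", (bar, a, tilt, center),
                                 np.array([[x[int(i), int(axis)], 0.0, 0.0]]))
    return float(e)


# ---------------------------------------------------------------------------
# exact enumeration of small discrete replica-exchange models
# ---------------------------------------------------------------------------

@dataclass
class DiscreteModel:
    """K states x M configurations with a reduced-energy table u[k][c]."""
    u: np.ndarray   # (K, M), kT units

    @property
    def K(self) -> int:
        return self.u.shape[0]

    @property
    def M(self) -> int:
        return self.u.shape[1]

    def conditional(self, state: int) -> np.ndarray:
        w = np.exp(-self.u[state] + self.u[state].min())
        return w / w.sum()


def enumerate_joint_density(model: DiscreteModel) -> dict:
    """Exact joint distribution P(X, S) = prod_k p(x_k | s_k) over replica
    configuration assignments X and permutations S."""
    K, M = model.K, model.M
    if M ** K * math.factorial(K) > 10 ** 4:
        raise ValueError("joint state space too large to enumerate")
    cond = np.stack([model.conditional(k) for k in range(K)])  # (K, M)
    out = {}
    total = 0.0
    for perm in itertools.permutations(range(K)):
        for confs in itertools.product(range(M), repeat=K):
            p = 1.0
            for replica in range(K):
                p *= cond[perm[replica], confs[replica]]
            out[(confs, perm)] = p
            total += p
    return {key: val / total for key, val in out.items()}


def gibbs_sample_discrete(model: DiscreteModel, n_sweeps: int, seed: int,
                          swap_attempts: int | None = None):
    """Discrete analog of the AREX Gibbs loop using the production swap
    kernel: exact conditional resampling of configurations, then the
    Metropolis pair-swap sweep on the state permutation."""
    from .sampling import default_swap_attempts, metropolis_swap_sweep
    K, M = model.K, model.M
    if swap_attempts is None:
        swap_attempts = default_swap_attempts(K)
    rng = np.random.default_rng(seed)
    perm = np.arange(K)
    confs = np.zeros(K, dtype=int)
    counts = {}
    cond = np.stack([model.conditional(k) for k in range(K)])
    cum = np.cumsum(cond, axis=1)
    for _ in range(n_sweeps):
        draws = rng.random(K)
        for replica in range(K):
            confs[replica] = np.searchsorted(cum[perm[replica]], draws[replica])
        u_matrix = model.u[:, confs]  # u[k, replica]
        perm = metropolis_swap_sweep(perm, u_matrix, swap_attempts, rng)
        key = (tuple(int(c) for c in confs), tuple(int(s) for s in perm))
        counts[key] = counts.get(key, 0) + 1
    return {k: v / n_sweeps for k, v in counts.items()}


def total_variation(p: dict, q: dict) -> float:
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


# ---------------------------------------------------------------------------
# high-budget reference simulation
# ---------------------------------------------------------------------------

def long_reference_delta_g(pair: ToyMutationPair, budget: int, seed: int,
                           K: int = 12, steps_per_iteration: int = 25,
                           temperature: float | None = None) -> OracleResult:
    """Reference AREX estimate at a budget much larger than the standard
    test budget; flagged unconverged if the trailing slope test fails."""
    from .diagnostics import convergence_slope_test
    from .estimation import bootstrap_delta_g, decorrelate, dg_time_series
    from .hybrid import build_hybrid
    from .potential import AlchemicalParams, LambdaProtocol
    from .sampling import run_arex

    temperature = temperature or pair.meta.get("temperature", 300.0)
    hybrid = build_hybrid(pair)
    record = run_arex(hybrid, LambdaProtocol.linear(K), AlchemicalParams(),
                      n_iterations=budget, steps_per_iteration=steps_per_iteration,
                      temperature=temperature, seed=seed)
    series = dg_time_series(record, n_points=8, n_bootstrap=30, seed=seed)
    verdict = convergence_slope_test(series)
    result = bootstrap_delta_g(decorrelate(record), n_bootstrap=100, seed=seed)
    return OracleResult(
        value=result.delta_g, method="long_reference",
        tolerance=max(2.0 * result.sigma, 1e-6),
        provenance={"budget": budget, "seed": seed, "K": K,
                    "converged": verdict.converged, "sigma": result.sigma})


# ---------------------------------------------------------------------------
# BAR: independent two-state estimator used to cross-check MBAR
# ---------------------------------------------------------------------------

def bar_solve(w_forward: np.ndarray, w_reverse: np.ndarray,
              tol: float = 1e-12) -> float:
    """Bennett acceptance ratio free energy difference (kT units) from
    forward work values u_1(x)-u_0(x) on state-0 samples and reverse work
    u_0(x)-u_1(x) on state-1 samples.  Solved as a root of the implicit
    BAR equation."""
    wf = np.asarray(w_forward, dtype=float)
    wr = np.asarray(w_reverse, dtype=float)
    n_f, n_r = wf.size, wr.size
    M = math.log(n_f / n_r)

    def fermi(x):
        return 1.0 / (1.0 + np.exp(x))

    def residual(df):
        return (np.log(fermi(M + wf - df).sum()) -
                np.log(fermi(-M + wr + df).sum()))

    lo, hi = -500.0, 500.0
    return float(brentq(residual, lo, hi, xtol=tol))
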