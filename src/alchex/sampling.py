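"""Replica propagation and alchemical replica exchange.

AREX is a Gibbs sampler: each iteration first updates all replica
positions with Langevin dynamics at their current alchemical states, then
updates the replica -> state permutation by attempting many Metropolis
swaps of pairs of state labels, which approximates drawing an
independent permutation.  AREST is the identical loop with the
REST-scaled potential; the thermostat always runs at T0 — solute
tempering enters only through the scaled Hamiltonian.

Integrator: BAOAB-splitting Langevin.  With kcal/mol, nm, amu and ps,
the force conversion is 1 kcal/mol = 4.184 amu nm^2/ps^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np

from .constants import BOLTZMANN_KCAL, KCAL_TO_MD
from .hybrid import HybridSystem, HybridTerm
from .potential import AlchemicalParams, HybridEvaluator, LambdaProtocol, RESTParams

# nominal time label per recorded iteration, in "ns", mirroring the
# convention of reporting statistical inefficiencies in time units with a
# 0.1 ns sampling interval
NOMINAL_INTERVAL_NS = 0.1


@dataclass
class ReplicaEnsemble:
    """Positions, velocities and the replica -> state permutation."""
    positions: np.ndarray      # (R, n, 3)
    velocities: np.ndarray     # (R, n, 3)
    permutation: np.ndarray    # (R,) state index of each replica
    iteration: int = 0

    def __post_init__(self):
        K = self.permutation.shape[0]
        if sorted(self.permutation.tolist()) != list(range(K)):
            raise ValueError("permutation must be a bijection replica -> state")


@dataclass
class RunRecord:
    """Per-iteration record of a replica-exchange run.

    u_kn : (n_iter, K, R) reduced potential of every replica's sample at
        every alchemical state, kT units.
    state_history : (n_iter, R) state at which each replica's sample was
        generated.
    dudl : (n_iter, R) dU/dlambda of each replica at its state, kcal/mol.
    observables : name -> (n_iter, R) series.
    """
    lambdas: tuple
    temperature: float
    u_kn: np.ndarray
    state_history: np.ndarray
    dudl: np.ndarray
    observables: dict = field(default_factory=dict)
    positions: np.ndarray | None = None
    sampling_interval: float = NOMINAL_INTERVAL_NS
    seed: int | None = None
    meta: dict = field(default_factory=dict)
    error: str | None = None

    @property
    def n_iterations(self) -> int:
        return self.u_kn.shape[0]

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[1]

    @property
    def n_replicas(self) -> int:
        return self.u_kn.shape[2]


# ---------------------------------------------------------------------------
# Langevin dynamics
# ---------------------------------------------------------------------------

def choose_timestep(hybrid: HybridSystem, safety: float = 0.25,
                    dt_max: float = 0.1) -> float:
    """Stability pre-check: bound the stiffest angular frequency from the
    force-constant tables (restraints, bonds, well curvature, LJ curvature
    at the minimum) and take dt = safety * 2/omega_max, capped."""
    k_max = 1.0  # kcal/mol/nm^2 floor
    for t in hybrid.terms:
        for p in (t.params_old, t.params_new):
            if p is None:
                continue
            if t.kind == "bond":
                k_max = max(k_max, p[0])
            elif t.kind == "restraint":
                k_max = max(k_max, max(p[0]))
            elif t.kind == "well":
                k_max = max(k_max, 8.0 * p[0] / p[1] ** 2)
    eps = max(hybrid.eps_old.max(initial=0.0), hybrid.eps_new.max(initial=0.0))
    sig = min(hybrid.sigma_old.min(initial=0.3), hybrid.sigma_new.min(initial=0.3))
    if eps > 0:
        k_max = max(k_max, 57.15 * eps / sig ** 2)
    m_min = hybrid.masses[~hybrid.frozen].min() if (~hybrid.frozen).any() else 1.0
    omega = np.sqrt(k_max * KCAL_TO_MD / m_min)  # 1/ps
    return float(min(dt_max, safety * 2.0 / omega))


def maxwell_velocities(hybrid: HybridSystem, temperature: float, shape,
                       rng: np.random.Generator) -> np.ndarray:
    kT_md = BOLTZMANN_KCAL * temperature * KCAL_TO_MD
    v = rng.normal(0.0, 1.0, size=shape) * np.sqrt(kT_md / hybrid.masses)[:, None]
    v[..., hybrid.frozen, :] = 0.0
    return v


def langevin_propagate(evaluator: HybridEvaluator, x: np.ndarray, lam,
                       n_steps: int, dt: float, friction: float,
                       temperature: float, rng: np.random.Generator,
                       velocities: np.ndarray | None = None,
                       return_velocities: bool = False):
    """BAOAB Langevin update toward the Boltzmann distribution of the
    state's (possibly REST-scaled) potential at temperature T0.

    x may be (n, 3) or a replica batch (R, n, 3) with per-replica lam.
    """
    h = evaluator.hybrid
    x = np.array(x, dtype=float)
    scalar = x.ndim == 2
    if scalar:
        x = x[None]
    lam = np.broadcast_to(np.asarray(lam, dtype=float), x.shape[:1]).copy()
    masses = h.masses[:, None]
    mobile = ~h.frozen
    kT_md = BOLTZMANN_KCAL * temperature * KCAL_TO_MD
    c1 = np.exp(-friction * dt)
    c2 = np.sqrt(1.0 - c1 * c1)
    sigma_v = np.sqrt(kT_md / h.masses)[:, None]
    if velocities is None:
        v = rng.normal(0.0, 1.0, size=x.shape) * sigma_v
    else:
        v = np.array(velocities, dtype=float)
        if v.ndim == 2:
            v = v[None]
    v[:, h.frozen, :] = 0.0

    def accel(pos):
        f = evaluator.forces(pos, lam) * KCAL_TO_MD  # amu nm/ps^2
        if not np.all(np.isfinite(f)):
            raise FloatingPointError(
                "non-finite force during propagation; configuration dump: "
                f"{np.array2string(pos[~np.isfinite(f).all(axis=-1)][:5])}")
        f[:, h.frozen, :] = 0.0
        return f / masses

    a = accel(x)
    half = 0.5 * dt
    for _ in range(n_steps):
        v += half * a
        x[:, mobile] += half * v[:, mobile]
        # O-step: at T = 0 the noise term vanishes but friction still damps
        noise = rng.normal(0.0, 1.0, size=v.shape)
        v = c1 * v + c2 * sigma_v * noise
        v[:, h.frozen, :] = 0.0
        x[:, mobile] += half * v[:, mobile]
        a = accel(x)
        v += half * a
    if scalar:
        x, v = x[0], v[0]
    return (x, v) if return_velocities else x


# ---------------------------------------------------------------------------
# state-permutation update
# ---------------------------------------------------------------------------

def metropolis_swap_sweep(permutation: np.ndarray, u_matrix: np.ndarray,
                          n_attempts: int, rng: np.random.Generator) -> np.ndarray:
    """Attempt ``n_attempts`` random pairwise swaps of state labels.

    u_matrix[k, r] is the reduced potential of replica r's sample at state
    k.  A swap of the states of replicas (a, b) currently at (i, j) is
    accepted with min(1, exp(-Delta)),
    Delta = [u(i, b) + u(j, a)] - [u(i, a) + u(j, b)].
    Many cheap attempts approximate an independent draw of the permutation.
    """
    perm = np.array(permutation, dtype=int)
    K = perm.shape[0]
    if K < 2 or n_attempts < 1:
        return perm
    a_all = rng.integers(0, K, size=n_attempts)
    off = rng.integers(1, K, size=n_attempts)
    b_all = (a_all + off) % K
    logu = np.log(rng.random(size=n_attempts))
    for a, b, lu in zip(a_all, b_all, logu):
        i, j = perm[a], perm[b]
        delta = (u_matrix[i, b] + u_matrix[j, a]) - (u_matrix[i, a] + u_matrix[j, b])
        if lu < -delta:
            perm[a], perm[b] = j, i
    return perm


def default_swap_attempts(K: int) -> int:
    return K ** 3


# ---------------------------------------------------------------------------
# observables
# ---------------------------------------------------------------------------

def default_observables(hybrid: HybridSystem) -> list:
    obs = []
    slow = hybrid.tagged("slow_dof")
    if slow:
        obs.append({"name": "slow_dof", "kind": "coordinate",
                    "particle": slow[0], "axis": 0})
    return obs


def compute_observables(hybrid: HybridSystem, x: np.ndarray, specs: list) -> dict:
    """Evaluate observable specs on a replica batch x (R, n, 3).

    kinds: coordinate (particle, axis), distance (i, j), torsion
    (quadruple), neighbor_count (around tagged/mutating particles within
    radius, counting untagged particles).
    """
    out = {}
    for spec in specs:
        kind = spec["kind"]
        if kind == "coordinate":
            out[spec["name"]] = x[:, spec["particle"], spec["axis"]].copy()
        elif kind == "distance":
            d = x[:, spec["j"]] - x[:, spec["i"]]
            out[spec["name"]] = np.linalg.norm(d, axis=-1)
        elif kind == "torsion":
            i, j, k, l = spec["quadruple"]
            b1 = x[:, j] - x[:, i]
            b2 = x[:, k] - x[:, j]
            b3 = x[:, l] - x[:, k]
            n1 = np.cross(b1, b2)
            n2 = np.cross(b2, b3)
            nb2 = np.linalg.norm(b2, axis=-1)
            m1 = np.cross(n1, b2 / np.maximum(nb2, 1e-12)[:, None])
            phi = np.degrees(np.arctan2((m1 * n2).sum(-1), (n1 * n2).sum(-1)))
            degen = (np.linalg.norm(n1, axis=-1) < 1e-8) | (np.linalg.norm(n2, axis=-1) < 1e-8)
            out[spec["name"]] = np.where(degen, np.nan, phi)
        elif kind == "neighbor_count":
            centers = spec.get("particles") or hybrid.tagged("mutating")
            radius = spec.get("radius", 0.5)
            others = [i for i in range(hybrid.n_atoms) if i not in centers]
            if not centers or not others or radius <= 0:
                out[spec["name"]] = np.zeros(x.shape[0])
                continue
            d = np.linalg.norm(x[:, others, None, :] - x[:, None, centers, :]
                               .transpose(0, 2, 1, 3), axis=-1)
            out[spec["name"]] = (d.min(axis=-1) <= radius).sum(axis=-1).astype(float)
        else:
            raise ValueError(f"unknown observable kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# AREX / AREST driver
# ---------------------------------------------------------------------------

def run_arex(hybrid: HybridSystem, protocol: LambdaProtocol,
             params: AlchemicalParams, n_iterations: int,
             steps_per_iteration: int, temperature: float, seed: int,
             rest: RESTParams | None = None,
             observables: list | None = None,
             dt: float | None = None, friction: float = 1.0,
             swap_attempts: int | None = None,
             store_positions: bool = False,
             x0: np.ndarray | None = None) -> RunRecord:
    """Alternate Langevin propagation (all replicas, each at its current
    state) with Metropolis swap sweeps; record the full reduced-potential
    matrix, state history, dU/dlambda and observables every iteration."""
    K = protocol.K
    ev = HybridEvaluator(hybrid, params, rest)
    rng = np.random.default_rng(seed)
    if dt is None:
        dt = choose_timestep(hybrid)
    if swap_attempts is None:
        swap_attempts = default_swap_attempts(K)
    if observables is None:
        observables = default_observables(hybrid)
    lam_states = np.asarray(protocol.lambdas)
    x = (np.repeat(hybrid.positions0[None], K, axis=0) if x0 is None
         else np.array(x0, dtype=float))
    v = maxwell_velocities(hybrid, temperature, x.shape, rng)
    perm = np.arange(K)

    u_kn = np.empty((n_iterations, K, K))
    state_history = np.empty((n_iterations, K), dtype=int)
    dudl = np.empty((n_iterations, K))
    obs_data = {spec["name"]: np.empty((n_iterations, K)) for spec in observables}
    pos_store = np.empty((n_iterations, K, hybrid.n_atoms, 3)) if store_positions else None
    h_fd = 1e-4
    error = None

    n_done = 0
    try:
        for it in range(n_iterations):
            lam_rep = lam_states[perm]
            x, v = langevin_propagate(ev, x, lam_rep, steps_per_iteration, dt,
                                      friction, temperature, rng,
                                      velocities=v, return_velocities=True)
            u = ev.u_matrix(x, lam_states, temperature)
            lo = np.clip(lam_rep - h_fd, 0.0, 1.0)
            hi = np.clip(lam_rep + h_fd, 0.0, 1.0)
            dudl_it = (ev.energy(x, hi) - ev.energy(x, lo)) / (hi - lo)
            u_kn[it] = u
            state_history[it] = perm
            dudl[it] = dudl_it
            for name, series in compute_observables(hybrid, x, observables).items():
                obs_data[name][it] = series
            if store_positions:
                pos_store[it] = x
            perm = metropolis_swap_sweep(perm, u, swap_attempts, rng)
            n_done = it + 1
    except FloatingPointError as exc:   # flush partial record with error flag
        error = str(exc)
        u_kn = u_kn[:n_done]
        state_history = state_history[:n_done]
        dudl = dudl[:n_done]
        obs_data = {k: a[:n_done] for k, a in obs_data.items()}
        if store_positions:
            pos_store = pos_store[:n_done]

    return RunRecord(
        lambdas=tuple(protocol.lambdas), temperature=temperature,
        u_kn=u_kn, state_history=state_history, dudl=dudl,
        observables=obs_data, positions=pos_store,
        sampling_interval=NOMINAL_INTERVAL_NS, seed=seed,
        meta={"method": "arest" if rest is not None else "arex",
              "dt": dt, "friction": friction,
              "steps_per_iteration": steps_per_iteration,
              "swap_attempts": swap_attempts,
              "rest": None if rest is None else
              {"T0": rest.T0, "Tmax": rest.Tmax,
               "inter_exponent": rest.inter_exponent}},
        error=error)


def run_arest(hybrid: HybridSystem, protocol: LambdaProtocol,
              params: AlchemicalParams, rest: RESTParams, *args, **kwargs) -> RunRecord:
    """AREX with a REST region: identical Gibbs loop over the REST-scaled
    potential.  Requires assign_rest_region to have been applied."""
    if hybrid.rest_membership is None:
        raise ValueError("hybrid has no REST region; call assign_rest_region first")
    return run_arex(hybrid, protocol, params, *args, rest=rest, **kwargs)


def add_positional_restraints(hybrid: HybridSystem, selection: str,
                              force_constant: float) -> HybridSystem:
    """Restrain selected particles to their reference positions.

    force_constant is given in kcal/mol/A^2 (the conventional unit for
    heavy-atom restraints) and converted to kcal/mol/nm^2 internally.  The
    restraint is identical at both endstates (non-alchemical) and classed
    nonrest so solute tempering never weakens it.
    """
    if force_constant < 0:
        raise ValueError("force_constant must be non-negative")
    atoms = hybrid.tagged(selection)
    if not atoms:
        warnings.warn(f"no particles tagged {selection!r}; restraints not added")
        return hybrid
    k_nm = force_constant * 100.0  # kcal/mol/A^2 -> kcal/mol/nm^2
    new_terms = list(hybrid.terms)
    for i in atoms:
        p = ((k_nm, k_nm, k_nm), tuple(float(c) for c in hybrid.positions0[i]))
        new_terms.append(HybridTerm(kind="restraint", atoms=(int(i),),
                                    params_old=p, params_new=p,
                                    rest_override="nonrest"))
    return dc_replace(hybrid, terms=new_terms)
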