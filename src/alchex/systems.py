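"""Toy particle systems and mutation-pair fixtures.

Every downstream stage (hybrid construction, alchemical potentials,
replica exchange, estimation, diagnostics) is exercised on the small
self-contained systems built here.  Fixtures are designed around known
answers: the harmonic ladder has a closed-form free energy change, the
two-particle Lennard-Jones mutation reduces to a 1-D radial integral, and
the double-well fixture plants a metastable "slow" coordinate whose
population shifts between endstates.

A system is a flat collection of particles with nonbonded parameters plus
four kinds of potential terms: bonds/angles/torsions between particles,
and two on-site term types — isotropic positional restraints (harmonic
anchors to fixed points in space) and 1-D quartic double wells with a
linear tilt.  On-site terms are what let a toy be anchored, separable and
analytically tractable without a surrounding molecule.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import quad

from .constants import kT

SCHEMA_VERSION = 1


@dataclass
class ParticleSystem:
    """A toy molecular system.

    positions : (n, 3) array, nm
    charges : (n,) array, elementary charge
    lj_sigma / lj_epsilon : (n,) arrays, nm and kcal/mol
    masses : (n,) array, amu
    bonds : list of (i, j, k_spring kcal/mol/nm^2, r0 nm)
    angles : list of (i, j, k, k_angle kcal/mol/rad^2, theta0 rad)
    torsions : list of (i, j, k, l, barrier kcal/mol, periodicity, phase rad)
    restraints : list of (i, k_spring, (cx, cy, cz) nm) where k_spring
            (kcal/mol/nm^2) is a scalar (isotropic) or a per-axis 3-tuple
    wells : list of (i, axis, barrier kcal/mol, half_width nm, tilt kcal/mol,
            center nm); energy barrier*((u/a)^2-1)^2 + tilt*u/(2a) with
            u = x[i, axis] - center and a = half_width
    tags : per-particle list of string labels ("mutating", "counter",
            "frozen", "slow_dof", "heavy", ...)
    """

    positions: np.ndarray
    charges: np.ndarray
    lj_sigma: np.ndarray
    lj_epsilon: np.ndarray
    masses: np.ndarray
    bonds: list = field(default_factory=list)
    angles: list = field(default_factory=list)
    torsions: list = field(default_factory=list)
    restraints: list = field(default_factory=list)
    wells: list = field(default_factory=list)
    tags: list = field(default_factory=list)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        n = self.positions.shape[0]
        for name in ("charges", "lj_sigma", "lj_epsilon", "masses"):
            arr = np.asarray(getattr(self, name), dtype=float).ravel()
            if arr.shape[0] != n:
                raise ValueError(f"{name} has length {arr.shape[0]}, expected {n}")
            setattr(self, name, arr)
        if not self.tags:
            self.tags = [[] for _ in range(n)]
        if len(self.tags) != n:
            raise ValueError("tags length mismatch")
        self.tags = [list(t) for t in self.tags]
        if np.any(self.lj_sigma <= 0):
            raise ValueError("lj_sigma must be positive")
        if np.any(self.lj_epsilon < 0):
            raise ValueError("lj_epsilon must be non-negative")
        if np.any(self.masses <= 0):
            raise ValueError("masses must be positive")
        self._check_terms()

    def _check_terms(self):
        n = self.n_particles
        for nm, terms, width in (("bonds", self.bonds, 2), ("angles", self.angles, 3),
                                 ("torsions", self.torsions, 4)):
            for t in terms:
                idx = [int(v) for v in t[:width]]
                if len(set(idx)) != width or any(i < 0 or i >= n for i in idx):
                    raise ValueError(f"{nm} term {t} references invalid particles")
                if t[width] < 0:
                    raise ValueError(f"{nm} term {t} has negative force constant")
        for t in self.restraints:
            i, k, _c = t
            kvec = np.atleast_1d(np.asarray(k, dtype=float))
            if not (0 <= int(i) < n) or np.any(kvec < 0) or kvec.size not in (1, 3):
                raise ValueError(f"invalid restraint {t}")
        for t in self.wells:
            i, axis = int(t[0]), int(t[1])
            if not (0 <= i < n) or axis not in (0, 1, 2) or t[3] <= 0:
                raise ValueError(f"invalid well {t}")

    @property
    def n_particles(self) -> int:
        return self.positions.shape[0]

    def has_tag(self, i: int, tag: str) -> bool:
        return tag in self.tags[i]

    def tagged(self, tag: str) -> list[int]:
        return [i for i in range(self.n_particles) if tag in self.tags[i]]

    def total_charge(self) -> float:
        return float(self.charges.sum())

    def to_dict(self) -> dict:
        return {
            "positions": self.positions.tolist(),
            "charges": self.charges.tolist(),
            "lj_sigma": self.lj_sigma.tolist(),
            "lj_epsilon": self.lj_epsilon.tolist(),
            "masses": self.masses.tolist(),
            "bonds": [list(b[:2]) + [b[2], b[3]] for b in self.bonds],
            "angles": [list(a) for a in self.angles],
            "torsions": [list(t) for t in self.torsions],
            "restraints": [[r[0], list(r[1]) if np.ndim(r[1]) else r[1], list(r[2])]
                           for r in self.restraints],
            "wells": [list(w) for w in self.wells],
            "tags": self.tags,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ParticleSystem":
        return cls(
            positions=np.asarray(d["positions"], dtype=float),
            charges=np.asarray(d["charges"], dtype=float),
            lj_sigma=np.asarray(d["lj_sigma"], dtype=float),
            lj_epsilon=np.asarray(d["lj_epsilon"], dtype=float),
            masses=np.asarray(d["masses"], dtype=float),
            bonds=[tuple([int(b[0]), int(b[1]), float(b[2]), float(b[3])]) for b in d["bonds"]],
            angles=[tuple([int(a[0]), int(a[1]), int(a[2]), float(a[3]), float(a[4])])
                    for a in d["angles"]],
            torsions=[tuple([int(t[0]), int(t[1]), int(t[2]), int(t[3]),
                             float(t[4]), int(t[5]), float(t[6])]) for t in d["torsions"]],
            restraints=[(int(r[0]),
                         tuple(float(v) for v in r[1]) if isinstance(r[1], (list, tuple))
                         else float(r[1]),
                         tuple(float(v) for v in r[2]))
                        for r in d["restraints"]],
            wells=[(int(w[0]), int(w[1]), float(w[2]), float(w[3]), float(w[4]), float(w[5]))
                   for w in d["wells"]],
            tags=[list(t) for t in d["tags"]],
        )


@dataclass
class ToyMutationPair:
    """A WT ("old") and mutant ("new") system related by an atom mapping.

    atom_map is a list of (old_index, new_index) pairs for atoms that share
    coordinates in the hybrid; unmapped atoms are unique to one endstate.
    analytic_delta_g, when flagged valid, is the exact free energy change
    old -> new in kcal/mol under the temperature stored in meta.
    """

    old_system: ParticleSystem
    new_system: ParticleSystem
    atom_map: list
    analytic_delta_g: float | None = None
    analytic_valid: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        olds = [m[0] for m in self.atom_map]
        news = [m[1] for m in self.atom_map]
        if len(set(olds)) != len(olds) or len(set(news)) != len(news):
            raise ValueError("atom_map must be one-to-one")
        n_old, n_new = self.old_system.n_particles, self.new_system.n_particles
        if any(i < 0 or i >= n_old for i in olds) or any(j < 0 or j >= n_new for j in news):
            raise ValueError("atom_map indices out of range")
        self.atom_map = [(int(a), int(b)) for a, b in self.atom_map]

    @property
    def net_charge_change(self) -> int:
        return int(round(self.new_system.total_charge() - self.old_system.total_charge()))

    def reversed(self) -> "ToyMutationPair":
        """The new -> old transformation (forward/reverse consistency checks)."""
        return ToyMutationPair(
            old_system=self.new_system,
            new_system=self.old_system,
            atom_map=[(b, a) for a, b in self.atom_map],
            analytic_delta_g=(-self.analytic_delta_g
                              if self.analytic_delta_g is not None else None),
            analytic_valid=self.analytic_valid,
            meta={**self.meta, "reversed": not self.meta.get("reversed", False)},
        )

    def to_dict(self) -> dict:
        return {
            "schema_version": SCHEMA_VERSION,
            "old_system": self.old_system.to_dict(),
            "new_system": self.new_system.to_dict(),
            "atom_map": [list(m) for m in self.atom_map],
            "analytic_delta_g": self.analytic_delta_g,
            "analytic_valid": self.analytic_valid,
            "meta": self.meta,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ToyMutationPair":
        if d.get("schema_version", 0) > SCHEMA_VERSION:
            raise ValueError(f"unsupported fixture schema version {d['schema_version']}")
        return cls(
            old_system=ParticleSystem.from_dict(d["old_system"]),
            new_system=ParticleSystem.from_dict(d["new_system"]),
            atom_map=[tuple(m) for m in d["atom_map"]],
            analytic_delta_g=d.get("analytic_delta_g"),
            analytic_valid=bool(d.get("analytic_valid", False)),
            meta=d.get("meta", {}),
        )


def save_pair(pair: ToyMutationPair, path) -> None:
    with open(path, "w") as fh:
        json.dump(pair.to_dict(), fh, indent=1)


def load_pair(path) -> ToyMutationPair:
    with open(path) as fh:
        return ToyMutationPair.from_dict(json.load(fh))


def write_xyz(system: ParticleSystem, path, comment: str = "") -> None:
    """Plain XYZ export (coordinates in nm) for visual inspection."""
    with open(path, "w") as fh:
        fh.write(f"{system.n_particles}\n{comment}\n")
        for i, p in enumerate(system.positions):
            label = system.tags[i][0][:2].upper() if system.tags[i] else "X"
            fh.write(f"{label} {p[0]:.6f} {p[1]:.6f} {p[2]:.6f}\n")


# ---------------------------------------------------------------------------
# Fixture generators
# ---------------------------------------------------------------------------

def _spread_centers(n: int, rng: np.random.Generator, spacing: float = 2.0) -> np.ndarray:
    """Well-separated anchor sites (jittered grid), so zero-charge, zero-eps
    particles are effectively independent."""
    side = max(1, math.ceil(n ** (1.0 / 3.0)))
    grid = np.array([[ix, iy, iz] for ix in range(side)
                     for iy in range(side) for iz in range(side)][:n], dtype=float)
    return grid * spacing + rng.normal(0.0, 0.05, size=(n, 3))


def make_harmonic_ladder(n_particles: int, k_old: float, k_new: float,
                         temperature: float, seed: int,
                         n_mutating: int = 1) -> ToyMutationPair:
    """Independent 3-D harmonic oscillators anchored to fixed centers.

    The first ``n_mutating`` particles change spring constant from k_old to
    k_new between endstates.  The exact free energy change is
    (3*n_mutating/2) * kT * ln(k_new/k_old) from the Gaussian partition
    function, making this the primary oracle fixture for MBAR.
    """
    if k_old <= 0 or k_new <= 0:
        raise ValueError(f"spring constants must be positive, got k_old={k_old}, k_new={k_new}")
    if n_particles < 1 or not (1 <= n_mutating <= n_particles):
        raise ValueError("need n_particles >= 1 and 1 <= n_mutating <= n_particles")
    rng = np.random.default_rng(seed)
    centers = _spread_centers(n_particles, rng)
    base = dict(
        positions=centers.copy(),
        charges=np.zeros(n_particles),
        lj_sigma=np.full(n_particles, 0.3),
        lj_epsilon=np.zeros(n_particles),
        masses=np.full(n_particles, 12.0),
        tags=[["mutating"] if i < n_mutating else [] for i in range(n_particles)],
    )
    k_env = 10.0  # non-mutating anchors, identical in both endstates
    res_old = [(i, k_old if i < n_mutating else k_env, tuple(centers[i]))
               for i in range(n_particles)]
    res_new = [(i, k_new if i < n_mutating else k_env, tuple(centers[i]))
               for i in range(n_particles)]
    old = ParticleSystem(restraints=res_old, **{k: np.copy(v) if isinstance(v, np.ndarray) else v
                                                for k, v in base.items()})
    new = ParticleSystem(restraints=res_new, **{k: np.copy(v) if isinstance(v, np.ndarray) else v
                                                for k, v in base.items()})
    dg = 1.5 * n_mutating * kT(temperature) * math.log(k_new / k_old)
    return ToyMutationPair(
        old_system=old, new_system=new,
        atom_map=[(i, i) for i in range(n_particles)],
        analytic_delta_g=dg, analytic_valid=True,
        meta={"kind": "harmonic_ladder", "temperature": temperature, "seed": seed,
              "k_old": k_old, "k_new": k_new, "n_mutating": n_mutating},
    )


def make_lj_mutation(cluster_size: int, delta_sigma: float, delta_epsilon: float,
                     delta_charge: float, seed: int) -> ToyMutationPair:
    """Small restrained LJ cluster in which one tagged particle changes
    sigma/epsilon/charge between endstates (single-topology core mutation).

    For cluster_size == 2 the non-mutating partner is frozen at the origin
    and the mutating particle is weakly anchored there, so the
    configurational integral reduces to a 1-D radial integral (quadrature
    oracle in :mod:`alchex.reference`).
    """
    if cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    sigma0, eps0 = 0.3, 0.2
    if sigma0 + delta_sigma <= 0:
        raise ValueError(f"delta_sigma={delta_sigma} would make sigma non-positive")
    if eps0 + delta_epsilon < 0:
        raise ValueError(f"delta_epsilon={delta_epsilon} would make epsilon negative")
    rng = np.random.default_rng(seed)
    if cluster_size == 2:
        # frozen partner at origin; mutating particle near the LJ minimum
        positions = np.array([[2 ** (1 / 6) * sigma0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        tags = [["mutating"], ["frozen"]]
        restraints = [(0, 5.0, (0.0, 0.0, 0.0))]
    else:
        positions = _spread_centers(cluster_size, rng, spacing=0.45)
        tags = [["mutating"]] + [[] for _ in range(cluster_size - 1)]
        restraints = [(i, 10.0, tuple(positions[i])) for i in range(cluster_size)]
    common = dict(
        lj_sigma=np.full(cluster_size, sigma0),
        lj_epsilon=np.full(cluster_size, eps0),
        masses=np.full(cluster_size, 12.0),
        restraints=restraints,
        tags=[list(t) for t in tags],
    )
    old = ParticleSystem(positions=positions.copy(), charges=np.zeros(cluster_size), **common)
    new = ParticleSystem(positions=positions.copy(), charges=np.zeros(cluster_size),
                         **{k: (v.copy() if isinstance(v, np.ndarray) else
                                [list(t) for t in v] if k == "tags" else list(v))
                            for k, v in common.items()})
    new.lj_sigma[0] += delta_sigma
    new.lj_epsilon[0] += delta_epsilon
    new.charges[0] += delta_charge
    return ToyMutationPair(
        old_system=old, new_system=new,
        atom_map=[(i, i) for i in range(cluster_size)],
        meta={"kind": "lj_mutation", "seed": seed, "delta_sigma": delta_sigma,
              "delta_epsilon": delta_epsilon, "delta_charge": delta_charge,
              "temperature": 300.0},
    )


def _double_well_z(barrier: float, half_width: float, tilt: float, beta: float) -> float:
    a = half_width

    def boltz(u):
        return math.exp(-beta * (barrier * ((u / a) ** 2 - 1.0) ** 2 + tilt * u / (2 * a)))

    z, _ = quad(boltz, -6 * a, 6 * a, limit=200)
    return z


def make_double_well_mutation(barrier: float = 4.5,
                              well_offset_coupling: float = 5.0,
                              temperature: float = 300.0, seed: int = 0,
                              half_width: float = 0.25) -> ToyMutationPair:
    """A planted slow degree of freedom coupled to the alchemical coordinate.

    Particle 1 ("slow_dof") moves in a symmetric quartic double well of
    height ``barrier`` along x; between endstates the well acquires a linear
    tilt of magnitude ``well_offset_coupling``, shifting the equilibrium
    population of the two wells.  The defaults (4.5 kcal/mol barrier,
    about 7.5 kT at 300 K, with a 5 kcal/mol tilt) put the coordinate in
    the rare-hop regime: roughly one barrier crossing per replica per ten
    nominal time units, so short runs drift visibly while remaining far
    from equilibrium — the pathology the diagnostics workflow is meant to
    catch.  Solute tempering to 600 K halves the effective barrier at
    mid-lambda and restores hopping.

    Two additional anchored environment particles serve as decoy degrees of
    freedom for the correlation analysis.  The exact free energy change is a
    1-D quadrature over the well coordinate.
    """
    if barrier <= 0:
        raise ValueError(f"barrier must be positive, got {barrier}")
    rng = np.random.default_rng(seed)
    n = 4
    positions = np.array([
        [0.0, 0.0, 0.0],              # mutating core particle
        [2 * half_width, 0.6, 0.0],   # slow_dof carrier, starts in the +well
        [1.8, 0.0, 0.0],              # environment decoys
        [0.0, 1.8, 0.5],
    ]) + rng.normal(0.0, 0.01, size=(n, 3))
    tags = [["mutating"], ["slow_dof", "mutating"], [], []]
    restraints = [(0, 20.0, tuple(positions[0])),
                  (1, (0.0, 20.0, 20.0), (0.0, 0.6, 0.0)),  # y,z anchored; x free in the well
                  (2, 20.0, tuple(positions[2])),
                  (3, 20.0, tuple(positions[3]))]
    common = dict(
        charges=np.zeros(n),
        lj_sigma=np.full(n, 0.3),
        lj_epsilon=np.zeros(n),
        masses=np.full(n, 12.0),
    )
    well_old = (1, 0, barrier, half_width, 0.0, half_width)
    well_new = (1, 0, barrier, half_width, well_offset_coupling, half_width)
    old = ParticleSystem(positions=positions.copy(), restraints=list(restraints),
                         wells=[well_old], tags=[list(t) for t in tags], **common)
    new = ParticleSystem(positions=positions.copy(), restraints=list(restraints),
                         wells=[well_new], tags=[list(t) for t in tags],
                         **{k: v.copy() for k, v in common.items()})
    beta = 1.0 / kT(temperature)
    # restraint in x is absent for the well particle, so only the well tilt
    # differs between endstates; everything else cancels exactly
    dg = -kT(temperature) * math.log(
        _double_well_z(barrier, half_width, well_offset_coupling, beta)
        / _double_well_z(barrier, half_width, 0.0, beta))
    return ToyMutationPair(
        old_system=old, new_system=new,
        atom_map=[(i, i) for i in range(n)],
        analytic_delta_g=dg, analytic_valid=True,
        meta={"kind": "double_well", "temperature": temperature, "seed": seed,
              "barrier": barrier, "well_offset_coupling": well_offset_coupling,
              "half_width": half_width, "slow_dof_particle": 1, "slow_dof_axis": 0},
    )


def make_insertion_mutation(cluster_size: int, seed: int) -> ToyMutationPair:
    """Dual-topology fixture: the new endstate contains one extra anchored
    particle (unique_new) absent from the old endstate, plus one particle
    present only in the old endstate (unique_old).  Exercises softcore
    lifting, dummy-atom valence retention and the atom-class partition."""
    if cluster_size < 2:
        raise ValueError("cluster_size must be >= 2")
    rng = np.random.default_rng(seed)
    sites = _spread_centers(cluster_size + 1, rng, spacing=0.5)
    sigma0, eps0 = 0.3, 0.15

    def mk(n, extra_site):
        pos = np.vstack([sites[:cluster_size], extra_site[None, :]])
        charges = np.zeros(cluster_size + 1)
        charges[0] = 0.1
        charges[-1] = -0.1
        tags = [["mutating"]] + [[] for _ in range(cluster_size - 1)] + [["mutating"]]
        restraints = [(i, 10.0, tuple(pos[i])) for i in range(cluster_size + 1)]
        return ParticleSystem(
            positions=pos, charges=charges,
            lj_sigma=np.full(cluster_size + 1, sigma0),
            lj_epsilon=np.full(cluster_size + 1, eps0),
            masses=np.full(cluster_size + 1, 12.0),
            restraints=restraints, tags=tags)

    # unique particles of old and new sit at (deliberately) the same site, so
    # coincident-dummy configurations are reachable
    old = mk(cluster_size, sites[cluster_size])
    new = mk(cluster_size, sites[cluster_size])
    new.lj_sigma[-1] = sigma0 + 0.05
    return ToyMutationPair(
        old_system=old, new_system=new,
        atom_map=[(i, i) for i in range(cluster_size)],  # extras unmapped
        meta={"kind": "insertion", "seed": seed, "temperature": 300.0},
    )


def make_charge_change_mutation(base: ToyMutationPair, counter_charge: float) -> ToyMutationPair:
    """Add a counter-particle neutralizing a charge-changing mutation.

    The counter-particle exists in both endstates (mapped, core) with charge
    0 in the old system and ``counter_charge`` in the new one, so the total
    interpolated charge is constant in lambda.  This abstracts the
    water -> counterion transformation used for charge mutations.
    """
    dq = base.net_charge_change
    if dq == 0:
        raise ValueError("base pair has no net charge change; no counter-particle needed")
    if abs(counter_charge + dq) > 1e-9:
        raise ValueError(f"counter_charge={counter_charge} does not neutralize "
                         f"net charge change {dq}")

    def extended(system: ParticleSystem, q: float) -> ParticleSystem:
        far = system.positions.mean(axis=0) + np.array([2.5, 2.5, 2.5])
        return ParticleSystem(
            positions=np.vstack([system.positions, far[None, :]]),
            charges=np.append(system.charges, q),
            lj_sigma=np.append(system.lj_sigma, 0.3),
            lj_epsilon=np.append(system.lj_epsilon, 0.1),
            masses=np.append(system.masses, 18.0),
            bonds=list(system.bonds), angles=list(system.angles),
            torsions=list(system.torsions),
            restraints=list(system.restraints) + [(system.n_particles, 10.0, tuple(far))],
            wells=list(system.wells),
            tags=[list(t) for t in system.tags] + [["counter", "mutating"]],
        )

    old = extended(base.old_system, 0.0)
    new = extended(base.new_system, counter_charge)
    amap = list(base.atom_map) + [(base.old_system.n_particles, base.new_system.n_particles)]
    return ToyMutationPair(
        old_system=old, new_system=new, atom_map=amap,
        analytic_delta_g=None, analytic_valid=False,
        meta={**base.meta, "counter_charge": float(counter_charge),
              "base_kind": base.meta.get("kind"), "kind": "charge_change"},
    )
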