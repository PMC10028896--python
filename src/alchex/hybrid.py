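"""Hybrid (dual) topology construction.

The hybrid system contains both endstates at once: mapped atoms share
coordinates and carry both old and new nonbonded parameters, while
unmapped atoms exist only at one endstate and become non-interacting
"dummy" atoms (valence terms retained) at the other.  Atoms are
partitioned into four classes that drive the alchemical interpolation:

* ``unique_old`` — unmapped, present only in the WT endstate;
* ``unique_new`` — unmapped, present only in the mutant endstate;
* ``core``       — mapped atoms of the mutating region, parameters
  interpolated between endstates;
* ``environment`` — mapped atoms outside the mutating region, never
  modified.

For solute tempering, each interaction is further classified as ``rest``
(all participating atoms inside the REST region), ``inter`` (some in,
some out) or ``nonrest`` (none in), based on a single reference
configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .systems import ParticleSystem, ToyMutationPair

# atom-class codes
ENV, CORE, UNIQUE_OLD, UNIQUE_NEW = 0, 1, 2, 3
_CLASS_NAMES = {ENV: "environment", CORE: "core",
                UNIQUE_OLD: "unique_old", UNIQUE_NEW: "unique_new"}


@dataclass
class AtomClasses:
    unique_old: set
    unique_new: set
    core: set
    environment: set

    def __post_init__(self):
        sets = [self.unique_old, self.unique_new, self.core, self.environment]
        n = sum(len(s) for s in sets)
        union = set().union(*sets)
        if len(union) != n:
            raise ValueError("atom classes must be pairwise disjoint")
        if union and union != set(range(max(union) + 1)):
            raise ValueError("atom classes must cover the hybrid index range")

    @property
    def n_atoms(self) -> int:
        return (len(self.unique_old) + len(self.unique_new)
                + len(self.core) + len(self.environment))

    def codes(self) -> np.ndarray:
        out = np.empty(self.n_atoms, dtype=np.int8)
        for code, s in ((ENV, self.environment), (CORE, self.core),
                        (UNIQUE_OLD, self.unique_old), (UNIQUE_NEW, self.unique_new)):
            for i in s:
                out[i] = code
        return out


@dataclass
class HybridTerm:
    """A valence-class term with endpoint ownership.

    ``params_old``/``params_new`` are the per-endstate parameter tuples;
    a term present at only one endstate (dummy-owned) has None on the
    other side and contributes at full strength at every lambda.  A term
    present at both endstates is energy-interpolated,
    (1-lambda)*U_old + lambda*U_new, which is lambda-independent whenever
    the parameters coincide.
    """
    kind: str            # bond | angle | torsion | restraint | well
    atoms: tuple
    params_old: tuple | None
    params_new: tuple | None
    rest_override: str | None = None   # force a REST class regardless of atoms

    @property
    def matched(self) -> bool:
        return self.params_old is not None and self.params_new is not None


@dataclass
class HybridSystem:
    n_atoms: int
    positions0: np.ndarray            # reference configuration, (n, 3)
    masses: np.ndarray
    q_old: np.ndarray
    q_new: np.ndarray
    sigma_old: np.ndarray
    sigma_new: np.ndarray
    eps_old: np.ndarray
    eps_new: np.ndarray
    atom_classes: AtomClasses
    terms: list                        # list[HybridTerm]
    excluded_pairs: set                # frozenset({i, j}) nonbonded exclusions
    old_index: np.ndarray              # hybrid -> old system index, -1 if absent
    new_index: np.ndarray
    tags: list
    frozen: np.ndarray                 # bool per atom, excluded from dynamics
    rest_membership: np.ndarray | None = None
    class_codes: np.ndarray = field(init=False)

    def __post_init__(self):
        self.class_codes = self.atom_classes.codes()
        if self.atom_classes.n_atoms != self.n_atoms:
            raise ValueError("atom class partition does not cover the hybrid")

    @property
    def alchemical_atoms(self) -> np.ndarray:
        return np.flatnonzero(self.class_codes != ENV)

    def has_tag(self, i: int, tag: str) -> bool:
        return tag in self.tags[i]

    def tagged(self, tag: str) -> list[int]:
        return [i for i in range(self.n_atoms) if tag in self.tags[i]]

    def rest_class(self, atoms) -> str:
        """Three-way REST classification of an interaction by its atoms."""
        if self.rest_membership is None:
            return "nonrest"
        inside = [bool(self.rest_membership[int(a)]) for a in atoms]
        if all(inside):
            return "rest"
        if not any(inside):
            return "nonrest"
        return "inter"

    def to_dict(self) -> dict:
        return {
            "n_atoms": self.n_atoms,
            "positions0": self.positions0.tolist(),
            "masses": self.masses.tolist(),
            "nonbonded": {k: getattr(self, k).tolist()
                          for k in ("q_old", "q_new", "sigma_old", "sigma_new",
                                    "eps_old", "eps_new")},
            "hybrid": {
                "classes": {name: sorted(getattr(self.atom_classes, name))
                            for name in ("unique_old", "unique_new", "core", "environment")},
                "exclusions": sorted(sorted(p) for p in self.excluded_pairs),
                "rest_membership": (self.rest_membership.tolist()
                                    if self.rest_membership is not None else None),
            },
            "terms": [{"kind": t.kind, "atoms": list(t.atoms),
                       "params_old": t.params_old, "params_new": t.params_new}
                      for t in self.terms],
            "tags": self.tags,
        }


def _is_core_tagged(tags: list) -> bool:
    return "mutating" in tags or "counter" in tags


def _hybrid_layout(pair: ToyMutationPair):
    """Hybrid index layout: all old atoms in order, then unique-new atoms."""
    n_old = pair.old_system.n_particles
    n_new = pair.new_system.n_particles
    old_to_new = dict(pair.atom_map)
    mapped_new = set(old_to_new.values())
    unique_new_atoms = [j for j in range(n_new) if j not in mapped_new]
    n_hybrid = n_old + len(unique_new_atoms)
    old_index = np.full(n_hybrid, -1, dtype=int)
    new_index = np.full(n_hybrid, -1, dtype=int)
    old_index[:n_old] = np.arange(n_old)
    for i in range(n_old):
        if i in old_to_new:
            new_index[i] = old_to_new[i]
    for k, j in enumerate(unique_new_atoms):
        new_index[n_old + k] = j
    # map from each endstate's index to hybrid index
    old_to_hybrid = {i: i for i in range(n_old)}
    new_to_hybrid = {}
    for h in range(n_hybrid):
        if new_index[h] >= 0:
            new_to_hybrid[int(new_index[h])] = h
    return n_hybrid, old_index, new_index, old_to_hybrid, new_to_hybrid


def classify_atoms(pair: ToyMutationPair) -> AtomClasses:
    """Partition the hybrid atoms into unique-old/unique-new/core/environment.

    Mapped atoms tagged "mutating" or "counter" (at either endstate) form
    the core; remaining mapped atoms are environment; unmapped atoms are
    unique to their endstate.
    """
    n_hybrid, old_index, new_index, _, _ = _hybrid_layout(pair)
    uo, un, core, env = set(), set(), set(), set()
    for h in range(n_hybrid):
        io, jn = int(old_index[h]), int(new_index[h])
        if io >= 0 and jn < 0:
            uo.add(h)
        elif io < 0 and jn >= 0:
            un.add(h)
        else:
            tagged = (_is_core_tagged(pair.old_system.tags[io])
                      or _is_core_tagged(pair.new_system.tags[jn]))
            (core if tagged else env).add(h)
    return AtomClasses(unique_old=uo, unique_new=un, core=core, environment=env)


def _term_key(kind: str, atoms: tuple) -> tuple:
    if kind == "bond":
        return (kind, tuple(sorted(atoms)))
    if kind in ("angle", "torsion"):
        return (kind, min(tuple(atoms), tuple(reversed(atoms))))
    return (kind, tuple(atoms))


def _collect_terms(system: ParticleSystem, to_hybrid: dict) -> dict:
    out = {}
    for (i, j, k, r0) in system.bonds:
        a = (to_hybrid[int(i)], to_hybrid[int(j)])
        out[_term_key("bond", a)] = ("bond", a, (float(k), float(r0)))
    for (i, j, k, ka, t0) in system.angles:
        a = (to_hybrid[int(i)], to_hybrid[int(j)], to_hybrid[int(k)])
        out[_term_key("angle", a)] = ("angle", a, (float(ka), float(t0)))
    for (i, j, k, l, bar, per, ph) in system.torsions:
        a = tuple(to_hybrid[int(v)] for v in (i, j, k, l))
        out[_term_key("torsion", a)] = ("torsion", a, (float(bar), int(per), float(ph)))
    for (i, ks, center) in system.restraints:
        a = (to_hybrid[int(i)],)
        kvec = tuple(np.broadcast_to(np.asarray(ks, dtype=float), (3,)).tolist())
        out[_term_key("restraint", a)] = ("restraint", a, (kvec, tuple(float(c) for c in center)))
    for (i, axis, bar, a_w, tilt, center) in system.wells:
        a = (to_hybrid[int(i)], int(axis))
        out[_term_key("well", a)] = ("well", a[:1] + (int(axis),),
                                     (float(bar), float(a_w), float(tilt), float(center)))
    return out


def build_hybrid(pair: ToyMutationPair) -> HybridSystem:
    """Build the union topology: shared coordinates for mapped atoms, both
    endstates' nonbonded parameters per atom, valence terms of both
    endstates with endpoint ownership, and unique-old/unique-new
    nonbonded exclusions."""
    classes = classify_atoms(pair)
    n_hybrid, old_index, new_index, old_to_h, new_to_h = _hybrid_layout(pair)
    old, new = pair.old_system, pair.new_system

    for io, jn in pair.atom_map:
        if old.masses[io] != new.masses[jn]:
            raise ValueError(
                f"mapped atoms ({io}, {jn}) have differing masses "
                f"({old.masses[io]} vs {new.masses[jn]}); shared-coordinate "
                f"dynamics would be ill-defined")

    pos = np.zeros((n_hybrid, 3))
    masses = np.zeros(n_hybrid)
    q_old = np.zeros(n_hybrid)
    q_new = np.zeros(n_hybrid)
    # zero-interaction defaults for the absent side: sigma copied from the
    # present side (keeps combining rules well defined), eps and q zero
    sigma_old = np.full(n_hybrid, 0.3)
    sigma_new = np.full(n_hybrid, 0.3)
    eps_old = np.zeros(n_hybrid)
    eps_new = np.zeros(n_hybrid)
    tags = [[] for _ in range(n_hybrid)]
    frozen = np.zeros(n_hybrid, dtype=bool)

    for h in range(n_hybrid):
        io, jn = int(old_index[h]), int(new_index[h])
        if io >= 0:
            pos[h] = old.positions[io]
            masses[h] = old.masses[io]
            q_old[h] = old.charges[io]
            sigma_old[h] = old.lj_sigma[io]
            eps_old[h] = old.lj_epsilon[io]
            tags[h] = list(old.tags[io])
            frozen[h] = "frozen" in old.tags[io]
        if jn >= 0:
            if io < 0:
                pos[h] = new.positions[jn]
                masses[h] = new.masses[jn]
                tags[h] = list(new.tags[jn])
                frozen[h] = "frozen" in new.tags[jn]
            else:
                tags[h] = sorted(set(tags[h]) | set(new.tags[jn]))
            q_new[h] = new.charges[jn]
            sigma_new[h] = new.lj_sigma[jn]
            eps_new[h] = new.lj_epsilon[jn]
        if io >= 0 and jn < 0:
            sigma_new[h] = sigma_old[h]
        if jn >= 0 and io < 0:
            sigma_old[h] = sigma_new[h]

    old_terms = _collect_terms(old, old_to_h)
    new_terms = _collect_terms(new, new_to_h)
    terms = []
    for key in sorted(set(old_terms) | set(new_terms), key=repr):
        o = old_terms.get(key)
        nw = new_terms.get(key)
        kind, atoms = (o or nw)[0], (o or nw)[1]
        terms.append(HybridTerm(kind=kind, atoms=atoms,
                                params_old=o[2] if o else None,
                                params_new=nw[2] if nw else None))

    excluded = {frozenset((a, b)) for a in classes.unique_old for b in classes.unique_new}

    return HybridSystem(
        n_atoms=n_hybrid, positions0=pos, masses=masses,
        q_old=q_old, q_new=q_new, sigma_old=sigma_old, sigma_new=sigma_new,
        eps_old=eps_old, eps_new=eps_new,
        atom_classes=classes, terms=terms, excluded_pairs=excluded,
        old_index=old_index, new_index=new_index, tags=tags, frozen=frozen)


def assign_rest_region(hybrid: HybridSystem, reference_positions: np.ndarray,
                       radius: float) -> HybridSystem:
    """Mark the REST region: all alchemical atoms plus any atom within
    ``radius`` (nm) of an alchemical atom in the reference configuration.
    Membership is computed once and not updated during sampling."""
    if radius < 0:
        raise ValueError(f"radius must be non-negative, got {radius}")
    ref = np.asarray(reference_positions, dtype=float).reshape(hybrid.n_atoms, 3)
    member = hybrid.class_codes != ENV
    alch = np.flatnonzero(member)
    if alch.size and np.isfinite(radius):
        d = np.linalg.norm(ref[:, None, :] - ref[None, alch, :], axis=-1)
        member = member | (d.min(axis=1) <= radius)
    elif alch.size and not np.isfinite(radius):
        member = np.ones(hybrid.n_atoms, dtype=bool)
    hybrid.rest_membership = member
    return hybrid
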