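"""Alchemically modified potential energy functions.

The hybrid potential U(x; lambda) interpolates between the WT (lambda=0)
and mutant (lambda=1) endstates:

* electrostatics — screened Coulomb over linearly interpolated charges,
  U = C q_i(l) q_j(l) erfc(alpha r_eff) / r_eff;
* sterics — Lennard-Jones 12-6 over linearly interpolated sigma and
  epsilon (Lorentz-Berthelot combination);
* softcore — inter-particle distances involving unique (single-endstate)
  atoms are "lifted" into a 4th dimension, r_eff = sqrt(r^2 + w(l)^2)
  with w(l) = w_lifting * (chi_old * l + chi_new * (1 - l)), so a
  decoupling atom can never produce a singular energy;
* valence — bonds, angles, torsions, positional restraints and on-site
  double wells; dummy-owned terms stay on at every lambda, terms present
  at both endstates are energy-interpolated;
* solute tempering — every interaction's contribution is multiplied by
  alpha(l)^e with e = 1 (rest), 1/2 (inter, REST2 convention,
  configurable) or 0 (nonrest), where alpha dips from 1 at the endstates
  to T0/Tmax at lambda = 1/2.

Energies are in kcal/mol.  The vectorised :class:`HybridEvaluator` is the
workhorse (it batches over replicas); the module-level functions mirror
the one-shot operations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .constants import BOLTZMANN_KCAL, COULOMB_KCAL_NM
from .hybrid import CORE, ENV, UNIQUE_NEW, UNIQUE_OLD, HybridSystem

_TWO_OVER_SQRT_PI = 2.0 / math.sqrt(math.pi)


@dataclass(frozen=True)
class AlchemicalParams:
    """Nonbonded/alchemical settings.

    w_lifting : maximal softcore lifting distance, nm.  Of the order of an
        LJ diameter so that coincident decoupling atoms are regularised
        without collapsing overlap between neighbouring states.
    screening_alpha : erfc screening parameter, 1/nm; 0 means plain Coulomb
        (the toys are non-periodic, so there is no reciprocal-space part).
    coulomb_constant : kcal nm / (mol e^2).
    cutoff : nonbonded cutoff in nm, or None for no cutoff.
    """
    w_lifting: float = 0.4
    screening_alpha: float = 0.0
    coulomb_constant: float = COULOMB_KCAL_NM
    cutoff: float | None = None

    def __post_init__(self):
        if self.w_lifting < 0 or self.screening_alpha < 0 or self.coulomb_constant <= 0:
            raise ValueError("invalid alchemical parameters")


@dataclass(frozen=True)
class LambdaProtocol:
    """Ordered alchemical states; evenly spaced by default."""
    lambdas: tuple

    def __post_init__(self):
        lam = tuple(float(v) for v in self.lambdas)
        if len(lam) < 1 or lam[0] != 0.0 or lam[-1] != 1.0:
            if not (len(lam) == 1 and lam[0] in (0.0, 1.0)):
                raise ValueError("protocol must start at 0 and end at 1")
        if any(b <= a for a, b in zip(lam, lam[1:])):
            raise ValueError("lambdas must be strictly increasing")
        object.__setattr__(self, "lambdas", lam)

    @classmethod
    def linear(cls, K: int) -> "LambdaProtocol":
        if K < 2:
            raise ValueError("need at least 2 states")
        return cls(tuple(np.linspace(0.0, 1.0, K)))

    @property
    def K(self) -> int:
        return len(self.lambdas)


@dataclass(frozen=True)
class RESTParams:
    """Solute-tempering schedule.

    The scale factor alpha(l) = 1 - 4 l (1 - l) (1 - T0/Tmax) equals 1 at
    both endstates (they must be unscaled) and reaches its minimum T0/Tmax
    at l = 1/2, where the REST region's effective temperature is Tmax.
    inter_exponent is the power of alpha applied to interactions straddling
    the REST boundary (1/2 reproduces the REST2 construction).
    """
    T0: float = 300.0
    Tmax: float = 600.0
    inter_exponent: float = 0.5

    def __post_init__(self):
        if not (self.Tmax >= self.T0 > 0):
            raise ValueError(f"need Tmax >= T0 > 0, got T0={self.T0}, Tmax={self.Tmax}")
        if self.inter_exponent not in (0.5, 1.0):
            raise ValueError("inter_exponent must be 0.5 or 1.0")

    def alpha(self, lam):
        lam = np.asarray(lam, dtype=float)
        return 1.0 - 4.0 * lam * (1.0 - lam) * (1.0 - self.T0 / self.Tmax)


def _check_lambda(lam) -> None:
    if np.any(np.asarray(lam) < 0) or np.any(np.asarray(lam) > 1):
        raise ValueError(f"lambda must lie in [0, 1], got {lam}")


class HybridEvaluator:
    """Precomputed, replica-batched evaluator of U(x; lambda) and forces.

    ``x`` may be a single configuration (n, 3) or a batch (R, n, 3);
    ``lam`` a scalar or length-R array.  All pair interactions use O(N^2)
    explicit pair lists, which is the right trade at toy scale.
    """

    def __init__(self, hybrid: HybridSystem, params: AlchemicalParams | None = None,
                 rest: RESTParams | None = None):
        self.hybrid = hybrid
        self.params = params or AlchemicalParams()
        self.rest = rest
        n = hybrid.n_atoms
        codes = hybrid.class_codes
        ii, jj = np.triu_indices(n, k=1)
        keep = np.array([frozenset((int(a), int(b))) not in hybrid.excluded_pairs
                         for a, b in zip(ii, jj)], dtype=bool)
        self.pi, self.pj = ii[keep], jj[keep]
        self.lift_old = ((codes[self.pi] == UNIQUE_OLD) | (codes[self.pj] == UNIQUE_OLD)).astype(float)
        self.lift_new = ((codes[self.pi] == UNIQUE_NEW) | (codes[self.pj] == UNIQUE_NEW)).astype(float)
        self.m_env = codes == ENV
        self.m_core = codes == CORE
        self.m_old = codes == UNIQUE_OLD
        self.m_new = codes == UNIQUE_NEW
        self._pair_rest_exp = self._rest_exponents(
            [(int(a), int(b)) for a, b in zip(self.pi, self.pj)])
        self._build_terms()

    # -- REST bookkeeping ---------------------------------------------------

    def _rest_exponents(self, atom_tuples) -> np.ndarray:
        if self.rest is None or self.hybrid.rest_membership is None:
            return np.zeros(len(atom_tuples))
        expo = {"rest": 1.0, "inter": self.rest.inter_exponent, "nonrest": 0.0}
        return np.array([expo[self.hybrid.rest_class(t)] for t in atom_tuples])

    def _rest_scale(self, lam, exponents):
        """alpha(lam)^e per interaction; exact 1.0 when REST is off."""
        if self.rest is None or self.hybrid.rest_membership is None:
            return None
        alpha = np.asarray(self.rest.alpha(lam), dtype=float)
        return np.power(alpha[..., None], exponents)

    # -- per-atom interpolation --------------------------------------------

    def charges(self, lam):
        """Interpolated per-atom charges q_i(lambda), batched over lam."""
        lam = np.asarray(lam, dtype=float)[..., None]
        h = self.hybrid
        return (self.m_old * (1.0 - lam) * h.q_old
                + self.m_new * lam * h.q_new
                + self.m_core * ((1.0 - lam) * h.q_old + lam * h.q_new)
                + self.m_env * h.q_old)

    def sigmas(self, lam):
        lam = np.asarray(lam, dtype=float)[..., None]
        h = self.hybrid
        return (self.m_old * h.sigma_old + self.m_new * h.sigma_new
                + self.m_core * ((1.0 - lam) * h.sigma_old + lam * h.sigma_new)
                + self.m_env * h.sigma_old)

    def epsilons(self, lam):
        # environment epsilon is constant: environment atoms are unmodified
        lam = np.asarray(lam, dtype=float)[..., None]
        h = self.hybrid
        return (self.m_old * (1.0 - lam) * h.eps_old
                + self.m_new * lam * h.eps_new
                + self.m_core * ((1.0 - lam) * h.eps_old + lam * h.eps_new)
                + self.m_env * h.eps_old)

    def effective_distance(self, r, lam):
        """Softcore-lifted pair distances; r shaped (..., P)."""
        lam = np.asarray(lam, dtype=float)[..., None]
        w = self.params.w_lifting * (self.lift_old * lam + self.lift_new * (1.0 - lam))
        return np.sqrt(np.asarray(r) ** 2 + w ** 2)

    # -- valence term tables ------------------------------------------------

    def _build_terms(self):
        h = self.hybrid
        groups = {}
        for t in h.terms:
            mode = 2 if t.matched else (0 if t.params_new is None else 1)
            groups.setdefault(t.kind, []).append((t, mode))
        self._terms = {}
        for kind, entries in groups.items():
            atoms = np.array([e[0].atoms[:1] if kind in ("restraint", "well")
                              else e[0].atoms for e in entries], dtype=int)
            modes = np.array([e[1] for e in entries], dtype=int)
            po = [e[0].params_old if e[0].params_old is not None else e[0].params_new
                  for e in entries]
            pn = [e[0].params_new if e[0].params_new is not None else e[0].params_old
                  for e in entries]
            if self.rest is None or self.hybrid.rest_membership is None:
                rest_exp = np.zeros(len(entries))
            else:
                expo = {"rest": 1.0, "inter": self.rest.inter_exponent, "nonrest": 0.0}
                rest_exp = np.array([
                    expo[e[0].rest_override] if e[0].rest_override is not None
                    else expo[self.hybrid.rest_class(
                        e[0].atoms[:1] if kind in ("restraint", "well") else e[0].atoms)]
                    for e in entries])
            if kind == "well":
                axes = np.array([e[0].atoms[1] for e in entries], dtype=int)
                self._terms[kind] = (atoms[:, 0], axes, modes, po, pn, rest_exp)
            else:
                self._terms[kind] = (atoms, modes, po, pn, rest_exp)

    @staticmethod
    def _side_weights(modes, lam):
        """Endpoint weights (w_old, w_new) per term; lam scalar or (R,)."""
        lam = np.asarray(lam, dtype=float)[..., None]
        wo = np.where(modes == 0, 1.0, np.where(modes == 1, 0.0, 1.0 - lam))
        wn = np.where(modes == 1, 1.0, np.where(modes == 0, 0.0, lam))
        return wo, wn

    # -- nonbonded energies/forces -------------------------------------------

    def _nonbonded(self, x, lam, want_forces):
        h, p = self.hybrid, self.params
        rvec = x[..., self.pj, :] - x[..., self.pi, :]
        r = np.linalg.norm(rvec, axis=-1)
        reff = self.effective_distance(r, lam)
        q = self.charges(lam)
        Q = q[..., self.pi] * q[..., self.pj]
        sig = self.sigmas(lam)
        sij = 0.5 * (sig[..., self.pi] + sig[..., self.pj])
        eps = self.epsilons(lam)
        eij = np.sqrt(eps[..., self.pi] * eps[..., self.pj])
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            inv = 1.0 / reff
            if p.screening_alpha > 0:
                screen = erfc(p.screening_alpha * reff)
            else:
                screen = 1.0
            e_elec = p.coulomb_constant * Q * inv * screen
            x6 = (sij * inv) ** 6
            e_lj = 4.0 * eij * x6 * (x6 - 1.0)
            if p.cutoff is not None:
                beyond = r > p.cutoff
                e_elec = np.where(beyond, 0.0, e_elec)
                e_lj = np.where(beyond, 0.0, e_lj)
            scale = self._rest_scale(lam, self._pair_rest_exp)
            if scale is not None:
                e_elec = e_elec * scale
                e_lj = e_lj * scale
            energies = e_elec.sum(axis=-1), e_lj.sum(axis=-1)
            if not want_forces:
                return energies, None
            # dU/dr_eff
            de_elec = p.coulomb_constant * Q * (-(screen) * inv ** 2)
            if p.screening_alpha > 0:
                de_elec = de_elec - (p.coulomb_constant * Q * inv * _TWO_OVER_SQRT_PI
                                     * p.screening_alpha
                                     * np.exp(-(p.screening_alpha * reff) ** 2))
            de_lj = -24.0 * eij * x6 * (2.0 * x6 - 1.0) * inv
            de = de_elec + de_lj
            if p.cutoff is not None:
                de = np.where(r > p.cutoff, 0.0, de)
            if scale is not None:
                de = de * scale
            # dU/dr = dU/dr_eff * r/r_eff; force on j = -dU/dr * rvec/r
            g = de * inv  # (dU/dr)/r, the factor multiplying rvec
            g = np.where(np.isfinite(g), g, 0.0)
        contrib = g[..., None] * rvec
        forces = np.zeros_like(x)
        fl = np.moveaxis(forces, -2, 0)
        cl = np.moveaxis(contrib, -2, 0)
        np.add.at(fl, self.pi, cl)
        np.add.at(fl, self.pj, -cl)
        return energies, forces

    # -- valence energies/forces ---------------------------------------------

    def _valence(self, x, lam, want_forces):
        total = np.zeros(x.shape[:-2])
        forces = np.zeros_like(x) if want_forces else None

        def accumulate(e_terms, fpairs):
            nonlocal total
            total = total + e_terms
            if want_forces:
                fl = np.moveaxis(forces, -2, 0)
                for idx, contrib in fpairs:
                    np.add.at(fl, idx, np.moveaxis(contrib, -2, 0))

        for kind, data in self._terms.items():
            if kind == "well":
                atoms, axes, modes, po, pn, rexp = data
            else:
                atoms, modes, po, pn, rexp = data
            wo, wn = self._side_weights(modes, lam)
            scale = self._rest_scale(lam, rexp)
            handler = getattr(self, f"_term_{kind}")
            e, fpairs = handler(x, atoms if kind != "well" else (atoms, axes),
                                wo, wn, po, pn, want_forces)
            if scale is not None:
                e = e * scale
                if want_forces:
                    fpairs = [(idx, c * scale[..., None]) for idx, c in fpairs]
            accumulate(e.sum(axis=-1), fpairs if want_forces else [])
        return total, forces

    def _term_bond(self, x, atoms, wo, wn, po, pn, want_forces):
        i, j = atoms[:, 0], atoms[:, 1]
        k_o = np.array([p[0] for p in po]); r0_o = np.array([p[1] for p in po])
        k_n = np.array([p[0] for p in pn]); r0_n = np.array([p[1] for p in pn])
        rvec = x[..., j, :] - x[..., i, :]
        r = np.linalg.norm(rvec, axis=-1)
        e = wo * 0.5 * k_o * (r - r0_o) ** 2 + wn * 0.5 * k_n * (r - r0_n) ** 2
        if not want_forces:
            return e, []
        de = wo * k_o * (r - r0_o) + wn * k_n * (r - r0_n)
        with np.errstate(divide="ignore", invalid="ignore"):
            g = np.where(r > 0, de / r, 0.0)
        contrib = g[..., None] * rvec
        return e, [(i, contrib), (j, -contrib)]

    def _term_restraint(self, x, atoms, wo, wn, po, pn, want_forces):
        i = atoms[:, 0]
        k_o = np.array([p[0] for p in po]); c_o = np.array([p[1] for p in po])
        k_n = np.array([p[0] for p in pn]); c_n = np.array([p[1] for p in pn])
        d_o = x[..., i, :] - c_o
        d_n = x[..., i, :] - c_n
        e = (wo * 0.5 * (k_o * d_o ** 2).sum(axis=-1)
             + wn * 0.5 * (k_n * d_n ** 2).sum(axis=-1))
        if not want_forces:
            return e, []
        contrib = -(wo[..., None] * k_o * d_o + wn[..., None] * k_n * d_n)
        return e, [(i, contrib)]

    def _term_well(self, x, atoms_axes, wo, wn, po, pn, want_forces):
        i, axes = atoms_axes
        B_o = np.array([p[0] for p in po]); a_o = np.array([p[1] for p in po])
        t_o = np.array([p[2] for p in po]); c_o = np.array([p[3] for p in po])
        B_n = np.array([p[0] for p in pn]); a_n = np.array([p[1] for p in pn])
        t_n = np.array([p[2] for p in pn]); c_n = np.array([p[3] for p in pn])
        u = x[..., i, axes]

        def well_e(B, a, t, c):
            v = (u - c) / a
            return B * (v ** 2 - 1.0) ** 2 + t * (u - c) / (2 * a)

        def well_de(B, a, t, c):
            v = (u - c) / a
            return B * 4.0 * v * (v ** 2 - 1.0) / a + t / (2 * a)

        e = wo * well_e(B_o, a_o, t_o, c_o) + wn * well_e(B_n, a_n, t_n, c_n)
        if not want_forces:
            return e, []
        de = wo * well_de(B_o, a_o, t_o, c_o) + wn * well_de(B_n, a_n, t_n, c_n)
        contrib = np.zeros(x.shape[:-2] + (len(i), 3))
        contrib[..., np.arange(len(i)), axes] = -de
        return e, [(i, contrib)]

    def _term_angle(self, x, atoms, wo, wn, po, pn, want_forces):
        i, j, k = atoms[:, 0], atoms[:, 1], atoms[:, 2]
        k_o = np.array([p[0] for p in po]); t0_o = np.array([p[1] for p in po])
        k_n = np.array([p[0] for p in pn]); t0_n = np.array([p[1] for p in pn])
        u = x[..., i, :] - x[..., j, :]
        v = x[..., k, :] - x[..., j, :]
        nu = np.linalg.norm(u, axis=-1)
        nv = np.linalg.norm(v, axis=-1)
        cos = np.clip((u * v).sum(axis=-1) / (nu * nv), -1.0, 1.0)
        theta = np.arccos(cos)
        e = wo * 0.5 * k_o * (theta - t0_o) ** 2 + wn * 0.5 * k_n * (theta - t0_n) ** 2
        if not want_forces:
            return e, []
        de = wo * k_o * (theta - t0_o) + wn * k_n * (theta - t0_n)
        sin = np.sqrt(np.maximum(1.0 - cos ** 2, 1e-12))
        uhat = u / nu[..., None]
        vhat = v / nv[..., None]
        dthe_i = (cos[..., None] * uhat - vhat) / (nu * sin)[..., None]
        dthe_k = (cos[..., None] * vhat - uhat) / (nv * sin)[..., None]
        fi = -de[..., None] * dthe_i
        fk = -de[..., None] * dthe_k
        return e, [(i, fi), (k, fk), (j, -(fi + fk))]

    def _term_torsion(self, x, atoms, wo, wn, po, pn, want_forces):
        i, j, k, l = (atoms[:, c] for c in range(4))
        V_o = np.array([p[0] for p in po]); n_o = np.array([p[1] for p in po])
        ph_o = np.array([p[2] for p in po])
        V_n = np.array([p[0] for p in pn]); n_n = np.array([p[1] for p in pn])
        ph_n = np.array([p[2] for p in pn])
        b1 = x[..., j, :] - x[..., i, :]
        b2 = x[..., k, :] - x[..., j, :]
        b3 = x[..., l, :] - x[..., k, :]
        n1 = np.cross(b1, b2)
        n2 = np.cross(b2, b3)
        nb2 = np.linalg.norm(b2, axis=-1)
        m1 = np.cross(n1, b2 / np.maximum(nb2, 1e-12)[..., None])
        xcomp = (n1 * n2).sum(axis=-1)
        ycomp = (m1 * n2).sum(axis=-1)
        phi = np.arctan2(ycomp, xcomp)
        e = (wo * V_o * (1.0 + np.cos(n_o * phi - ph_o))
             + wn * V_n * (1.0 + np.cos(n_n * phi - ph_n)))
        if not want_forces:
            return e, []
        de = (-wo * V_o * n_o * np.sin(n_o * phi - ph_o)
              - wn * V_n * n_n * np.sin(n_n * phi - ph_n))
        sn1 = np.maximum((n1 ** 2).sum(axis=-1), 1e-12)
        sn2 = np.maximum((n2 ** 2).sum(axis=-1), 1e-12)
        P = (nb2 / sn1)[..., None] * n1
        Q = (nb2 / sn2)[..., None] * n2
        c12 = ((b1 * b2).sum(axis=-1) / np.maximum(nb2 ** 2, 1e-12))[..., None]
        c32 = ((b3 * b2).sum(axis=-1) / np.maximum(nb2 ** 2, 1e-12))[..., None]
        dphi_i = P
        dphi_j = -(1.0 + c12) * P - c32 * Q
        dphi_k = c12 * P + (1.0 + c32) * Q
        dphi_l = -Q
        return e, [(i, -de[..., None] * dphi_i), (j, -de[..., None] * dphi_j),
                   (k, -de[..., None] * dphi_k), (l, -de[..., None] * dphi_l)]

    # -- public evaluation ----------------------------------------------------

    def _prep(self, x, lam):
        x = np.asarray(x, dtype=float)
        scalar = x.ndim == 2
        if scalar:
            x = x[None]
        lam = np.broadcast_to(np.asarray(lam, dtype=float), x.shape[:-2])
        _check_lambda(lam)
        return x, lam, scalar

    def energy_components(self, x, lam):
        x, lam, scalar = self._prep(x, lam)
        (e_elec, e_lj), _ = self._nonbonded(x, lam, False)
        e_val, _ = self._valence(x, lam, False)
        comp = {"electrostatics": e_elec, "sterics": e_lj, "valence": e_val}
        if scalar:
            comp = {k: float(v[0]) for k, v in comp.items()}
        return comp

    def energy(self, x, lam):
        comp = self.energy_components(x, lam)
        return comp["electrostatics"] + comp["sterics"] + comp["valence"]

    def forces(self, x, lam):
        """-dU/dx, kcal/mol/nm, same shape as x."""
        x, lam, scalar = self._prep(x, lam)
        (_, _), f_nb = self._nonbonded(x, lam, True)
        _, f_val = self._valence(x, lam, True)
        f = f_nb + f_val
        return f[0] if scalar else f

    def du_dlambda(self, x, lam, h: float = 1e-4):
        """dU/dlambda at fixed x by central finite difference (one-sided at
        the endpoints)."""
        x = np.asarray(x, dtype=float)
        lam = float(np.asarray(lam))
        _check_lambda(lam)
        lo, hi = max(0.0, lam - h), min(1.0, lam + h)
        e_hi = self.energy(x, hi)
        e_lo = self.energy(x, lo)
        if not (np.all(np.isfinite(np.atleast_1d(e_hi)))
                and np.all(np.isfinite(np.atleast_1d(e_lo)))):
            raise FloatingPointError(
                f"non-finite potential at lambda in [{lo}, {hi}]; cannot differentiate")
        return (e_hi - e_lo) / (hi - lo)

    def u_matrix(self, x, lambdas, temperature: float):
        """Reduced potentials of replica batch x (R, n, 3) at every lambda:
        returns (K, R) in units of kT."""
        x = np.asarray(x, dtype=float)
        beta = 1.0 / (BOLTZMANN_KCAL * temperature)
        out = np.empty((len(lambdas), x.shape[0]))
        for s, lam in enumerate(lambdas):
            out[s] = beta * self.energy(x, np.full(x.shape[0], lam))
        return out


# ---------------------------------------------------------------------------
# one-shot operations
# ---------------------------------------------------------------------------

def interpolated_charge(atom_index: int, hybrid: HybridSystem, lam: float,
                        evaluator: HybridEvaluator | None = None) -> float:
    _check_lambda(lam)
    ev = evaluator or HybridEvaluator(hybrid)
    return float(ev.charges(float(lam))[int(atom_index)])


def effective_distance(r: float, lam: float, pair_class: tuple,
                       params: AlchemicalParams) -> float:
    """Softcore-lifted distance for a pair with indicator pair_class =
    (chi_ij_old, chi_ij_new)."""
    _check_lambda(lam)
    chi_old, chi_new = pair_class
    w = params.w_lifting * (chi_old * lam + chi_new * (1.0 - lam))
    return math.sqrt(r * r + w * w)


def electrostatics_energy(hybrid: HybridSystem, x, lam: float,
                          params: AlchemicalParams | None = None) -> float:
    return HybridEvaluator(hybrid, params).energy_components(x, lam)["electrostatics"]


def sterics_energy(hybrid: HybridSystem, x, lam: float,
                   params: AlchemicalParams | None = None) -> float:
    return HybridEvaluator(hybrid, params).energy_components(x, lam)["sterics"]


def valence_energy(hybrid: HybridSystem, x, lam: float = 0.0) -> float:
    """Valence-class energy (bonds, angles, torsions, restraints, wells).
    Dummy-owned terms contribute at every lambda; matched terms with equal
    endpoint parameters make this lambda-independent."""
    return HybridEvaluator(hybrid).energy_components(x, lam)["valence"]


def total_potential(hybrid: HybridSystem, x, lam: float,
                    params: AlchemicalParams | None = None,
                    rest: RESTParams | None = None) -> float:
    return HybridEvaluator(hybrid, params, rest).energy(x, lam)


def du_dlambda(hybrid: HybridSystem, x, lam: float,
               params: AlchemicalParams | None = None,
               rest: RESTParams | None = None, h: float = 1e-4) -> float:
    return float(HybridEvaluator(hybrid, params, rest).du_dlambda(x, lam, h=h))


def reduced_potential(U: float, temperature: float):
    """u = U / kT, dimensionless."""
    if temperature <= 0:
        raise ValueError("temperature must be positive")
    return np.asarray(U) / (BOLTZMANN_KCAL * temperature)
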