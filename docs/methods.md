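# Methods

## Scope and design

`alchex` implements hybrid-topology alchemical relative free energy
calculations and their sampling diagnostics at desk scale.  The package
trades molecular realism for verifiability: every toy system is built so
that some downstream quantity has an exact answer (a Gaussian partition
function, a 1-D quadrature, an exactly enumerable discrete model), and
the validation suite checks the pipeline against those answers rather
than against reference simulation output.

Units everywhere: nm, kcal/mol, K, elementary charge, amu, ps;
k_B = 0.0019872041 kcal/mol/K, Coulomb constant C = 33.20637
kcal·nm/(mol·e²).  With these units 1 kcal/mol = 4.184 amu·nm²/ps²,
which is the only conversion the integrator needs.

## Toy systems and fixtures

A `ParticleSystem` is a flat particle list with charges, Lennard-Jones
parameters and masses, plus five term types: bonds, angles, torsions
(between particles), and two on-site types — positional restraints
(isotropic or per-axis harmonic anchors) and 1-D quartic double wells
with a linear tilt, U = B((u/a)²−1)² + tilt·u/(2a).  On-site terms are
what make toys anchored, separable, and analytically tractable without a
surrounding molecule.  Systems are non-periodic; there is no cutoff by
default and no reciprocal-space electrostatics (the screened-Coulomb
erfc form is retained with a configurable screening parameter, default
0 = plain Coulomb).

Fixtures and their oracles:

- **Harmonic ladder** — independent 3-D oscillators anchored to fixed
  centers; the mutating particle's spring constant changes k_old→k_new.
  ΔG = (3·n_mut/2)·kT·ln(k_new/k_old) exactly; the quadrature oracle
  recomputes it by numerical 1-D integration.
- **LJ mutation** — a small restrained cluster whose tagged particle
  changes σ/ε/q (single-topology core mutation).  The two-particle
  variant freezes the partner at the origin and weakly anchors the
  mobile particle there, reducing ΔG to a radial integral.
- **Insertion mutation** — dual-topology fixture with one unique-old and
  one unique-new anchored particle sharing a site, exercising softcore
  lifting, dummy valence retention and the atom-class partition.
- **Charge-change mutation** — wraps a charge-changing base fixture with
  a mapped counter-particle whose charge interpolates 0→(−Δq), so the
  total charge is constant in λ.  This abstracts the water→counterion
  transformation used for charge mutations; 24 states are used instead
  of 12, mirroring the doubling used for charge mutations at scale.
- **Double well** (planted slow degree of freedom) — one particle moves
  in a quartic double well along x (tag `slow_dof`); between endstates
  the well acquires a linear tilt, so the equilibrium well populations
  differ at λ=0 and λ=1 and ∂U/∂λ is exactly proportional to the
  coordinate.

### Double-well parameters (the planted pathology)

Defaults: barrier B = 4.5 kcal/mol (≈7.5 kT at 300 K), tilt
c = 5 kcal/mol, half-width a = 0.25 nm.  The choice is kinetic, made by
Kramers-style estimates and confirmed by hop counts: at 300 K the well
curvature gives an attempt frequency of ~2.4/ps, so the hop rate is
~e^(−7.5) of that — roughly one crossing per replica per 10 nominal
time units.  This is the *rarely-hopping* regime: short runs drift
visibly toward equilibrium without reaching it, which is exactly the
signature the convergence diagnostics must catch.  A taller barrier
(≥5 kcal/mol) yields essentially no hops, so the ΔG series looks flat
and the slope test cannot see the problem (slow modes beyond the
simulation horizon are invisible to any time-series diagnostic — a
fundamental limitation, not a defect of the test).  A much larger tilt
(≥6 kcal/mol) makes the downhill conversion at λ=1 so fast that the
drift completes during burn-in.  Solute tempering to Tmax = 600 K
halves the effective barrier at λ = ½ (≈3.8 kT) and restores hopping.

## Hybrid topology

Mapped atoms share coordinates (old-system geometry is the reference)
and carry both endstates' nonbonded parameters; mapped atoms tagged
`mutating` or `counter` are *core* (interpolated), other mapped atoms
are *environment* (never modified); unmapped atoms are unique to one
endstate.  Unique-old/unique-new nonbonded pairs are excluded outright:
the two species never coexist physically, and exclusion avoids spurious
endstate coupling (the lifted form would otherwise give them a constant
residual interaction).  The REST region is all alchemical atoms plus
any atom within a radius (default 0.5 nm) of one in a single reference
configuration; membership is not updated during sampling.

Valence terms carry endpoint ownership.  A term present at only one
endstate (dummy-owned) contributes at full strength at every λ — dummy
atoms retain their valence terms, which keeps them tethered and makes
their free energy contribution cancel between endstates.  A term
present at both endstates is energy-interpolated,
(1−λ)·U_old + λ·U_new, which is λ-independent whenever the parameters
coincide and reduces to the standard behavior for unchanged terms.
This preserves the defining endstate property exactly: U(x;0) is the
unmodified WT potential plus the dummy valence terms of the unique-new
atoms, and symmetrically at λ=1 (validated to 1e−9 kcal/mol against an
independently coded plain-system energy).

## Alchemical potential

Charge, σ and ε interpolation follow the atom class: unique-old
parameters scale with (1−λ), unique-new with λ, core interpolates
linearly, environment is constant.  Environment ε is deliberately held
constant (not scaled by (1−λ)): environment atoms must be unmodified,
consistent with environment charges.  σ for the absent side of a unique
atom is copied from the present side so combining rules stay defined.

Softcore lifting applies only to pairs involving unique atoms:
w(λ) = w_lift·(χ_old·λ + χ_new·(1−λ)) with w_lift = 0.4 nm by default —
of the order of an LJ diameter, enough to regularize coincident
decoupling atoms without collapsing the overlap between neighboring
states.  The λ protocol is K evenly spaced values (K = 12 default, 24
for charge mutations).

REST scaling multiplies each interaction's energy (and force) by
α(λ)^e, with α(λ) = 1 − 4λ(1−λ)(1 − T0/Tmax).  This form satisfies the
required constraints — α(0) = α(1) = 1 so the endstates are unscaled,
minimum T0/Tmax at λ = ½ — and is smooth in λ.  The exponent e is 1 for
pure-REST interactions, ½ for interactions straddling the REST boundary
(the REST2 convention, which preserves the solute-tempering
detailed-balance construction across the boundary; configurable to 1),
and 0 outside.  Added heavy-particle restraints are classed non-REST
regardless of their atoms, so tempering never weakens a diagnostic
restraint.

∂U/∂λ is a central finite difference (h = 1e−4, one-sided at the
endpoints).  A property test verifies second-order convergence by
Richardson comparison; the finite-difference choice keeps the
derivative automatically correct for any future potential term.

## Sampling

BAOAB-splitting Langevin dynamics, friction 1/ps, thermostat always at
T0 (solute tempering enters only through the scaled Hamiltonian).  The
timestep comes from a stability pre-check: bound the stiffest force
constant from the term tables and LJ curvature, then dt = 0.25·(2/ω_max)
capped at 0.1 ps.  Frozen particles (tag `frozen`) are excluded from
dynamics and forces.

AREX alternates dynamics (all replicas batched through one vectorized
evaluator) with a swap sweep of K³ random pairwise Metropolis attempts
on the state permutation — cheap relative to dynamics, and many attempts
approximate an independent draw of the permutation.  The swap kernel is
validated against exact enumeration of a 2-replica/2-state discrete
model (total variation < 0.02 at 1e5 sweeps).  Every iteration records
the reduced potential of every replica at every state, the permutation,
∂U/∂λ, and requested observables.  One recorded iteration carries a
nominal time label of 0.1 ns, matching the convention of reporting
statistical inefficiencies and ΔG time series in nominal nanoseconds;
the diagnostics experiments concentrate 100 MD steps per iteration so
that drift rates on the nominal axis are comparable to the convergence
threshold's scale.

AREST runs the identical loop over the REST-scaled potential.  With
Tmax = T0 the scale factor is exactly 1.0 and the trajectory is
bitwise identical to AREX under a shared seed — a stronger-than-
statistical regression guarantee that the test suite checks directly.

## Estimation

Decorrelation: discard a burn-in fraction (default 10%), estimate the
statistical inefficiency g = 1 + 2Σ(1−t/N)C(t) of per-replica ∂U/∂λ
(autocorrelation truncated at its first negative crossing), subsample
at stride ⌈g⌉, and group samples by the state that generated them.
∂U/∂λ drives the stride because it is the convergence-limiting series;
for ΔG(t) truncation points where the strict stride leaves fewer than
5 samples per state, the stride is capped so every time point still
yields an estimate — its error bar is then optimistic, which the
drifting series itself exposes.

MBAR is solved by L-BFGS minimization of the convex MBAR objective,
followed by Newton–Raphson on the K-dimensional self-consistent system
(gauge f_0 = 0) with a self-consistent fallback: when state overlap is
nearly total the Hessian is ill-conditioned and Newton stagnates above
round-off, so stagnation (residual failing to halve for three
iterations) permanently switches to self-consistent iteration, which is
a contraction.  Convergence tolerance 1e−10 on max|Δf| (1e−8 for
warm-started bootstrap resamples, far below the statistical scale of
the uncertainty itself).  Zero-sample states are filled in as pure
perturbation estimates.  The K = 2 case is cross-checked against an
independently coded Bennett acceptance ratio root-solve.

Uncertainties: resample decorrelated columns with replacement within
each state (preserving N_k), re-solve MBAR per resample; σ is the SD of
resampled ΔG values, the 95% CI the 2.5/97.5 percentiles, and headline
error bars are 2σ.  Default 200 resamples.

## Diagnostics

- **Convergence**: OLS slope of the trailing half (or given window) of
  the ΔG time series.  Converged iff |slope| ≤ 0.1 kcal/mol per nominal
  time unit OR 0 ∈ slope ± 2·SE — faithful to both phrasings of the
  criterion ("close-to-zero slope" and "within statistical uncertainty
  of 0").  Type-I error of the 2·SE rule is verified to sit near its
  nominal few-percent level on flat-plus-noise series.
- **Mixing**: per-replica occupancy histograms, pooled empirical
  transition matrix and its subdominant eigenvalue, round-trip counts
  (state 0 → K−1 → 0), bottleneck flag if any replica misses states or
  the eigenvalue exceeds 0.995.  The validation suite's uniformity
  check thins each replica's state sequence by its statistical
  inefficiency before the chi-square test: raw replica-exchange series
  are autocorrelated, which would invalidate the multinomial null.
- **∂U/∂λ–DOF correlation**: Pearson correlation per replica between
  ∂U/∂λ and each cataloged observable (torsion angles in degrees on
  (−180, 180], frames with degenerate geometry excluded; pair
  distances; neighbor counts within a radius), averaged over replicas
  with a bootstrap-over-replicas 95% CI.  The category summary reports
  the max-|PCC| entry per category with rows ordered by ∂U/∂λ
  inefficiency, descending.
- **Internal consistency**: forward vs negated-reverse ΔG; the pair is
  inconsistent only if *neither* value is within 1 kcal/mol of the
  other's 95% CI.  Set-level RMSE/MUE carry bootstrap CIs (1000
  resamples).
- **Restrained comparison**: heavy-particle restraints (default
  50 kcal/mol/Å², energy ½k·d², classed non-REST and non-alchemical)
  pin the suspected slow motion; if the restrained ΔG series converges
  while the unrestrained one does not, the verdict is
  "conformational-sampling problem"; if both fail, "not solely
  conformational"; otherwise "no detected problem".

## Validation experiments and problem sizes

The validation suite (driven by `alchex.validation`, reported by
`scripts/acceptance.py`) uses these sizes, chosen to give each check
statistical teeth at desk scale:

| experiment | size |
|---|---|
| MBAR vs analytic | 20 repeats × (K=12, 2·10⁴ exact decorrelated samples, 100 bootstrap resamples) |
| endstate equivalence | 50 randomized fixtures × 20 configurations |
| swap kernel | 10⁵ Gibbs sweeps on the 2×2 discrete model |
| replica random walk | K=12, 600 iterations × 20 steps |
| inefficiency calibration | n = 10⁵ iid and AR(1) φ=0.9 |
| forward/reverse | 20 trials × 2 directions × (K=12, 250 iterations) |
| slow-DOF detection / restrained diagnosis | 5 seeds × (K=12, 100 iterations × 100 steps), 20-point ΔG series, paired restrained runs |
| AREST benefit | 5 seed pairs × (K=12, 200 iterations × 100 steps) |

For the MBAR calibration, exact Gaussian state sampling replaces MD:
the energy-interpolated harmonic restraint is itself harmonic at every
λ, so i.i.d. Boltzmann samples are available in closed form and the
experiment isolates the estimator from the sampler (which has its own
checks).  The calibration uses 100 bootstrap resamples: the sampling
error of σ at that size (~7%) is negligible against the 3σ acceptance
margin, and it keeps the 20-repeat experiment fast.

## What the toys do and do not show

Passing these checks demonstrates that the machinery is correct: the
alchemical potential has the required endstate, continuity, charge and
softcore properties; the sampler targets the right joint distribution;
MBAR and its error bars are calibrated; and the diagnostics detect a
*planted* slow degree of freedom that is, by construction, perfectly
correlated with ∂U/∂λ.  The slope-test verdicts on the double-well
fixture are intrinsically stochastic: the drift rate at these
conditions sits near the fixed 0.1 kcal/mol-per-unit threshold, so
whether a given 5-seed batch flags 3, 4 or 5 runs as unconverged varies
with the seeds (the correlation-table ranking and the AREST
inefficiency contrast are far more stable).  Real protein systems differ in ways the toys
deliberately omit: rugged many-minima landscapes with many coupled slow
modes (detection then depends on having cataloged the right
observables), explicit solvent and periodic electrostatics
(reciprocal-space terms are out of scope here), constraint algorithms,
and force-field detail.  The slope-based convergence test inherits its
real-world blind spot: a slow mode with correlation time beyond the
simulation horizon produces a flat series and a false "converged"
verdict — the tall-barrier regime of the double-well fixture reproduces
this failure mode on demand.

## Numerical notes and edge cases

- Coincident interacting particles with no lift produce non-finite
  energies; propagation aborts with a configuration dump, and the
  evaluator zeroes the corresponding force entries so diagnostics can
  still report.
- Constant series have g defined as 1 with a degeneracy flag;
  zero-variance observables get NaN PCC with a degeneracy flag.
- The autocorrelation truncation (first negative crossing) slightly
  underestimates g for strongly correlated short series; the AR(1)
  calibration bounds the bias at 20% for g ≈ 19, n = 10⁵.
- Bootstrap resamples that fail to converge are redrawn with a cap
  (warning past 10% failures).
- JSON fixture round trips are bitwise because floats serialize via
  `repr` (shortest round-trip representation).
- Fixture randomness, run randomness and bootstrap randomness are all
  `numpy.random.default_rng` streams keyed by a single integer seed.
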