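# alchex

Desk-scale alchemical relative free energy calculations with replica
exchange, solute tempering, MBAR estimation, and a sampling-diagnostics
workflow — exercised on toy particle systems with analytic and
brute-force oracles.

## Who this is for

Relative free energy calculations for protein mutations are notoriously
sensitive to *sampling problems*: slow conformational degrees of freedom
that fail to equilibrate within feasible simulation time, producing
free energy estimates that look precise but drift with more data.
`alchex` reimplements the full methodology — hybrid dual topology,
softcore alchemical potentials, alchemical replica exchange (AREX),
replica exchange with solute tempering (AREST), MBAR, and the
convergence/mixing/slow-degree-of-freedom diagnostics — at a scale where
every stage can be checked against an exact answer.  It is a test bed
for the method, not a production MD engine: systems are small particle
clusters with planted pathologies, and the oracles (Gaussian partition
functions, 1-D quadrature, exact enumeration of discrete replica
exchange) are first-class citizens.

## The method

A mutation is expressed as a **hybrid topology**: mapped atoms share
coordinates and carry both endstates' nonbonded parameters; unmapped
atoms are *unique* to one endstate and become non-interacting dummies
(valence terms retained) at the other.  Atoms partition into
`unique_old / unique_new / core / environment` classes.  The alchemical
potential U(x; λ) interpolates:

- electrostatics: U = C·q_i(λ)q_j(λ)·erfc(α·r_eff)/r_eff with linearly
  interpolated charges;
- sterics: Lennard-Jones 12-6 with linearly interpolated σ, ε
  (Lorentz–Berthelot combination);
- softcore: distances involving unique atoms are lifted into a 4th
  dimension, r_eff = √(r² + w(λ)²), w(λ) = w_lift·(χ_old·λ + χ_new·(1−λ)),
  so decoupling atoms never produce singularities;
- solute tempering (AREST): each interaction is scaled by α(λ)^e with
  e = 1 (all atoms in the REST region), ½ (boundary-crossing), or 0,
  where α(λ) dips from 1 at the endstates to T0/Tmax at λ = ½.

**AREX** is a Gibbs sampler alternating Langevin dynamics (BAOAB) per
replica with Metropolis swap sweeps of the replica→state permutation.
Free energies come from **MBAR** on decorrelated reduced-potential
matrices, with bootstrap uncertainties.  The **diagnostics** workflow
asks, in order: has ΔG(t) converged (trailing-window slope,
0 ± 0.1 kcal/mol per time unit)?  are replicas mixing (occupancy,
transition matrix, round trips)?  which degree of freedom correlates
with ∂U/∂λ (Pearson correlation tables)?  and is the problem
conformational (restrained-vs-unrestrained comparison)?

## Worked example

```python
import alchex as ax

# 3 anchored 3-D oscillators; the tagged one stiffens k: 1 -> e^2
pair = ax.make_harmonic_ladder(3, 1.0, 7.389056, 300.0, seed=1)
print(f"analytic dG = {pair.analytic_delta_g:.4f} kcal/mol")

hybrid = ax.build_hybrid(pair)
record = ax.run_arex(hybrid, ax.LambdaProtocol.linear(12),
                     ax.AlchemicalParams(), n_iterations=400,
                     steps_per_iteration=20, temperature=300.0, seed=7)
matrix = ax.decorrelate(record)
result = ax.bootstrap_delta_g(matrix, n_bootstrap=200, seed=3)
print(f"MBAR dG = {result.delta_g:.4f} +/- {2*result.sigma:.4f} kcal/mol")

mix = ax.replica_mixing_report(record)
print(f"round trips per replica: min {mix.round_trips.min()}, "
      f"bottleneck: {mix.bottleneck}")
```

Output from this exact snippet:

```
analytic dG = 1.7885 kcal/mol
MBAR dG = 1.7975 +/- 0.1009 kcal/mol
round trips per replica: min 10, bottleneck: False
```

The MBAR estimate agrees with the closed-form Gaussian free energy
(3·kT at this spring-constant ratio) within its two-standard-deviation
error bar, and every replica performs multiple round trips through the
12 alchemical states.

The same pipeline is scriptable from the shell:

```bash
alchex fixtures --system harmonic_ladder --k-old 1 --k-new 7.389 --out fx/
alchex run --config run.yaml
alchex estimate --record out/record
alchex diagnose --record out/record
```

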