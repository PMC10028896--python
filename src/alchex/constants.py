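"""Physical constants and unit conventions.

Units throughout the package: lengths in nm, energies in kcal/mol,
temperatures in K, charges in elementary charge units (e), masses in amu,
times in ps.  With these units 1 kcal/mol = 4.184 amu nm^2/ps^2, which is
the conversion used by the Langevin integrator.
"""

# Boltzmann constant, kcal/mol/K
BOLTZMANN_KCAL = 0.0019872041

# Coulomb constant C in kcal*nm/(mol*e^2): k_e * N_A * e^2 expressed in
# these units (332.0637 kcal*Angstrom/(mol*e^2) / 10).
COULOMB_KCAL_NM = 33.20637

# 1 kcal/mol in amu*nm^2/ps^2 (kJ/mol is exactly 1 in MD units).
KCAL_TO_MD = 4.184


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    return BOLTZMANN_KCAL * temperature
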