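"""Physical constants and unit conventions.

Internal units: lengths in Angstrom, energies in kcal/mol, times in ps,
masses in amu (g/mol), temperatures in K, charges in elementary charge.
"""

#: Avogadro constant (1/mol), CODATA defined value.
N_AVOGADRO = 6.02214076e23

#: Molar gas constant in kcal mol^-1 K^-1.
R_KCAL = 1.987204259e-3

#: Coulomb prefactor in kcal mol^-1 Angstrom e^-2.
COULOMB_K = 332.0637133

#: Converts force/mass (kcal mol^-1 A^-1 / amu) to acceleration (A ps^-2).
ACCEL_UNIT = 418.4

#: Angstrom^3 -> litre.
A3_TO_L = 1e-27


def kT(temperature: float) -> float:
    """Thermal energy k_B*T in kcal/mol."""
    return R_KCAL * temperature


def beta(temperature: float) -> float:
    """Inverse thermal energy 1/(k_B*T) in mol/kcal."""
    return 1.0 / kT(temperature)
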