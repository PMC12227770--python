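"""Adams-value machinery: the conversions tying the grand canonical control
parameter B to concentration, excess chemical potential, dissociation
constant and standard binding free energy.

The Adams value for a species held in equilibrium with a reference solution
of concentration c is

    B_eq(c) = beta * mu'_sol + ln(V_GCMC / V(c))
            = beta * mu'_sol + ln(N_A * c * V_GCMC),

where mu'_sol is the excess chemical potential (approximated by the
infinitely dilute solvation free energy), V_GCMC is the volume of the region
open to insertions/deletions, and V(c) = 1/(N_A c) is the average volume per
molecule in solution.  The Adams value at which a single binding site is
occupied half the time, B_50, corresponds to c = K_D and equals the
dimensionless gas-to-site transfer free energy, from which

    dG0 = kT * ln(K_D / c0),  c0 = 1 M by convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import A3_TO_L, N_AVOGADRO, beta as beta_fn, kT as kT_fn

__all__ = [
    "AdamsSpec",
    "volume_per_molecule",
    "b_from_concentration",
    "concentration_from_b",
    "b50_from_kd",
    "kd_from_b50",
    "dg_from_kd",
    "dg_from_b50",
    "boltzmann_population",
]


def volume_per_molecule(c: float) -> float:
    """Average volume per molecule (A^3) in a solution of concentration c (M)."""
    if c <= 0:
        raise ValueError("concentration must be positive")
    return 1.0 / (c * N_AVOGADRO * A3_TO_L)


@dataclass
class AdamsSpec:
    """Thermodynamic context for Adams-value conversions.

    mu_ex : excess chemical potential of the species in the reference
        solution (kcal/mol), with optional standard error.
    temperature : K.
    v_gcmc : volume of the GCMC region (A^3).
    c_std : standard-state concentration (mol/L), 1 M by convention.
    """

    mu_ex: float
    temperature: float = 298.0
    v_gcmc: float = 1.0
    c_std: float = 1.0
    mu_ex_err: float = 0.0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.v_gcmc <= 0:
            raise ValueError("v_gcmc must be positive")
        if self.c_std <= 0:
            raise ValueError("c_std must be positive")

    @property
    def beta(self) -> float:
        return beta_fn(self.temperature)

    @property
    def kT(self) -> float:
        return kT_fn(self.temperature)

    @property
    def v_std(self) -> float:
        """Standard-state volume per molecule, 1/(c0 N_A), in A^3."""
        return volume_per_molecule(self.c_std)


def b_from_concentration(spec: AdamsSpec, c: float) -> float:
    """Adams value for equilibrium with a reference solution at c (mol/L)."""
    if c <= 0:
        raise ValueError("concentration must be positive")
    return spec.beta * spec.mu_ex + math.log(spec.v_gcmc / volume_per_molecule(c))


def concentration_from_b(spec: AdamsSpec, b: float) -> float:
    """Reference-solution concentration (mol/L) implied by an Adams value."""
    return math.exp(b - spec.beta * spec.mu_ex) / (
        N_AVOGADRO * spec.v_gcmc * A3_TO_L
    )


def b50_from_kd(spec: AdamsSpec, kd: float) -> float:
    """Adams value giving 50% site occupancy for dissociation constant kd (M)."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    return b_from_concentration(spec, kd)


def kd_from_b50(spec: AdamsSpec, b50: float) -> float:
    """Dissociation constant (mol/L) from the half-occupancy Adams value."""
    return concentration_from_b(spec, b50)


def dg_from_kd(kd: float, temperature: float = 298.0, c_std: float = 1.0) -> float:
    """Standard Gibbs binding free energy, dG0 = kT ln(K_D / c0), kcal/mol."""
    if kd <= 0:
        raise ValueError("K_D must be positive")
    return kT_fn(temperature) * math.log(kd / c_std)


def dg_from_b50(
    spec: AdamsSpec, b50: float, b50_err: float = 0.0
) -> tuple[float, float]:
    """Standard binding free energy with standard error from B_50.

    dG0 = kT*B50 - mu_ex - kT*ln(V_GCMC/V_std): the gas-to-site transfer
    free energy minus the solvation free energy and the standard-state
    correction.  Algebraically identical to dg_from_kd(kd_from_b50(B50)).
    The error combines kT*sigma(B50) and sigma(mu_ex) in quadrature.
    """
    kT_ = spec.kT
    dg = kT_ * b50 - spec.mu_ex - kT_ * math.log(spec.v_gcmc / spec.v_std)
    err = math.hypot(kT_ * b50_err, spec.mu_ex_err)
    return dg, err


def boltzmann_population(delta_f_kt: float) -> tuple[int, int]:
    """Two-state populations (rounded %) for a free-energy gap in kT units.

    The favoured state has p = 1 / (1 + exp(-dF)); a gap of 0.79 kT gives
    the 69:31 split typical of competing ligand binding modes.
    """
    try:
        p = 1.0 / (1.0 + math.exp(-delta_f_kt))
    except OverflowError:
        p = 0.0 if delta_f_kt < 0 else 1.0
    major = round(100.0 * p)
    return major, 100 - major
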