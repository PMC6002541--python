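"""Internal unit system and physical constants.

Lengths are carried in angstrom, time in picoseconds, charge in units of the
elementary charge e, and potential in volt.  In this system the bulk ion
diffusion constants take their literature values directly (e.g. D_K+ =
0.196 A^2/ps) and thermal voltages are O(25 mV), so no quantity spans a
pathological exponent range.  Currents come out in e/ps and are converted to
ampere only at the observables layer.
"""

from __future__ import annotations

#: elementary charge in coulomb (2019 SI exact value)
E_CHARGE_C = 1.602176634e-19

#: Boltzmann constant over e, in volt per kelvin (k_B T / e = KB_OVER_E * T)
KB_OVER_E = 8.617333262e-5

#: vacuum permittivity in e / (V * angstrom)
#: eps0 = 8.8541878128e-12 C/(V m) = 8.8541878128e-12 / e * 1e-10  e/(V A)
EPS0_E_PER_V_A = 8.8541878128e-12 / E_CHARGE_C * 1e-10

#: number density of a 1 mol/L solution in angstrom^-3
MOLAR_TO_PER_A3 = 6.02214076e-4

#: 1 e/ps expressed in ampere
E_PER_PS_TO_AMPERE = E_CHARGE_C / 1e-12  # = 1.602176634e-7 A

NM = 10.0  # angstrom per nanometre


def thermal_voltage(temperature_K: float) -> float:
    """k_B T / e in volt."""
    return KB_OVER_E * temperature_K


def molar_to_density(c_mol_per_L: float) -> float:
    """mol/L -> number density in A^-3."""
    return c_mol_per_L * MOLAR_TO_PER_A3
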