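"""Physical constants and unit conversions.

Package-wide unit conventions: lengths in Å, times in ns, voltages in mV,
charges in elementary charges e, currents in pA, conductances in nS,
diffusion coefficients in cm²/s at the API surface (converted to Å²/ns
internally), energies in kcal/mol where the aMD machinery needs them.
"""

from __future__ import annotations

# CODATA 2018 exact values
BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO = 6.02214076e23

#: 1 e/ns expressed in pA (1.602176634e-19 C / 1e-9 s = 1.602176634e-10 A).
E_PER_NS_TO_PA = 160.2176634

#: 1 cm²/s expressed in Å²/ns.
CM2_PER_S_TO_A2_PER_NS = 1.0e7

#: kcal/mol per Kelvin (molar gas constant in kcal/mol/K).
KCAL_PER_MOL_PER_K = 1.987204259e-3

#: 1 mol/L expressed in particles per Å³.
MOL_PER_L_TO_PER_A3 = AVOGADRO / 1.0e27


def kt_joule(temperature_k: float) -> float:
    """Thermal energy k_B·T in joules."""
    return BOLTZMANN_J_PER_K * temperature_k


def kt_kcal_per_mol(temperature_k: float) -> float:
    """Thermal energy k_B·T in kcal/mol."""
    return KCAL_PER_MOL_PER_K * temperature_k


def beta_e_per_volt(temperature_k: float) -> float:
    """e/(k_B·T) in 1/volt — how many thermal units one volt of work is worth."""
    return ELEMENTARY_CHARGE_C / kt_joule(temperature_k)
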