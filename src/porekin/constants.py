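"""Physical constants (CODATA 2018) and unit helpers.

Package-wide unit conventions: current in pA, voltage in mV, time in s,
temperature in K, concentration in mol/L, length in nm unless a function
documents otherwise. Energies are reported in both kBT and kcal/mol.
"""

from __future__ import annotations

import numpy as np

BOLTZMANN_J_PER_K = 1.380649e-23
ELEMENTARY_CHARGE_C = 1.602176634e-19
AVOGADRO_PER_MOL = 6.02214076e23
VACUUM_PERMITTIVITY_F_PER_M = 8.8541878128e-12
FARADAY_C_PER_MOL = 96485.33212
GAS_CONSTANT_J_PER_MOL_K = 8.314462618
JOULE_PER_KCAL = 4184.0

#: default relative permittivity of water used for screening-length estimates
WATER_REL_PERMITTIVITY = 78.0


def thermal_energy_J(temperature_K: float) -> float:
    """kB*T in joules."""
    return BOLTZMANN_J_PER_K * float(temperature_K)


def thermal_voltage_mV(temperature_K: float) -> float:
    """kB*T/e in millivolts (25.4 mV at 295 K)."""
    return 1e3 * thermal_energy_J(temperature_K) / ELEMENTARY_CHARGE_C


def kBT_to_kcal_per_mol(energy_kBT: float, temperature_K: float) -> float:
    """Convert an energy expressed in kBT units to kcal/mol at the given T."""
    return (
        float(energy_kBT)
        * GAS_CONSTANT_J_PER_MOL_K
        * float(temperature_K)
        / JOULE_PER_KCAL
    )


def require_positive(**kwargs: float) -> None:
    """Raise ValueError naming the first non-positive keyword argument."""
    for name, value in kwargs.items():
        if not np.isfinite(value) or value <= 0:
            raise ValueError(f"{name} must be positive and finite, got {value!r}")
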