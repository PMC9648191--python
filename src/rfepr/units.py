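"""Physical constants and the thermodynamic state.

Internal energies are carried in kJ/mol (the GROMACS convention, matching the
units of the restraint force constants), while free energies are reported in
kcal/mol.  The kcal-facing gas constant is fixed at the CODATA-derived value
1.98720425864e-3 kcal/mol/K so that population ratios printed to one or two
significant figures round the way practitioners expect.
"""

from __future__ import annotations

from dataclasses import dataclass

#: Molar gas constant, kJ/mol/K.
GAS_CONSTANT_KJ: float = 8.31446261815324e-3

#: Molar gas constant, kcal/mol/K.
GAS_CONSTANT_KCAL: float = 1.98720425864e-3

#: Thermochemical calorie: kJ per kcal.
KJ_PER_KCAL: float = 4.184

#: Coulomb prefactor 1/(4 pi eps0) in kJ mol^-1 nm e^-2 (GROMACS convention).
COULOMB_CONSTANT: float = 138.935458


@dataclass(frozen=True)
class ThermoState:
    """Temperature and derived thermal-energy scales.

    Parameters
    ----------
    temperature : float
        Absolute temperature in kelvin.  Must be positive.
    """

    temperature: float = 300.0

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")

    @property
    def rt_kj(self) -> float:
        """Thermal energy RT in kJ/mol."""
        return GAS_CONSTANT_KJ * self.temperature

    @property
    def rt_kcal(self) -> float:
        """Thermal energy RT in kcal/mol."""
        return GAS_CONSTANT_KCAL * self.temperature


def kj_to_kcal(value_kj: float) -> float:
    """Convert an energy from kJ/mol to kcal/mol."""
    return value_kj / KJ_PER_KCAL


def kcal_to_kj(value_kcal: float) -> float:
    """Convert an energy from kcal/mol to kJ/mol."""
    return value_kcal * KJ_PER_KCAL
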