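"""Physical constants, reference electrodes, and energy unit conversions.

Every formula in the package threads temperature and the gas constant
through a :class:`PhysicalConstants` instance rather than hard-coding
298.15 K, so the effective temperature of the Nernst and acidity terms
stays testable.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

#: 1 hartree in electronvolt.
HARTREE_TO_EV = 27.2114
#: 1 hartree in kJ/mol.
HARTREE_TO_KJMOL = 2625.50
#: 1 eV in kJ/mol (derived so the three units stay mutually consistent).
EV_TO_KJMOL = HARTREE_TO_KJMOL / HARTREE_TO_EV

#: Absolute potentials of the reference electrodes, in V.  SHE is the
#: aqueous convention, SCE the acetonitrile one.
REFERENCE_POTENTIALS = {"SHE": 4.281, "SCE": 4.429}

_TO_HARTREE = {
    "hartree": 1.0,
    "eV": 1.0 / HARTREE_TO_EV,
    "kJ/mol": 1.0 / HARTREE_TO_KJMOL,
}


def convert_energy(value: float, from_unit: str, to_unit: str) -> float:
    """Convert an energy between hartree, eV and kJ/mol.

    Round-trips are identities to better than 1e-12 relative because all
    conversions route through a single constants table.
    """
    for unit in (from_unit, to_unit):
        if unit not in _TO_HARTREE:
            raise ValueError(
                f"unknown energy unit {unit!r}; supported units are "
                f"{sorted(_TO_HARTREE)}"
            )
    if not math.isfinite(value):
        raise ValueError(f"energy value must be finite, got {value!r}")
    return value * _TO_HARTREE[from_unit] / _TO_HARTREE[to_unit]


@dataclass(frozen=True)
class PhysicalConstants:
    """Constants entering the electrochemical and statistical formulas.

    Parameters
    ----------
    R : gas constant, J mol^-1 K^-1.
    T : temperature, K.
    F : Faraday constant, C mol^-1.
    n_electrons : electrons transferred in the redox step.
    reference : reference electrode label ("SHE" or "SCE").
    dG_1atm_to_1M : standard-state correction (1 atm gas -> 1 M solution)
        in kJ/mol, stored as the conventional literal +7.91.
    use_literal_standard_state : if False, the correction is recomputed
        as RT ln(24.46) (~7.93 kJ/mol at 298.15 K) instead of the literal.
    """

    R: float = 8.31446
    T: float = 298.15
    F: float = 96485.3
    n_electrons: int = 1
    reference: str = "SHE"
    dG_1atm_to_1M: float = 7.91
    use_literal_standard_state: bool = True

    def __post_init__(self) -> None:
        if self.R <= 0 or self.T <= 0 or self.F <= 0:
            raise ValueError("R, T and F must be strictly positive")
        if self.n_electrons < 1:
            raise ValueError("n_electrons must be >= 1")
        if self.reference not in REFERENCE_POTENTIALS:
            raise ValueError(
                f"unknown reference electrode {self.reference!r}; "
                f"supported: {sorted(REFERENCE_POTENTIALS)}"
            )

    @property
    def ref_potential(self) -> float:
        """Absolute potential of the chosen reference electrode, V."""
        return REFERENCE_POTENTIALS[self.reference]

    @property
    def RT(self) -> float:
        """R*T in J/mol."""
        return self.R * self.T

    @property
    def RT_kjmol(self) -> float:
        """R*T in kJ/mol."""
        return self.R * self.T / 1000.0

    @property
    def nernst_volt(self) -> float:
        """RT/F in volts -- the prefactor of every Nernst log term."""
        return self.R * self.T / self.F

    @property
    def standard_state_correction(self) -> float:
        """The 1 atm -> 1 M free-energy correction actually applied, kJ/mol."""
        if self.use_literal_standard_state:
            return self.dG_1atm_to_1M
        return self.RT_kjmol * math.log(24.46)


#: Default constants: 298.15 K, one electron, SHE reference.
DEFAULT_CONSTANTS = PhysicalConstants()
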