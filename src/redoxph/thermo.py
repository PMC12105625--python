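"""Solution-phase free-energy assembly and thermodynamic-cycle quantities.

The one-electron oxidation free energy in solution is obtained from a
Born-Haber cycle: gas-phase adiabatic ionization plus the difference of
the solvation free energies of the cation radical and the neutral.
Per-species solution free energies G_sol are assembled from single-point
electronic energies, ZPE, thermal corrections, the 1 atm -> 1 M
standard-state term, and the continuum solvation free energy.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DEFAULT_CONSTANTS, PhysicalConstants, convert_energy

__all__ = [
    "ThermoComponents",
    "PhaseEnergyPair",
    "assemble_gsol",
    "solvation_free_energy",
    "adiabatic_ionization_energy",
    "oxidation_free_energy_solution",
    "cbs_extrapolate",
]


@dataclass(frozen=True)
class ThermoComponents:
    """Per-conformer energy bookkeeping feeding the G_sol assembly.

    ``e_tot_singlepoint``, ``zpe`` and ``dg_thermal_0K_to_298K`` are in
    hartree; ``dg_solv`` is in kJ/mol.  ``apply_standard_state`` toggles
    the 1 atm -> 1 M correction.
    """

    e_tot_singlepoint: float
    zpe: float
    dg_thermal_0K_to_298K: float
    dg_solv: float
    apply_standard_state: bool = True

    def __post_init__(self) -> None:
        for name in ("e_tot_singlepoint", "zpe", "dg_thermal_0K_to_298K", "dg_solv"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.zpe < 0:
            raise ValueError("zero-point energy must be non-negative")


@dataclass(frozen=True)
class PhaseEnergyPair:
    """Total energies of a neutral molecule and its radical cation in one phase."""

    g_neutral: float
    g_cation: float
    phase: str  # "gas" or "solution"
    unit: str = "hartree"

    def __post_init__(self) -> None:
        if self.phase not in ("gas", "solution"):
            raise ValueError(f"phase must be 'gas' or 'solution', got {self.phase!r}")
        if not (math.isfinite(self.g_neutral) and math.isfinite(self.g_cation)):
            raise ValueError("phase energies must be finite")


def assemble_gsol(
    components: ThermoComponents,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """Assemble the solution-phase free energy G_sol, in kJ/mol.

    G_sol = E_tot + ZPE + dG_thermal (hartree terms converted to kJ/mol)
    + standard-state correction (if requested) + dG_solv.
    """
    gas_part_hartree = (
        components.e_tot_singlepoint
        + components.zpe
        + components.dg_thermal_0K_to_298K
    )
    g = convert_energy(gas_part_hartree, "hartree", "kJ/mol")
    if components.apply_standard_state:
        g += constants.standard_state_correction
    return g + components.dg_solv


def solvation_free_energy(
    g_solution: float,
    g_gas: float,
    unit_solution: str = "hartree",
    unit_gas: str | None = None,
) -> float:
    """Solvation free energy as G_sol(solution geometry) - G_gas(same geometry).

    Both energies must carry the same unit tag; the result is in that unit.
    """
    if unit_gas is None:
        unit_gas = unit_solution
    if unit_gas != unit_solution:
        raise ValueError(
            f"unit mismatch: solution energy in {unit_solution!r}, "
            f"gas energy in {unit_gas!r}"
        )
    return g_solution - g_gas


def adiabatic_ionization_energy(pair: PhaseEnergyPair) -> float:
    """Adiabatic ionization energy (AIE) in eV from fully optimized gas-phase
    energies of the neutral and its radical cation.

    Solution-phase input is rejected: use
    :func:`oxidation_free_energy_solution` for the solvated cycle.
    """
    if pair.phase != "gas":
        raise ValueError(
            "adiabatic ionization energy is defined for gas-phase energies; "
            "use oxidation_free_energy_solution for the solution phase"
        )
    return convert_energy(pair.g_cation - pair.g_neutral, pair.unit, "eV")


def oxidation_free_energy_solution(
    dg_ie_gas: float,
    dg_solv_cation: float,
    dg_solv_neutral: float,
) -> float:
    """Close the thermodynamic cycle: solution-phase ionization free energy.

    dG_IE^sol = dG_IE^gas + dG_solv(cation radical) - dG_solv(neutral).
    All three inputs must share one unit; the result is in that unit.
    """
    for v in (dg_ie_gas, dg_solv_cation, dg_solv_neutral):
        if not math.isfinite(v):
            raise ValueError("all cycle terms must be finite")
    return dg_ie_gas + dg_solv_cation - dg_solv_neutral


def cbs_extrapolate(
    e_tz: float,
    e_qz: float,
    x: int = 3,
    y: int = 4,
    exponent: int = 3,
) -> float:
    """Two-point complete-basis-set extrapolation of total energies.

    Inverse-power form on the cardinal numbers of the correlation-consistent
    basis pair (default cc-pVTZ/cc-pVQZ, X=3, Y=4, cubic weighting):

        E_CBS = (Y^p * E_QZ - X^p * E_TZ) / (Y^p - X^p)

    The exponent is configurable; the fixed point E_TZ == E_QZ maps to
    itself for any exponent.
    """
    if y <= x or x < 2:
        raise ValueError("cardinal numbers must satisfy Y > X >= 2")
    wx, wy = float(x) ** exponent, float(y) ** exponent
    return (wy * e_qz - wx * e_tz) / (wy - wx)
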