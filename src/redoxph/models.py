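"""Oxidation-potential models M1-M4 and the prototropic machinery.

A dissociating molecule RH has two one-electron oxidation pathways:
the neutral one (RH -> RH+. ) and the deprotonated one (R- -> R.).
The hierarchy of models converts solution-phase ionization free energies
into observable potentials:

* **M1** -- standard potential of one pathway: E = dG_IE^sol/nF - ref.
* **M2** -- Henderson-Hasselbalch mole-fraction average of the two
  pathways' M1 potentials at a given pH.
* **M3** -- Nernst prototropic correction for one pathway:
  E = E0 + (RT/F) ln[(10^-pH + Ka(0)r)/(10^-pH + Ka(+1)o)].
* **M4** -- Nernst treatment with both protonated and deprotonated
  oxidants/reductants active; relative to M3 it adds the neutralization
  term (RT/F) ln[Ka(+1)o/Ka(0)r] and doubles the pH/Ka term.

Ka(+1)o is the acidity constant of the radical cation RH+., Ka(0)r that
of the neutral reduced molecule RH.  Non-acidic sites are expressed with
the literal sentinel Ka = 0.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .constants import DEFAULT_CONSTANTS, PhysicalConstants

__all__ = [
    "AcidBaseSpec",
    "MoleFractions",
    "RedoxCouple",
    "PotentialResult",
    "pka_to_delta_g",
    "pka_to_ka",
    "ka_to_pka",
    "mole_fractions",
    "m1_potential",
    "m2_potential",
    "prototropic_correction",
    "m3_potential",
    "neutralization_term",
    "m4_potential",
    "select_pathway",
    "speciation_curve",
]

#: Literal Ka for a site with no acidic proton.
NON_ACIDIC = 0.0


def pka_to_ka(pka: float | None) -> float | None:
    """Ka = 10^-pKa; None passes through (meaning: unspecified)."""
    if pka is None:
        return None
    return 10.0 ** (-pka)


def ka_to_pka(ka: float) -> float:
    if ka <= 0:
        raise ValueError("pKa is undefined for Ka <= 0 (non-acidic sentinel)")
    return -math.log10(ka)


def pka_to_delta_g(
    pka: float,
    T: float = DEFAULT_CONSTANTS.T,
    R: float = DEFAULT_CONSTANTS.R,
) -> float:
    """Deprotonation free energy from pKa: dG = ln(10) R T pKa, in kJ/mol.

    One pKa unit costs ~5.708 kJ/mol at 298.15 K.
    """
    if not math.isfinite(pka):
        raise ValueError("pKa must be finite")
    return math.log(10.0) * R * T * pka / 1000.0


@dataclass(frozen=True)
class AcidBaseSpec:
    """Acidity constants of the redox couple's protonation ladder.

    Stored as literal Ka values so that "non-acidic" (Ka = 0) and other
    values with no finite pKa are expressible.  Use :meth:`from_pka` for
    the usual convention.

    ``ka_oxidized_plus1`` -- Ka(+1)o, of the radical cation RH+.
    ``ka_reduced_0``      -- Ka(0)r, of the neutral reduced molecule RH.
    ``ka_reduced_minus1`` -- Ka(-1)r, of the anion R- (optional).
    """

    ka_oxidized_plus1: float | None = None
    ka_reduced_0: float | None = None
    ka_reduced_minus1: float | None = None

    def __post_init__(self) -> None:
        for name in ("ka_oxidized_plus1", "ka_reduced_0", "ka_reduced_minus1"):
            v = getattr(self, name)
            if v is not None and (not math.isfinite(v) or v < 0):
                raise ValueError(f"{name} must be a finite Ka >= 0 or None")

    @classmethod
    def from_pka(
        cls,
        pka_oxidized_plus1: float | None = None,
        pka_reduced_0: float | None = None,
        pka_reduced_minus1: float | None = None,
    ) -> "AcidBaseSpec":
        return cls(
            ka_oxidized_plus1=pka_to_ka(pka_oxidized_plus1),
            ka_reduced_0=pka_to_ka(pka_reduced_0),
            ka_reduced_minus1=pka_to_ka(pka_reduced_minus1),
        )

    @property
    def pka_reduced_0(self) -> float:
        if self.ka_reduced_0 is None:
            raise ValueError("pKa(0)r is not specified")
        return ka_to_pka(self.ka_reduced_0)

    @property
    def is_acidic(self) -> bool:
        """Whether the reduced molecule has an acidic proton at all."""
        return bool(self.ka_reduced_0)  # None or 0 -> False


@dataclass(frozen=True)
class MoleFractions:
    """Henderson-Hasselbalch speciation of RH vs R- at a given pH."""

    x_rh: float
    x_r_minus: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.x_rh <= 1.0 and 0.0 <= self.x_r_minus <= 1.0):
            raise ValueError("mole fractions must lie in [0, 1]")
        if abs(self.x_rh + self.x_r_minus - 1.0) > 1e-12:
            raise ValueError("mole fractions must sum to 1")


def mole_fractions(ph: float, pka: float) -> MoleFractions:
    """Extent of ionization at a given pH: x_RH = 1/(1 + 10^(pH - pKa))."""
    if not (math.isfinite(ph) and math.isfinite(pka)):
        raise ValueError("pH and pKa must be finite")
    x_rh = 1.0 / (1.0 + 10.0 ** (ph - pka))
    return MoleFractions(x_rh=x_rh, x_r_minus=1.0 - x_rh)


@dataclass(frozen=True)
class PotentialResult:
    """A potential value tagged with its model, conditions and pathway."""

    model: str  # M1..M4
    E: float  # V vs the reference electrode
    reference: str
    pH: float | None = None
    pathway: str = "neutral"  # neutral | deprotonated | mixed
    species_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.E):
            raise ValueError("potential must be finite")
        if self.model not in ("M1", "M2", "M3", "M4"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.model != "M1" and self.pH is None:
            raise ValueError(f"{self.model} requires a pH")


@dataclass(frozen=True)
class RedoxCouple:
    """The four-corner oxidation system RH / R- / RH+. / R. plus its
    acidity ladder.

    ``dg_ie_neutral_ev`` is dG_IE(0)r^sol (RH -> RH+.), in eV per electron;
    ``dg_ie_deprotonated_ev`` is dG_IE(-1)r^sol (R- -> R.), optional.
    The deprotonated pathway, being electron-rich, never costs more than
    the neutral one; a couple claiming otherwise is rejected.
    """

    dg_ie_neutral_ev: float
    acid_base: AcidBaseSpec = field(default_factory=AcidBaseSpec)
    dg_ie_deprotonated_ev: float | None = None
    reference: str = "SHE"
    species_id: str | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.dg_ie_neutral_ev):
            raise ValueError("dg_ie_neutral_ev must be finite")
        if self.dg_ie_deprotonated_ev is not None:
            if self.dg_ie_deprotonated_ev > self.dg_ie_neutral_ev:
                raise ValueError(
                    "the deprotonated pathway cannot cost more than the "
                    "neutral one: dG_IE(-1)r <= dG_IE(0)r"
                )


def m1_potential(
    dg_ie_sol_ev: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    pathway: str = "neutral",
    species_id: str | None = None,
) -> PotentialResult:
    """Standard oxidation potential from the solution ionization free energy.

    E = dG_IE^sol / n - ref, with dG in eV per electron (the division by F
    is implicit in the electronvolt unit).
    """
    e = dg_ie_sol_ev / constants.n_electrons - constants.ref_potential
    return PotentialResult(
        model="M1", E=e, reference=constants.reference, pathway=pathway,
        species_id=species_id,
    )


def m2_potential(
    couple: RedoxCouple,
    ph: float,
    constants: PhysicalConstants | None = None,
) -> PotentialResult:
    """Mole-fraction average of the two pathways' M1 potentials at a pH.

    E = x_RH * E_M1(neutral) + x_R- * E_M1(deprotonated), with x from the
    Henderson-Hasselbalch equation at pKa(0)r.  Because the free-energy ->
    potential map is affine, this equals the mole-fraction-weighted dG
    divided by nF.
    """
    constants = constants or PhysicalConstants(reference=couple.reference)
    x = mole_fractions(ph, couple.acid_base.pka_reduced_0)
    e_neutral = m1_potential(couple.dg_ie_neutral_ev, constants).E
    if couple.dg_ie_deprotonated_ev is None:
        if x.x_r_minus > 1e-12:
            raise ValueError(
                "deprotonated-pathway energy is required when x_R- > 0 "
                f"(x_R- = {x.x_r_minus:.3g} at pH {ph})"
            )
        e = e_neutral
    else:
        e_deprot = m1_potential(couple.dg_ie_deprotonated_ev, constants).E
        e = x.x_rh * e_neutral + x.x_r_minus * e_deprot
    return PotentialResult(
        model="M2", E=e, reference=constants.reference, pH=ph,
        pathway="mixed", species_id=couple.species_id,
    )


def _checked_kas(acid_base: AcidBaseSpec) -> tuple[float, float]:
    ka_red = acid_base.ka_reduced_0
    ka_ox = acid_base.ka_oxidized_plus1
    if ka_red is None or ka_ox is None:
        raise ValueError("both Ka(0)r and Ka(+1)o are required")
    return ka_ox, ka_red


def prototropic_correction(
    acid_base: AcidBaseSpec,
    ph: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """The pH/Ka-dependent Nernst term of M3, in V:

    (RT/F) ln[(10^-pH + Ka(0)r) / (10^-pH + Ka(+1)o)].

    Negative whenever the radical cation is the more acidic species
    (Ka(+1)o > Ka(0)r), which is the usual situation.
    """
    ka_ox, ka_red = _checked_kas(acid_base)
    h = 10.0 ** (-ph)
    num, den = h + ka_red, h + ka_ox
    if num <= 0 or den <= 0:
        raise ValueError("10^-pH + Ka must be positive in both states")
    return constants.nernst_volt * math.log(num / den)


def m3_potential(
    e_standard: float,
    acid_base: AcidBaseSpec,
    ph: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    species_id: str | None = None,
) -> PotentialResult:
    """M3: standard potential of one pathway plus the prototropic correction."""
    e = e_standard + prototropic_correction(acid_base, ph, constants)
    return PotentialResult(
        model="M3", E=e, reference=constants.reference, pH=ph,
        species_id=species_id,
    )


def neutralization_term(
    ka_oxidized_plus1: float,
    ka_reduced_0: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
) -> float:
    """(RT/F) ln[Ka(+1)o / Ka(0)r], in V -- the first term of M4.

    It is minus the free energy (per F) of the endergonic neutralization
    RH+. + R- <=> R. + RH, hence positive whenever the radical cation is
    more acidic than the neutral molecule.
    """
    if ka_oxidized_plus1 <= 0 or ka_reduced_0 <= 0:
        raise ValueError("neutralization term requires both Ka strictly positive")
    return constants.nernst_volt * math.log(ka_oxidized_plus1 / ka_reduced_0)


def m4_potential(
    e_standard: float,
    acid_base: AcidBaseSpec,
    ph: float,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    species_id: str | None = None,
) -> PotentialResult:
    """M4: both protonation levels of oxidant and reductant are active.

    E = E0 + (RT/F) ln[Ka(+1)o/Ka(0)r]
          + 2 (RT/F) ln[(10^-pH + Ka(0)r)/(10^-pH + Ka(+1)o)].

    The pH/Ka term enters twice because the added species R. and R- are
    governed by the same acidity constants as RH+. and RH.
    """
    ka_ox, ka_red = _checked_kas(acid_base)
    if ka_red <= 0:
        raise ValueError(
            "M4 requires an acidic reduced molecule (Ka(0)r > 0); for a "
            "non-acidic compound use M3 or the neutral-pathway M1"
        )
    if ka_ox <= 0:
        raise ValueError("M4 requires Ka(+1)o > 0")
    e = (
        e_standard
        + neutralization_term(ka_ox, ka_red, constants)
        + 2.0 * prototropic_correction(acid_base, ph, constants)
    )
    return PotentialResult(
        model="M4", E=e, reference=constants.reference, pH=ph,
        species_id=species_id,
    )


def select_pathway(
    couple: RedoxCouple,
    ph: float,
    threshold: float = 0.5,
) -> str:
    """Choose the pathway whose reduced species dominates at the given pH.

    Returns "deprotonated" iff x_R- strictly exceeds ``threshold``
    (so a pH == pKa tie keeps the neutral pathway at the default 0.5).
    Strongly acidic molecules such as a 5-carboxy nucleobase (pKa ~ 4.3)
    are essentially fully ionized at pH 7 and should be oxidized from R-.
    """
    x = mole_fractions(ph, couple.acid_base.pka_reduced_0)
    return "deprotonated" if x.x_r_minus > threshold else "neutral"


def speciation_curve(
    couple: RedoxCouple,
    e_standard: float,
    model: str,
    ph_grid: Sequence[float],
    constants: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Potential vs pH over a grid for M2, M3 or M4.

    Returns a DataFrame with columns ``pH, E_volts, model, reference``.
    For M3/M4 in the usual ordering Ka(+1)o > Ka(0)r the curve is
    non-increasing in pH, flattening to E0 well below both pKa values.
    """
    if len(ph_grid) == 0:
        raise ValueError("pH grid must be non-empty")
    grid = [float(p) for p in ph_grid]
    if any(b < a for a, b in zip(grid, grid[1:])):
        raise ValueError("pH grid must be ascending")
    constants = constants or PhysicalConstants(reference=couple.reference)
    rows = []
    for ph in grid:
        if model == "M2":
            e = m2_potential(couple, ph, constants).E
        elif model == "M3":
            e = m3_potential(e_standard, couple.acid_base, ph, constants).E
        elif model == "M4":
            e = m4_potential(e_standard, couple.acid_base, ph, constants).E
        else:
            raise ValueError("speciation_curve supports models M2, M3, M4")
        rows.append((ph, e, model, constants.reference))
    return pd.DataFrame(rows, columns=["pH", "E_volts", "model", "reference"])
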