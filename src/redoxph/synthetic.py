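"""Synthetic ensembles and redox couples with known ground truth, plus the
packaged reference tables.

The generators emulate the statistical structure of the real inputs --
conformer ensembles with a controlled free-energy spread, and redox
couples built so that the noiseless pipeline recovers a prescribed
standard potential exactly -- so every downstream stage is testable with
no quantum-chemistry runs and no downloads.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable

import numpy as np
import pandas as pd

from .constants import DEFAULT_CONSTANTS, EV_TO_KJMOL, PhysicalConstants
from .ensembles import ConformerRecord, SpeciesEnsemble
from .models import AcidBaseSpec, RedoxCouple, pka_to_delta_g

__all__ = [
    "SyntheticSystemSpec",
    "GroundTruth",
    "generate_ensemble",
    "generate_redox_couple",
    "generate_species_table",
    "load_fixture",
    "fixture_metadata",
    "parse_censored",
    "FIXTURE_TABLES",
]

FIXTURE_TABLES = ("table1", "table2", "table3", "table4", "table5", "table6")

_STATE_STREAM = {
    ("reduced", "neutral"): 0,
    ("reduced", "deprotonated"): 1,
    ("oxidized", "neutral"): 2,
    ("oxidized", "deprotonated"): 3,
}


@dataclass(frozen=True)
class SyntheticSystemSpec:
    """Ground-truth description of one synthetic redox system.

    ``pka_ladder`` lists the successive deprotonation pKa values of the
    *reduced* species (first entry pKa(0)r, optional second pKa(-1)r),
    and must be non-decreasing (each deprotonation is harder than the
    last).  ``radical_acidity_shift`` is pKa(0)r - pKa(+1)o, >= 0: the
    radical cation is at least as acidic as its parent; 0 gives the
    degenerate couple in which M3 and M4 collapse onto M1.
    """

    seed: int = 0
    true_e_standard: float = 1.50  # V vs reference
    pka_ladder: tuple[float, ...] = (9.5,)
    radical_acidity_shift: float = 5.0
    n_tautomers: int = 2
    n_conformers_per_tautomer: int = 3
    conformer_spread: float = 6.0  # kJ/mol
    solvation_shift_cation: float = -250.0  # kJ/mol
    noise_sd: float = 0.0  # kJ/mol
    reference: str = "SHE"

    def __post_init__(self) -> None:
        if self.n_tautomers < 1 or self.n_conformers_per_tautomer < 1:
            raise ValueError("counts must be >= 1")
        if self.conformer_spread < 0 or self.noise_sd < 0:
            raise ValueError("spread and noise must be non-negative")
        if len(self.pka_ladder) < 1:
            raise ValueError("pKa ladder needs at least one entry")
        if any(b < a for a, b in zip(self.pka_ladder, self.pka_ladder[1:])):
            raise ValueError(
                "pKa ladder must be non-decreasing (each deprotonation is "
                "harder than the previous one)"
            )
        if self.radical_acidity_shift < 0:
            raise ValueError("radical_acidity_shift must be >= 0")

    @property
    def pka_reduced_0(self) -> float:
        return self.pka_ladder[0]

    @property
    def pka_oxidized_plus1(self) -> float:
        return self.pka_ladder[0] - self.radical_acidity_shift


@dataclass(frozen=True)
class GroundTruth:
    """Noiseless quantities a recovery test can compare against."""

    e_standard_neutral: float  # V, M1 of the neutral pathway
    e_standard_deprotonated: float  # V, M1 of the deprotonated pathway
    dg_ie_neutral_ev: float
    dg_ie_deprotonated_ev: float
    acid_base: AcidBaseSpec


def _rng(spec: SyntheticSystemSpec, stream: int) -> np.random.Generator:
    # One named generator per (spec, stream); no global state.
    return np.random.default_rng(np.random.SeedSequence([spec.seed, stream]))


def _corner_base_gsol(
    spec: SyntheticSystemSpec,
    redox_state: str,
    protonation: str,
    constants: PhysicalConstants,
) -> float:
    """Minimum G_sol (kJ/mol) of one corner of the redox square.

    The four corners are mutually consistent: the neutral ionization gap
    equals (true_E + ref) per electron, and each deprotonation costs its
    ladder free energy, so any route around the square closes.
    """
    g = -1000.0  # arbitrary absolute reference for RH
    if redox_state == "oxidized":
        g += (spec.true_e_standard + constants.ref_potential) * EV_TO_KJMOL
        if protonation == "deprotonated":
            g += pka_to_delta_g(spec.pka_oxidized_plus1, T=constants.T, R=constants.R)
    elif protonation == "deprotonated":
        g += pka_to_delta_g(spec.pka_reduced_0, T=constants.T, R=constants.R)
    return g


def generate_ensemble(
    spec: SyntheticSystemSpec,
    redox_state: str = "reduced",
    protonation: str = "neutral",
    constants: PhysicalConstants | None = None,
) -> SpeciesEnsemble:
    """Draw a conformer/tautomer ensemble for one corner of the redox square.

    Conformer G_sol values are the corner's base free energy plus
    exponential-like offsets clipped to ``conformer_spread`` (so the
    low-energy region is denser, as in relaxed conformer searches), plus
    optional Gaussian noise.  Deterministic for a fixed seed; the four
    corners use separate substreams.
    """
    if (redox_state, protonation) not in _STATE_STREAM:
        raise ValueError(f"unknown state {(redox_state, protonation)!r}")
    constants = constants or PhysicalConstants(reference=spec.reference)
    rng = _rng(spec, _STATE_STREAM[(redox_state, protonation)])
    base = _corner_base_gsol(spec, redox_state, protonation, constants)
    records = []
    for t in range(spec.n_tautomers):
        for c in range(spec.n_conformers_per_tautomer):
            if spec.conformer_spread > 0:
                offset = min(
                    rng.exponential(spec.conformer_spread / 3.0),
                    spec.conformer_spread,
                )
            else:
                offset = 0.0
            if t == 0 and c == 0:
                offset = 0.0  # the global minimum anchors the ensemble
            noise = spec.noise_sd * rng.standard_normal() if spec.noise_sd else 0.0
            records.append(
                ConformerRecord(
                    species_id=f"synthetic_{redox_state}_{protonation}",
                    tautomer_id=f"t{t}",
                    conformer_id=f"c{c}",
                    g_sol=base + offset + noise,
                )
            )
    charge = 0 if protonation == "neutral" else -1
    if redox_state == "oxidized":
        charge += 1
    return SpeciesEnsemble(
        species_id=records[0].species_id,
        charge=charge,
        redox_state=redox_state,
        records=records,
    )


def generate_redox_couple(
    spec: SyntheticSystemSpec,
    constants: PhysicalConstants | None = None,
) -> tuple[RedoxCouple, GroundTruth]:
    """Construct a redox couple whose neutral-pathway M1 potential equals
    ``spec.true_e_standard`` exactly at zero noise.

    The deprotonated pathway is placed by closing the thermodynamic
    square: dG_IE(-1)r = dG_IE(0)r + dG_a(+1)o - dG_a(0)r, which encodes
    the fact that the radical cation is the more acidic species and makes
    dG_IE(-1)r <= dG_IE(0)r by construction.
    """
    constants = constants or PhysicalConstants(reference=spec.reference)
    acid_base = AcidBaseSpec.from_pka(
        pka_oxidized_plus1=spec.pka_oxidized_plus1,
        pka_reduced_0=spec.pka_reduced_0,
        pka_reduced_minus1=spec.pka_ladder[1] if len(spec.pka_ladder) > 1 else None,
    )
    dg_neutral = (spec.true_e_standard + constants.ref_potential) * constants.n_electrons
    dga_ox = pka_to_delta_g(spec.pka_oxidized_plus1, T=constants.T, R=constants.R)
    dga_red = pka_to_delta_g(spec.pka_reduced_0, T=constants.T, R=constants.R)
    dg_deprot = dg_neutral + (dga_ox - dga_red) / EV_TO_KJMOL
    truth = GroundTruth(
        e_standard_neutral=spec.true_e_standard,
        e_standard_deprotonated=dg_deprot / constants.n_electrons - constants.ref_potential,
        dg_ie_neutral_ev=dg_neutral,
        dg_ie_deprotonated_ev=dg_deprot,
        acid_base=acid_base,
    )
    if spec.noise_sd > 0:
        rng = _rng(spec, 17)
        eps = spec.noise_sd / EV_TO_KJMOL
        dg_neutral = dg_neutral + eps * rng.standard_normal()
        dg_deprot = min(dg_deprot + eps * rng.standard_normal(), dg_neutral)
    couple = RedoxCouple(
        dg_ie_neutral_ev=dg_neutral,
        dg_ie_deprotonated_ev=dg_deprot,
        acid_base=acid_base,
        reference=spec.reference,
        species_id="synthetic",
    )
    return couple, truth


def generate_species_table(
    spec: SyntheticSystemSpec,
    constants: PhysicalConstants | None = None,
) -> pd.DataFrame:
    """Emit the four corners of a synthetic system in the species-energies
    file schema, decomposed into single-point energy, ZPE, thermal
    correction and solvation free energy so that reassembling G_sol
    through the pipeline reproduces the generated ensembles exactly.

    Cation-bearing states carry ``solvation_shift_cation`` as their
    solvation free energy (charged species solvate far more strongly).
    """
    constants = constants or PhysicalConstants(reference=spec.reference)
    from .constants import HARTREE_TO_KJMOL

    zpe_au, dg_thermal_au = 0.1, 0.01
    rows = []
    for (redox_state, protonation) in _STATE_STREAM:
        ens = generate_ensemble(spec, redox_state, protonation, constants)
        charged = (redox_state == "oxidized" and protonation == "neutral") or (
            redox_state == "reduced" and protonation == "deprotonated"
        )
        dg_solv = spec.solvation_shift_cation if charged else -30.0
        for rec in ens.records:
            e_tot_au = (
                (rec.g_sol - dg_solv - constants.standard_state_correction)
                / HARTREE_TO_KJMOL
                - zpe_au
                - dg_thermal_au
            )
            rows.append(
                {
                    "species_id": "synthetic",
                    "state": redox_state,
                    "protonation": 0 if protonation == "neutral" else -1,
                    "tautomer_id": rec.tautomer_id,
                    "conformer_id": rec.conformer_id,
                    "E_tot_au": e_tot_au,
                    "ZPE_au": zpe_au,
                    "dG_thermal_au": dg_thermal_au,
                    "dG_solv_kjmol": dg_solv,
                    "basis_tag": "none",
                    "explicit_waters": 0,
                }
            )
    return pd.DataFrame(rows)


def load_fixture(table: str) -> pd.DataFrame:
    """Load one of the packaged reference tables (``table1`` .. ``table6``).

    Censored entries (e.g. ">2.15") are preserved as strings; use
    :func:`parse_censored` to split them into values and flags.
    """
    if table not in FIXTURE_TABLES:
        raise ValueError(f"unknown fixture {table!r}; available: {FIXTURE_TABLES}")
    ref = resources.files("redoxph.data").joinpath(f"{table}.csv")
    with resources.as_file(ref) as path:
        return pd.read_csv(path, dtype={"compound": str}, keep_default_na=True)


def fixture_metadata(table: str) -> dict:
    """Sidecar metadata of a packaged table: units, censoring, footnotes."""
    if table not in FIXTURE_TABLES:
        raise ValueError(f"unknown fixture {table!r}; available: {FIXTURE_TABLES}")
    ref = resources.files("redoxph.data").joinpath(f"{table}.meta.json")
    return json.loads(ref.read_text())


def parse_censored(values: Iterable) -> tuple[np.ndarray, list[str]]:
    """Split a fixture column into floats and censoring flags.

    Entries like ">2.15" become (2.15, "lower_bound"); plain numbers are
    (value, "exact"); missing entries become (nan, "exact").
    """
    out_vals, out_flags = [], []
    for v in values:
        if isinstance(v, str) and v.strip().startswith(">"):
            out_vals.append(float(v.strip()[1:]))
            out_flags.append("lower_bound")
        elif v is None or (isinstance(v, float) and math.isnan(v)):
            out_vals.append(float("nan"))
            out_flags.append("exact")
        else:
            out_vals.append(float(v))
            out_flags.append("exact")
    return np.array(out_vals), out_flags
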