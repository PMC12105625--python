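"""End-to-end orchestration: ensembles -> redox couples -> potentials.

For each species the pipeline Boltzmann-combines the conformer ensembles
of the four redox-square corners, forms the pathway ionization free
energies, attaches the acidity ladder, and evaluates the requested model.
Per-species failures (missing states, inapplicable models) are collected
in the report while the run continues for the remaining species.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping

import pandas as pd

from .calibration import AdjustmentRule, linear_adjust
from .constants import EV_TO_KJMOL, PhysicalConstants
from .ensembles import SpeciesEnsemble
from .models import (
    AcidBaseSpec,
    RedoxCouple,
    m1_potential,
    m2_potential,
    m3_potential,
    m4_potential,
    select_pathway,
)

logger = logging.getLogger("redoxph")

__all__ = ["RunConfig", "run_pipeline"]

_MODELS = ("M1", "M2", "M3", "M4")


@dataclass(frozen=True)
class RunConfig:
    """Settings of one pipeline run."""

    model: str = "M1"
    pH: float = 7.0
    reference: str = "SHE"
    temperature: float = 298.15
    averaging_mode: str = "weighted_mean"
    pKa_source: str = "file"  # experimental | computed | file
    adjustment: AdjustmentRule | None = None
    force_neutral_pathway: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in _MODELS:
            raise ValueError(f"model must be one of {_MODELS}")
        if self.pKa_source not in ("experimental", "computed", "file"):
            raise ValueError(f"unknown pKa source {self.pKa_source!r}")
        if not math.isfinite(self.pH):
            raise ValueError("pH must be finite")

    def constants(self) -> PhysicalConstants:
        return PhysicalConstants(T=self.temperature, reference=self.reference)


def _couple_from_ensembles(
    species_id: str,
    ensembles: Mapping[tuple[str, str, int], SpeciesEnsemble],
    acid_base: AcidBaseSpec,
    config: RunConfig,
) -> RedoxCouple:
    def g(state: str, protonation: int) -> float | None:
        ens = ensembles.get((species_id, state, protonation))
        return None if ens is None else ens.g_sol_ensemble

    g_red0, g_ox0 = g("reduced", 0), g("oxidized", 0)
    if g_red0 is None or g_ox0 is None:
        raise ValueError(
            f"{species_id}: neutral-pathway states (reduced/oxidized at "
            "protonation 0) are required"
        )
    dg_neutral = (g_ox0 - g_red0) / EV_TO_KJMOL
    g_redm1, g_oxm1 = g("reduced", -1), g("oxidized", -1)
    dg_deprot = (
        (g_oxm1 - g_redm1) / EV_TO_KJMOL
        if g_redm1 is not None and g_oxm1 is not None
        else None
    )
    return RedoxCouple(
        dg_ie_neutral_ev=dg_neutral,
        dg_ie_deprotonated_ev=dg_deprot,
        acid_base=acid_base,
        reference=config.reference,
        species_id=species_id,
    )


def _evaluate(couple: RedoxCouple, config: RunConfig, log: list[str]):
    constants = config.constants()
    model = config.model
    if model in ("M3", "M4") and not couple.acid_base.is_acidic:
        # no acidic proton: the prototropic models do not apply
        log.append(
            f"{couple.species_id}: no acidic proton (Ka(0)r = 0); "
            f"{model} is not applicable, falling back to M1"
        )
        logger.info(log[-1])
        model = "M1"
    if model == "M1":
        return m1_potential(
            couple.dg_ie_neutral_ev, constants, species_id=couple.species_id
        )
    if model == "M2":
        return m2_potential(couple, config.pH, constants)
    # M3/M4 start from the M1 value of the dominant pathway unless the
    # neutral pathway is forced
    pathway = (
        "neutral"
        if config.force_neutral_pathway
        else select_pathway(couple, config.pH)
    )
    if pathway == "deprotonated" and couple.dg_ie_deprotonated_ev is not None:
        e_standard = m1_potential(couple.dg_ie_deprotonated_ev, constants).E
    else:
        if pathway == "deprotonated":
            log.append(
                f"{couple.species_id}: deprotonated pathway dominant at "
                f"pH {config.pH} but its energies are missing; using neutral"
            )
            pathway = "neutral"
        e_standard = m1_potential(couple.dg_ie_neutral_ev, constants).E
    fn = m3_potential if model == "M3" else m4_potential
    result = fn(
        e_standard, couple.acid_base, config.pH, constants,
        species_id=couple.species_id,
    )
    return type(result)(
        model=result.model, E=result.E, reference=result.reference,
        pH=result.pH, pathway=pathway, species_id=result.species_id,
    )


def run_pipeline(
    config: RunConfig,
    ensembles: Mapping[tuple[str, str, int], SpeciesEnsemble],
    pka_table: Mapping[str, AcidBaseSpec] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Run the chosen model over every species present in the ensembles.

    Returns a results table (one row per species, plus an adjusted column
    when an :class:`AdjustmentRule` is configured) and a report holding
    intermediates and per-species errors.
    """
    from .fileio import results_to_frame

    pka_table = pka_table or {}
    species_ids = sorted({key[0] for key in ensembles})
    if not species_ids:
        raise ValueError("no species in input")

    results, errors, log = [], {}, []
    intermediates = {}
    for sid in species_ids:
        try:
            acid_base = pka_table.get(sid, AcidBaseSpec())
            couple = _couple_from_ensembles(sid, ensembles, acid_base, config)
            intermediates[sid] = {
                "dg_ie_neutral_ev": couple.dg_ie_neutral_ev,
                "dg_ie_deprotonated_ev": couple.dg_ie_deprotonated_ev,
            }
            results.append(_evaluate(couple, config, log))
        except ValueError as exc:
            errors[sid] = str(exc)
            logger.warning("%s: %s", sid, exc)

    frame = results_to_frame(results)
    if config.adjustment is not None and not frame.empty:
        raw = dict(zip(frame["species_id"], frame["E"]))
        adjusted = linear_adjust(raw, config.adjustment)
        frame["E_adjusted"] = frame["species_id"].map(adjusted)
    report = {
        "config": config,
        "n_species": len(species_ids),
        "n_ok": len(results),
        "errors": errors,
        "log": log,
        "intermediates": intermediates,
    }
    return frame, report
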