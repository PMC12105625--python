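"""Conformer/tautomer ensembles: deduplication, Boltzmann averaging, filters.

A species in a given charge and oxidation state is represented by the set
of its conformers and tautomers, each carrying a solution-phase free
energy G_sol (kJ/mol).  The species-level G_sol entering the redox models
is a Boltzmann combination over the set.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .constants import DEFAULT_CONSTANTS, HARTREE_TO_KJMOL

__all__ = [
    "ConformerRecord",
    "SpeciesEnsemble",
    "boltzmann_weights",
    "ensemble_gsol",
    "deduplicate",
    "tautomer_count",
    "contribution_filter",
]


@dataclass(frozen=True)
class ConformerRecord:
    """One conformer of one tautomer: its G_sol (kJ/mol) and, optionally, a
    geometry descriptor (atom-to-centroid distances in angstrom)."""

    species_id: str
    tautomer_id: str
    conformer_id: str
    g_sol: float
    geometry_descriptor: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not math.isfinite(self.g_sol):
            raise ValueError("g_sol must be finite")
        if self.geometry_descriptor is not None:
            desc = tuple(float(d) for d in self.geometry_descriptor)
            if any(d < 0 for d in desc):
                raise ValueError("atom-to-centroid distances must be non-negative")
            object.__setattr__(self, "geometry_descriptor", desc)


def boltzmann_weights(
    g_values: Sequence[float],
    T: float = DEFAULT_CONSTANTS.T,
    R: float = DEFAULT_CONSTANTS.R,
) -> np.ndarray:
    """Boltzmann populations of states with free energies in kJ/mol.

    w_i is proportional to exp(-(G_i - min G)/RT); the min-shift makes the
    computation overflow-safe and the result invariant under adding a
    constant to every G.
    """
    if len(g_values) == 0:
        raise ValueError("need at least one free energy to weight")
    if T <= 0:
        raise ValueError("temperature must be positive")
    g = np.asarray(g_values, dtype=float)
    rt = R * T / 1000.0  # kJ/mol
    w = np.exp(-(g - g.min()) / rt)
    return w / w.sum()


def ensemble_gsol(
    records: Sequence[ConformerRecord],
    T: float = DEFAULT_CONSTANTS.T,
    mode: str = "weighted_mean",
    R: float = DEFAULT_CONSTANTS.R,
) -> float:
    """Boltzmann-combined G_sol of an ensemble, kJ/mol.

    ``weighted_mean`` returns sum_i w_i G_i (population-weighted mean,
    the default reading of a Boltzmann-averaged free energy);
    ``partition_sum`` returns -RT ln sum_i exp(-G_i/RT), the free energy
    of the combined partition function, which lies at or below the most
    stable member.  Both reduce to the single record's G for a singleton.
    """
    if len(records) == 0:
        raise ValueError("ensemble must contain at least one conformer")
    g = np.array([r.g_sol for r in records], dtype=float)
    rt = R * T / 1000.0
    if mode == "weighted_mean":
        w = boltzmann_weights(g, T=T, R=R)
        return float(np.dot(w, g))
    if mode == "partition_sum":
        gmin = g.min()
        return float(gmin - rt * np.log(np.sum(np.exp(-(g - gmin) / rt))))
    raise ValueError(f"unknown averaging mode {mode!r}")


def _descriptors_match(
    a: tuple[float, ...] | None,
    b: tuple[float, ...] | None,
    tol: float,
) -> bool:
    # Absent descriptors cannot distinguish structures; sorting makes the
    # comparison independent of atom ordering.
    if a is None or b is None or len(a) == 0 or len(b) == 0:
        return True
    if len(a) != len(b):
        return False
    return all(abs(x - y) <= tol for x, y in zip(sorted(a), sorted(b)))


def deduplicate(
    records: Sequence[ConformerRecord],
    energy_threshold: float = 1e-7,
    geometry_tolerance: float = 0.01,
) -> list[ConformerRecord]:
    """Collapse duplicate conformers found independently by the search.

    Two records are the same structure iff their G_sol values differ by at
    most ``energy_threshold`` (in hartree) and their sorted atom-to-centroid
    distance lists agree element-wise within ``geometry_tolerance``
    (angstrom); a missing descriptor never blocks a merge.  Each duplicate
    group keeps its lowest-G member (ties broken by conformer_id), so the
    operation is idempotent.
    """
    if not records:
        return []
    if len({r.species_id for r in records}) > 1:
        raise ValueError("deduplicate expects records of a single species")
    thr_kj = energy_threshold * HARTREE_TO_KJMOL
    ordered = sorted(records, key=lambda r: (r.g_sol, r.conformer_id))
    unique: list[ConformerRecord] = []
    for rec in ordered:
        is_dup = any(
            abs(rec.g_sol - kept.g_sol) <= thr_kj
            and _descriptors_match(
                rec.geometry_descriptor, kept.geometry_descriptor, geometry_tolerance
            )
            for kept in unique
        )
        if not is_dup:
            unique.append(rec)
    return unique


def tautomer_count(n_lone_pairs: int, k_acidic_protons: int) -> int:
    """Number of proton arrangements: C(n, k) for k acidic protons
    distributed over n lone pairs."""
    if k_acidic_protons < 0 or n_lone_pairs < 0:
        raise ValueError("counts must be non-negative")
    if k_acidic_protons > n_lone_pairs:
        raise ValueError(
            "cannot place more acidic protons than available lone pairs"
        )
    return math.comb(n_lone_pairs, k_acidic_protons)


def contribution_filter(
    records: Sequence[ConformerRecord],
    threshold: float = 0.02,
    T: float = DEFAULT_CONSTANTS.T,
    R: float = DEFAULT_CONSTANTS.R,
) -> list[ConformerRecord]:
    """Keep the conformers whose Boltzmann weight exceeds ``threshold``.

    Mirrors the screening used to decide which structures warrant further
    (expensive) refinement: only members contributing more than 2% to the
    Boltzmann-averaged G_sol are retained.  The lowest-G record is always
    kept so the result is never empty.
    """
    if not records:
        raise ValueError("cannot filter an empty ensemble")
    w = boltzmann_weights([r.g_sol for r in records], T=T, R=R)
    kept = [r for r, wi in zip(records, w) if wi > threshold]
    if not kept:
        kept = [min(records, key=lambda r: (r.g_sol, r.conformer_id))]
    return kept


@dataclass
class SpeciesEnsemble:
    """All conformers/tautomers of one species in one charge and redox state,
    with the derived Boltzmann G_sol (kJ/mol)."""

    species_id: str
    charge: int
    redox_state: str  # "reduced" or "oxidized"
    records: list[ConformerRecord] = field(default_factory=list)
    averaging_mode: str = "weighted_mean"
    T: float = DEFAULT_CONSTANTS.T

    def __post_init__(self) -> None:
        if self.redox_state not in ("reduced", "oxidized"):
            raise ValueError("redox_state must be 'reduced' or 'oxidized'")
        if not self.records:
            raise ValueError("ensemble must contain at least one conformer")
        if any(r.species_id != self.species_id for r in self.records):
            raise ValueError("all records must share the ensemble's species_id")

    @property
    def g_sol_ensemble(self) -> float:
        """Boltzmann-combined G_sol of the ensemble, kJ/mol."""
        return ensemble_gsol(self.records, T=self.T, mode=self.averaging_mode)

    @property
    def weights(self) -> np.ndarray:
        return boltzmann_weights([r.g_sol for r in self.records], T=self.T)
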