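"""Reading and writing the pipeline's file formats.

The species-energies CSV carries one row per conformer per basis with the
raw energy components; rows with both a TZ and a QZ basis tag for the same
conformer are combined by two-point CBS extrapolation of the single-point
energy before G_sol assembly.
"""
from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Iterable

import pandas as pd

from .calibration import round_display
from .constants import DEFAULT_CONSTANTS, PhysicalConstants
from .ensembles import ConformerRecord, SpeciesEnsemble
from .models import PotentialResult
from .thermo import ThermoComponents, assemble_gsol, cbs_extrapolate

__all__ = [
    "SPECIES_ENERGY_COLUMNS",
    "read_species_energies",
    "results_to_frame",
    "write_results",
]

SPECIES_ENERGY_COLUMNS = [
    "species_id",
    "state",
    "protonation",
    "tautomer_id",
    "conformer_id",
    "E_tot_au",
    "ZPE_au",
    "dG_thermal_au",
    "dG_solv_kjmol",
    "basis_tag",
    "explicit_waters",
]

_KEY_COLUMNS = ["species_id", "state", "protonation", "tautomer_id", "conformer_id"]


def read_species_energies(
    path: str | Path,
    constants: PhysicalConstants = DEFAULT_CONSTANTS,
    apply_standard_state: bool = True,
    averaging_mode: str = "weighted_mean",
) -> dict[tuple[str, str, int], SpeciesEnsemble]:
    """Read a species-energies CSV into ensembles keyed by
    (species_id, state, protonation).

    Validates the schema, rejects duplicate conformer keys with their row
    numbers, CBS-extrapolates TZ/QZ basis pairs, assembles G_sol per
    conformer, and groups conformers into ensembles.
    """
    df = pd.read_csv(path)
    missing = [c for c in SPECIES_ENERGY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"species-energies file is missing column(s): {missing}")
    full_key = _KEY_COLUMNS + ["basis_tag"]
    dup = df.duplicated(subset=full_key, keep=False)
    if dup.any():
        rows = [i + 2 for i in df.index[dup].tolist()]  # 1-based incl. header
        raise ValueError(f"duplicate conformer keys at file rows {rows}")

    ensembles: dict[tuple[str, str, int], list[ConformerRecord]] = {}
    for key, grp in df.groupby(_KEY_COLUMNS, sort=False):
        species_id, state, protonation, tautomer_id, conformer_id = key
        tags = set(grp["basis_tag"])
        if tags == {"TZ", "QZ"}:
            e_tz = float(grp.loc[grp["basis_tag"] == "TZ", "E_tot_au"].iloc[0])
            e_qz = float(grp.loc[grp["basis_tag"] == "QZ", "E_tot_au"].iloc[0])
            e_tot = cbs_extrapolate(e_tz, e_qz)
            row = grp.iloc[0]
        elif len(grp) == 1:
            row = grp.iloc[0]
            e_tot = float(row["E_tot_au"])
        else:
            raise ValueError(
                f"conformer {key} has basis tags {sorted(tags)}; expected a "
                "single row or a TZ/QZ pair"
            )
        g_sol = assemble_gsol(
            ThermoComponents(
                e_tot_singlepoint=e_tot,
                zpe=float(row["ZPE_au"]),
                dg_thermal_0K_to_298K=float(row["dG_thermal_au"]),
                dg_solv=float(row["dG_solv_kjmol"]),
                apply_standard_state=apply_standard_state,
            ),
            constants,
        )
        rec = ConformerRecord(
            species_id=str(species_id),
            tautomer_id=str(tautomer_id),
            conformer_id=str(conformer_id),
            g_sol=g_sol,
        )
        ensembles.setdefault((str(species_id), str(state), int(protonation)), []).append(rec)

    return {
        key: SpeciesEnsemble(
            species_id=key[0],
            charge=key[2] + (1 if key[1] == "oxidized" else 0),
            redox_state=key[1],
            records=records,
            averaging_mode=averaging_mode,
            T=constants.T,
        )
        for key, records in ensembles.items()
    }


def results_to_frame(results: Iterable[PotentialResult]) -> pd.DataFrame:
    """Tabulate potential results with a display-rounded column (2 d.p.)."""
    rows = [asdict(r) for r in results]
    if not rows:
        return pd.DataFrame(
            columns=["species_id", "model", "E", "E_display", "pH", "reference", "pathway"]
        )
    df = pd.DataFrame(rows)
    df["E_display"] = df["E"].map(lambda e: f"{round_display(e, 2):.2f}")
    return df[["species_id", "model", "E", "E_display", "pH", "reference", "pathway"]]


def write_results(
    results: pd.DataFrame | Iterable[PotentialResult],
    path: str | Path,
    format: str = "csv",
) -> Path:
    """Write results as CSV or JSON with a stable column order.

    Floats are serialized at full precision; the ``E_display`` column
    carries the table-style 2 d.p. rounding.
    """
    df = results if isinstance(results, pd.DataFrame) else results_to_frame(results)
    path = Path(path)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        raise ValueError(f"unknown output format {format!r}")
    return path
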