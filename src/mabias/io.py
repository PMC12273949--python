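"""Readers and writers for the pipeline's on-disk formats.

Mutation tables are tab-separated with the canonical header (strain, block,
line, position, ref, alt, class, freq, reads_plus, reads_minus, region,
coding_effect, gene).  Plate-reader data is long-format CSV (plate, well,
clone, role, environment, time_min, od600); a wide-format importer (one
column per well) with a plate-map sidecar is provided for raw instrument
exports.  DFEs serialize to JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .catalog import MUTATION_TABLE_COLUMNS
from .dfe import DFE
from .growth import GrowthCurve

__all__ = [
    "read_mutation_table",
    "write_mutation_table",
    "read_plate_long",
    "write_plate_long",
    "read_plate_wide",
    "write_dfe_json",
    "read_dfe_json",
]

PLATE_LONG_COLUMNS = ["plate", "well", "clone", "role", "environment", "time_min", "od600"]


def read_mutation_table(path: str | Path) -> pd.DataFrame:
    """Read a tab-separated mutation table, validating the header."""
    table = pd.read_csv(path, sep="\t", dtype={"strain": str, "block": str, "line": str, "gene": str})
    missing = set(MUTATION_TABLE_COLUMNS) - set(table.columns) - {"gene"}
    if missing:
        raise ValueError(f"mutation table {path} lacks columns: {sorted(missing)}")
    if "gene" not in table.columns:
        table["gene"] = ""
    table["gene"] = table["gene"].fillna("")
    return table[MUTATION_TABLE_COLUMNS]


def write_mutation_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_plate_long(curves: Iterable[GrowthCurve], path: str | Path) -> None:
    rows = []
    for c in curves:
        for t, od in zip(c.times, c.od600):
            rows.append(
                {"plate": c.plate_id, "well": c.well_id, "clone": c.clone_id,
                 "role": c.role, "environment": c.environment, "time_min": t, "od600": od}
            )
    pd.DataFrame(rows, columns=PLATE_LONG_COLUMNS).to_csv(path, index=False)


def read_plate_long(path: str | Path) -> list[GrowthCurve]:
    """Read long-format plate CSV into GrowthCurve objects (one per well)."""
    table = pd.read_csv(path)
    missing = set(PLATE_LONG_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"plate CSV {path} lacks columns: {sorted(missing)}")
    curves = []
    for (plate, well), group in table.groupby(["plate", "well"], sort=False):
        group = group.sort_values("time_min")
        curves.append(
            GrowthCurve(
                plate_id=str(plate),
                well_id=str(well),
                clone_id=str(group["clone"].iloc[0]),
                role=str(group["role"].iloc[0]),
                environment=str(group["environment"].iloc[0]),
                times=group["time_min"].to_numpy(float),
                od600=group["od600"].to_numpy(float),
            )
        )
    return curves


def read_plate_wide(readings_path: str | Path, plate_map_path: str | Path) -> list[GrowthCurve]:
    """Import a wide instrument export (time_min + one column per well).

    The plate-map sidecar CSV must have columns well, clone, role,
    environment, and optionally plate.
    """
    wide = pd.read_csv(readings_path)
    if "time_min" not in wide.columns:
        raise ValueError("wide plate file needs a 'time_min' column")
    pmap = pd.read_csv(plate_map_path).set_index("well")
    curves = []
    for well in wide.columns:
        if well == "time_min":
            continue
        if well not in pmap.index:
            raise ValueError(f"well {well!r} missing from plate map")
        meta = pmap.loc[well]
        curves.append(
            GrowthCurve(
                plate_id=str(meta.get("plate", "P1")),
                well_id=str(well),
                clone_id=str(meta["clone"]),
                role=str(meta["role"]),
                environment=str(meta["environment"]),
                times=wide["time_min"].to_numpy(float),
                od600=wide[well].to_numpy(float),
            )
        )
    return curves


def write_dfe_json(dfes: Iterable[DFE], path: str | Path, seed: int | None = None) -> None:
    payload = {"seed": seed, "dfes": [d.to_dict() for d in dfes]}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_dfe_json(path: str | Path) -> list[DFE]:
    payload = json.loads(Path(path).read_text())
    dfes = []
    for d in payload["dfes"]:
        dfes.append(
            DFE(
                strain_id=d["strain"],
                environment=d["environment"],
                bin_edges=np.asarray(d["bin_edges"]),
                raw_counts=np.asarray(d["raw_counts"]),
                corrected_weights=np.asarray(d["corrected_weights"]),
                n_mutations=d["n_mutations"],
                f_b=d["f_b"],
                f_n=d["f_n"],
                f_d=d["f_d"],
                median_s=d["median_s"],
            )
        )
    return dfes
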