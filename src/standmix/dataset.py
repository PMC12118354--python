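"""Dataset container and CSV round-trip I/O.

A dataset is two tables plus provenance:

* ``trees.csv`` — one row per sampled tree: identity, stand type, species,
  plot, tree structure (AH, DBH, CA), raw leaf morphology (FW, DW, LT, LA)
  and green/senescent leaf N and P concentrations.
* ``soil.csv`` — one row per plot: topsoil (0–20 cm) physicochemistry.
* ``provenance.json`` — seed, design hash and generator version for
  synthetic data, or whatever metadata accompanied a field dataset.

The schema is strict: load errors name the offending column or row.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SchemaError

TREE_COLUMNS = [
    "tree_id",
    "stand_type",
    "species",
    "plot_id",
    "AH_m",
    "DBH_cm",
    "CA_m2",
    "FW_g",
    "DW_g",
    "LT_mm",
    "LA_cm2",
    "GLNC_gkg",
    "GLPC_gkg",
    "SLNC_gkg",
    "SLPC_gkg",
]
TREE_NUMERIC = TREE_COLUMNS[4:]

SOIL_COLUMNS = [
    "plot_id",
    "stand_type",
    "pH",
    "BD_gcm3",
    "SA_pct",
    "SI_pct",
    "CL_pct",
    "SOC_gkg",
    "TN_gkg",
    "TP_gkg",
    "AN_mgkg",
    "AP_mgkg",
]
SOIL_NUMERIC = SOIL_COLUMNS[2:]


@dataclass
class Dataset:
    """Tree and soil tables with provenance, comparable for exact equality."""

    trees: pd.DataFrame
    soil: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Dataset):
            return NotImplemented
        return (
            list(self.trees.columns) == list(other.trees.columns)
            and list(self.soil.columns) == list(other.soil.columns)
            and self.trees.equals(other.trees)
            and self.soil.equals(other.soil)
            and self.provenance == other.provenance
        )

    def validate(self) -> None:
        _check_columns(self.trees, TREE_COLUMNS, "trees")
        _check_columns(self.soil, SOIL_COLUMNS, "soil")
        dup = self.trees["tree_id"].duplicated()
        if dup.any():
            row = int(dup.idxmax())
            raise SchemaError(
                f"duplicate tree_id {self.trees['tree_id'].iloc[row]!r} at trees row {row}"
            )


def _check_columns(table: pd.DataFrame, required: list[str], name: str) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise SchemaError(f"missing column {missing[0]!r} in {name} table")


def _coerce_numeric(table: pd.DataFrame, columns: list[str], name: str) -> pd.DataFrame:
    out = table.copy()
    for col in columns:
        values = np.empty(len(out), dtype=float)
        for i, raw in enumerate(out[col].to_numpy()):
            if raw is None or (isinstance(raw, float) and np.isnan(raw)):
                values[i] = np.nan
                continue
            try:
                # Python's float() round-trips repr output exactly
                values[i] = float(raw)
            except (TypeError, ValueError):
                raise SchemaError(
                    f"non-numeric value {raw!r} in column {col!r} "
                    f"of {name} table (row {i})"
                ) from None
        out[col] = values
    return out


def write_dataset(dataset: Dataset, path) -> Path:
    """Write trees.csv, soil.csv and provenance.json into a directory."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    dataset.trees.to_csv(path / "trees.csv", index=False)
    dataset.soil.to_csv(path / "soil.csv", index=False)
    with open(path / "provenance.json", "w") as fh:
        json.dump(dataset.provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def load_dataset(path) -> Dataset:
    """Read a dataset directory, validating the schema strictly.

    Raises :class:`SchemaError` naming the first offending column/row on a
    missing mandatory column, a non-numeric cell in a numeric column, or a
    duplicate tree id. An empty tree table with a valid header is a valid,
    empty dataset.
    """
    path = Path(path)
    trees = pd.read_csv(path / "trees.csv", dtype=str)
    soil = pd.read_csv(path / "soil.csv", dtype=str)
    _check_columns(trees, TREE_COLUMNS, "trees")
    _check_columns(soil, SOIL_COLUMNS, "soil")
    trees = _coerce_numeric(trees, TREE_NUMERIC, "trees")
    soil = _coerce_numeric(soil, SOIL_NUMERIC, "soil")
    provenance = {}
    prov_path = path / "provenance.json"
    if prov_path.exists():
        with open(prov_path) as fh:
            provenance = json.load(fh)
    dataset = Dataset(trees=trees, soil=soil, provenance=provenance)
    dataset.validate()
    return dataset
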