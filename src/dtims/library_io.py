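"""Canonical CCS/m/z library schema, readers/writers, dedup and merging.

A library is a table of curated consensus entries keyed by
(chemical_id, ion_type, mode), plus provenance metadata.  The canonical CSV
form is bit-stable (fixed column order, ``%.6g`` floats, LF endings, UTF-8)
so that diff-based regression checks are meaningful; a JSON mirror carries
the metadata block alongside the entries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from . import chem

__all__ = [
    "LIBRARY_COLUMNS",
    "SchemaError",
    "Library",
    "read_library",
    "write_library",
    "read_inventory",
    "dedup_inventory",
    "count_summary",
]

LIBRARY_COLUMNS = [
    "chemical_id", "name", "formula", "class", "ion_type", "mode",
    "mz_theoretical", "mz_measured_mean", "mass_error_ppm", "ccs_mean_A2",
    "replicate_pct_diff", "n_replicates", "trend_pct_dev",
]

_FLOAT_COLUMNS = [
    "mz_theoretical", "mz_measured_mean", "mass_error_ppm", "ccs_mean_A2",
    "replicate_pct_diff", "trend_pct_dev",
]

KEY = ["chemical_id", "ion_type", "mode"]


class SchemaError(ValueError):
    """Raised for files that do not match the library/inventory schema."""


@dataclass(eq=False)
class Library:
    """Curated consensus library: entries table + provenance metadata."""

    entries: pd.DataFrame
    metadata: dict = dc_field(default_factory=dict)

    # per-entry list of contributing observation indices; populated by
    # from_entries when curation provenance is available (not serialized)
    _obs_index = None

    def __post_init__(self) -> None:
        missing = [c for c in LIBRARY_COLUMNS if c not in self.entries.columns]
        if missing:
            raise SchemaError(f"library entries missing columns: {missing}")
        dup = self.entries.duplicated(subset=KEY)
        if dup.any():
            rows = (self.entries.index[dup] + 1).tolist()
            raise SchemaError(f"duplicate (chemical_id, ion_type, mode) keys at rows {rows}")

    @classmethod
    def from_entries(
        cls,
        entry_df: pd.DataFrame,
        inventory: pd.DataFrame | None = None,
        metadata: dict | None = None,
    ) -> "Library":
        """Assemble a Library from curation output, joining chemical metadata."""
        df = entry_df.copy()
        internal = df.pop("_obs_index") if "_obs_index" in df.columns else None
        if df.empty:
            df = pd.DataFrame(columns=LIBRARY_COLUMNS)
        else:
            if inventory is not None:
                cols = [c for c in ("name", "formula", "class") if c in inventory.columns]
                df = df.merge(
                    inventory[["chemical_id", *cols]], on="chemical_id", how="left"
                )
            for col in LIBRARY_COLUMNS:
                if col not in df.columns:
                    df[col] = np.nan
            df = df[LIBRARY_COLUMNS].reset_index(drop=True)
            df["n_replicates"] = df["n_replicates"].astype(int)
        lib = cls(entries=df, metadata=metadata or {})
        if internal is not None:
            lib._obs_index = internal.reset_index(drop=True)
        return lib

    def __len__(self) -> int:
        return len(self.entries)


def _canonical_frame(entries: pd.DataFrame) -> pd.DataFrame:
    out = entries.copy()
    for col in _FLOAT_COLUMNS:
        out[col] = out[col].map(lambda v: "" if pd.isna(v) else f"{float(v):.6g}")
    out["n_replicates"] = out["n_replicates"].map(
        lambda v: "" if pd.isna(v) else str(int(v))
    )
    return out[LIBRARY_COLUMNS]


def write_library(lib: Library, path) -> None:
    """Write the canonical CSV (or JSON mirror for a .json path)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {
            "metadata": lib.metadata,
            "entries": json.loads(
                lib.entries.to_json(orient="records", double_precision=10)
            ),
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n",
                        encoding="utf-8")
        return
    frame = _canonical_frame(lib.entries)
    csv = frame.to_csv(index=False, lineterminator="\n")
    path.write_text(csv, encoding="utf-8", newline="")


def read_library(path, aliases: dict[str, str] | None = None) -> Library:
    """Read a library CSV/JSON; ``aliases`` maps foreign column names to
    canonical ones (for importing externally published tables)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text(encoding="utf-8"))
        df = pd.DataFrame(payload.get("entries", []), columns=LIBRARY_COLUMNS)
        meta = payload.get("metadata", {})
    else:
        df = pd.read_csv(path, comment="#")
        meta = {}
    if aliases:
        df = df.rename(columns=aliases)
    missing = [c for c in LIBRARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing columns {missing}")
    for i, token in enumerate(df["ion_type"]):
        try:
            df.loc[df.index[i], "ion_type"] = chem.normalize_ion_type(token)
        except chem.FormulaError as exc:
            raise SchemaError(f"{path.name}: row {i + 2}: {exc}") from exc
    dup = df.duplicated(subset=KEY)
    if dup.any():
        row = int(np.flatnonzero(dup)[0]) + 2  # 1-based with header line
        raise SchemaError(f"{path.name}: duplicate (chemical_id, ion_type, mode) at row {row}")
    for col in _FLOAT_COLUMNS:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n_replicates"] = pd.to_numeric(df["n_replicates"], errors="coerce").astype("Int64")
    return Library(entries=df[LIBRARY_COLUMNS].reset_index(drop=True), metadata=meta)


def load_alias_map(path) -> dict[str, str]:
    """Load a user-editable JSON column-alias map (foreign name -> canonical)."""
    return json.loads(Path(path).read_text(encoding="utf-8"))


INVENTORY_COLUMNS = ["chemical_id", "name", "formula", "class"]


def read_inventory(path) -> pd.DataFrame:
    """Read a chemical inventory CSV.

    Requires chemical_id, name, formula, class; optional boolean columns
    stable, amenable_pos, amenable_neg are preserved.
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in INVENTORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"inventory missing columns: {missing}")
    return df


def dedup_inventory(records: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop repeated chemical_ids, first occurrence wins.

    Returns ``(unique, report)`` where the report lists each duplicate row
    index with the index of the occurrence it duplicates.
    """
    first_pos: dict[str, int] = {}
    dup_rows = []
    keep = np.ones(len(records), dtype=bool)
    for pos, cid in enumerate(records["chemical_id"]):
        if cid in first_pos:
            keep[pos] = False
            dup_rows.append(
                {"chemical_id": cid,
                 "first_row": int(records.index[first_pos[cid]]),
                 "duplicate_row": int(records.index[pos])}
            )
        else:
            first_pos[cid] = pos
    report = pd.DataFrame(dup_rows, columns=["chemical_id", "first_row", "duplicate_row"])
    return records.loc[keep].reset_index(drop=True), report


def count_summary(library: Library, inventory: pd.DataFrame | None = None) -> dict:
    """Tally entries, unique chemicals, and per-class / per-mode / per-ion-type counts."""
    e = library.entries
    per_mode = e.groupby("mode")["chemical_id"].nunique().to_dict() if len(e) else {}
    per_ion = e.groupby("ion_type").size().to_dict() if len(e) else {}
    per_class: dict[str, int] = {}
    if len(e):
        if inventory is not None and "class" in inventory.columns:
            classes = dict(zip(inventory["chemical_id"], inventory["class"]))
            cls = e.drop_duplicates("chemical_id")["chemical_id"].map(
                lambda c: classes.get(c, "Unclassified")
            )
        else:
            cls = e.drop_duplicates("chemical_id")["class"].fillna("Unclassified")
        per_class = cls.value_counts().to_dict()
    return {
        "n_entries": int(len(e)),
        "n_unique_chemicals": int(e["chemical_id"].nunique()),
        "per_class": {str(k): int(v) for k, v in per_class.items()},
        "per_mode": {str(k): int(v) for k, v in per_mode.items()},
        "per_ion_type": {str(k): int(v) for k, v in per_ion.items()},
    }
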