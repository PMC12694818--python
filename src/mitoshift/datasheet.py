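"""Import of the study's numerical workbook via an explicit mapping file.

The workbook layout is not standardised, so nothing is guessed: a YAML
mapping file states, for each target schema, which sheet to read, how its
columns map onto the schema, and whether heteroplasmy columns are on the
percent scale.  Example::

    pairs:
      sheet: "Fig2A"
      percent: true
      columns:
        mother_id: "Mother"
        pup_id: "Pup"
        generation: "Generation"
        mother_h: "Mother heteroplasmy (%)"
        pup_h: "Pup heteroplasmy (%)"
    tissues:
      sheet: "Fig1D"
      percent: true
      wide: true            # one row per mouse, one column per tissue
      id_column: "Mouse"
      value_columns: ["Heart", "Liver", "Brain"]

Only the sections present in the mapping are imported.  Percent columns are
divided by 100 exactly once.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import yaml

from .errors import SchemaError
from .io import SCHEMAS

_HET_COLUMNS = {
    "pairs": ("mother_h", "pup_h"),
    "oocytes": ("mother_h", "h"),
    "tissues": ("h",),
}


def load_mapping(path: str | Path) -> dict:
    with open(path) as fh:
        mapping = yaml.safe_load(fh)
    if not isinstance(mapping, dict):
        raise SchemaError(f"{path}: mapping file must be a YAML mapping")
    return mapping


def import_datasheet(workbook: str | Path,
                     mapping: dict | str | Path) -> dict[str, pd.DataFrame]:
    """Read mapped sheets of an XLSX workbook into schema-shaped frames.

    Returns a dict keyed by schema name (``pairs``/``oocytes``/``tissues``)
    holding frames whose heteroplasmy columns are on the fraction scale.
    """
    if not isinstance(mapping, dict):
        mapping = load_mapping(mapping)
    out: dict[str, pd.DataFrame] = {}
    for schema_name, section in mapping.items():
        if schema_name not in SCHEMAS:
            raise SchemaError(f"mapping section {schema_name!r} is not a "
                              f"known schema ({sorted(SCHEMAS)})")
        sheet = section.get("sheet")
        if sheet is None:
            raise SchemaError(f"mapping for {schema_name!r} lacks 'sheet'")
        raw = pd.read_excel(workbook, sheet_name=sheet,
                            skiprows=section.get("skiprows", 0))
        if section.get("wide"):
            df = _from_wide(raw, section, schema_name)
        else:
            df = _from_columns(raw, section, schema_name)
        for col in _HET_COLUMNS.get(schema_name, ()):
            if col in df.columns and section.get("percent", False):
                df[col] = pd.to_numeric(df[col], errors="coerce") / 100.0
        df = df.dropna(how="all")
        # unmapped optional schema columns become missing values so the
        # schema-shaped frame is directly consumable downstream
        for spec in SCHEMAS[schema_name]:
            if spec.name not in df.columns:
                df[spec.name] = pd.NA
        out[schema_name] = df.reset_index(drop=True)
    return out


def _from_columns(raw: pd.DataFrame, section: dict,
                  schema_name: str) -> pd.DataFrame:
    colmap = section.get("columns")
    if not colmap:
        raise SchemaError(f"mapping for {schema_name!r} lacks 'columns'")
    missing = [src for src in colmap.values() if src not in raw.columns]
    if missing:
        raise SchemaError(f"sheet {section['sheet']!r}: source column(s) "
                          f"{missing} not found; have {list(raw.columns)}")
    df = pd.DataFrame({dst: raw[src] for dst, src in colmap.items()})
    for const_dst, value in (section.get("constants") or {}).items():
        df[const_dst] = value
    return df


def _from_wide(raw: pd.DataFrame, section: dict,
               schema_name: str) -> pd.DataFrame:
    """Wide layout (one row per subject, one column per measurement) into the
    long tissues schema."""
    if schema_name != "tissues":
        raise SchemaError("wide layout is only supported for 'tissues'")
    id_col = section.get("id_column")
    value_cols = section.get("value_columns")
    if not id_col or not value_cols:
        raise SchemaError("wide tissues mapping needs id_column and "
                          "value_columns")
    missing = [c for c in [id_col, *value_cols] if c not in raw.columns]
    if missing:
        raise SchemaError(f"sheet {section['sheet']!r}: column(s) {missing} "
                          "not found")
    long = raw.melt(id_vars=[id_col], value_vars=value_cols,
                    var_name="tissue", value_name="h")
    long = long.rename(columns={id_col: "mouse_id"})
    return long[["mouse_id", "tissue", "h"]]
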