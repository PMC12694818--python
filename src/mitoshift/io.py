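"""TSV schemas, validation, and report writing.

Every table crossing the package boundary is tab-separated with a required
header.  Heteroplasmy columns may arrive on the percent (0-100) scale; they
are divided by 100 exactly once when the caller passes ``percent=True`` —
never by heuristic detection.
"""

from __future__ import annotations

import hashlib
import json
import os
import tempfile
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .core import DdpcrWell, SiteCounts
from .errors import SchemaError
from .records import OocyteRecord, TransmissionPair


@dataclass(frozen=True)
class ColumnSpec:
    name: str
    dtype: str  # "str" | "int" | "float"
    required: bool = True
    is_heteroplasmy: bool = False
    minimum: float | None = None
    maximum: float | None = None


SCHEMAS: dict[str, list[ColumnSpec]] = {
    "pairs": [
        ColumnSpec("mother_id", "str"),
        ColumnSpec("pup_id", "str"),
        ColumnSpec("generation", "str"),
        ColumnSpec("mother_h", "float", is_heteroplasmy=True),
        ColumnSpec("pup_h", "float", is_heteroplasmy=True),
        ColumnSpec("maternal_age_months", "float", required=False, minimum=0),
        ColumnSpec("litter_id", "str", required=False),
        ColumnSpec("litter_size", "int", required=False, minimum=1),
    ],
    "oocytes": [
        ColumnSpec("mouse_id", "str"),
        ColumnSpec("mother_h", "float", is_heteroplasmy=True),
        ColumnSpec("stage_or_day", "str"),
        ColumnSpec("group", "str"),
        ColumnSpec("h", "float", is_heteroplasmy=True),
        ColumnSpec("wt_copies", "float", required=False, minimum=0),
        ColumnSpec("mut_copies", "float", required=False, minimum=0),
    ],
    "tissues": [
        ColumnSpec("mouse_id", "str"),
        ColumnSpec("tissue", "str"),
        ColumnSpec("h", "float", is_heteroplasmy=True),
    ],
    "ddpcr": [
        ColumnSpec("sample_id", "str"),
        ColumnSpec("droplets_total", "int", minimum=1),
        ColumnSpec("fam_positive", "int", minimum=0),
        ColumnSpec("hex_positive", "int", minimum=0),
    ],
    "sites": [
        ColumnSpec("pos", "int", minimum=1),
        ColumnSpec("ref", "str"),
        ColumnSpec("a_count", "int", minimum=0),
        ColumnSpec("c_count", "int", minimum=0),
        ColumnSpec("g_count", "int", minimum=0),
        ColumnSpec("t_count", "int", minimum=0),
    ],
}


def validate_table(path: str | Path, schema_name: str,
                   percent: bool = False) -> pd.DataFrame:
    """Read and validate a TSV against a named schema.

    Collects every violation (missing columns, unparseable numerics, range
    errors) into one :class:`SchemaError` naming file, row and column.  Rows
    are reported 1-based counting the header as row 1.  A header-only file
    yields an empty, correctly-typed frame.
    """
    if schema_name not in SCHEMAS:
        raise ValueError(f"unknown schema {schema_name!r}; "
                         f"expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    spec = SCHEMAS[schema_name]
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, comment="#",
                         keep_default_na=False)
    except Exception as exc:  # noqa: BLE001 - aggregated into SchemaError
        raise SchemaError(f"{path}: cannot parse TSV: {exc}") from exc

    errors: list[str] = []
    missing = [c.name for c in spec if c.required and c.name not in df.columns]
    if missing:
        errors.append(f"{path}: missing required column(s) {missing}")
        raise SchemaError(f"{path}: schema validation failed", errors)
    extra = [c for c in df.columns if c not in {s.name for s in spec}]
    if extra:
        errors.append(f"{path}: unexpected column(s) {extra}")

    out = pd.DataFrame(index=df.index)
    for col in spec:
        if col.name not in df.columns:
            out[col.name] = pd.Series([None] * len(df), dtype=object)
            continue
        raw = df[col.name]
        if col.dtype == "str":
            out[col.name] = raw.replace("", None)
            continue
        vals = pd.to_numeric(raw.mask(raw.eq("")), errors="coerce")
        bad = raw.ne("") & vals.isna()
        for idx in df.index[bad]:
            errors.append(f"{path}: row {idx + 2}, column {col.name!r}: "
                          f"unparseable value {raw[idx]!r}")
        if col.is_heteroplasmy and percent:
            vals = vals / 100.0
        lo = 0.0 if col.is_heteroplasmy else col.minimum
        hi = 1.0 if col.is_heteroplasmy else col.maximum
        if lo is not None:
            for idx in df.index[(vals < lo).fillna(False)]:
                errors.append(f"{path}: row {idx + 2}, column {col.name!r}: "
                              f"value {vals[idx]} below minimum {lo}")
        if hi is not None:
            for idx in df.index[(vals > hi).fillna(False)]:
                errors.append(f"{path}: row {idx + 2}, column {col.name!r}: "
                              f"value {vals[idx]} above maximum {hi}")
        if col.dtype == "int":
            nonint = vals.notna() & (vals != vals.round())
            for idx in df.index[nonint]:
                errors.append(f"{path}: row {idx + 2}, column {col.name!r}: "
                              f"expected integer, got {vals[idx]}")
        out[col.name] = vals

    if errors:
        raise SchemaError(f"{path}: schema validation failed "
                          f"({len(errors)} error(s))", errors)
    return out


# ---------------------------------------------------------------------------
# Frame <-> record conversion
# ---------------------------------------------------------------------------

def pairs_from_frame(df: pd.DataFrame) -> list[TransmissionPair]:
    out = []
    for row in df.itertuples(index=False):
        ls = getattr(row, "litter_size", None)
        age = getattr(row, "maternal_age_months", None)
        lid = getattr(row, "litter_id", None)
        out.append(TransmissionPair(
            mother_id=str(row.mother_id), pup_id=str(row.pup_id),
            generation=str(row.generation),
            mother_h=float(row.mother_h), pup_h=float(row.pup_h),
            maternal_age_months=None if age is None or pd.isna(age)
            else float(age),
            litter_id=None if lid is None or pd.isna(lid) else str(lid),
            litter_size=None if ls is None or pd.isna(ls) else int(ls),
        ))
    return out


def oocytes_from_frame(df: pd.DataFrame) -> list[OocyteRecord]:
    out = []
    for row in df.itertuples(index=False):
        sod = str(row.stage_or_day)
        stage, day = (None, int(sod)) if sod.isdigit() else (sod, None)
        wt = getattr(row, "wt_copies", None)
        mut = getattr(row, "mut_copies", None)
        out.append(OocyteRecord(
            mouse_id=str(row.mouse_id), mother_h=float(row.mother_h),
            h=float(row.h), stage=stage, day=day,
            wt_copies=None if wt is None or pd.isna(wt) else float(wt),
            mut_copies=None if mut is None or pd.isna(mut) else float(mut),
            group=str(row.group)))
    return out


def wells_from_frame(df: pd.DataFrame) -> list[DdpcrWell]:
    return [DdpcrWell(sample_id=str(r.sample_id),
                      droplets_total=int(r.droplets_total),
                      fam_positive=int(r.fam_positive),
                      hex_positive=int(r.hex_positive))
            for r in df.itertuples(index=False)]


def sites_from_frame(df: pd.DataFrame) -> list[SiteCounts]:
    return [SiteCounts(position=int(r.pos), ref_base=str(r.ref),
                       count_a=int(r.a_count), count_c=int(r.c_count),
                       count_g=int(r.g_count), count_t=int(r.t_count))
            for r in df.itertuples(index=False)]


def pairs_to_frame(pairs: Iterable[TransmissionPair]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mother_id": p.mother_id, "pup_id": p.pup_id,
        "generation": p.generation, "mother_h": p.mother_h, "pup_h": p.pup_h,
        "maternal_age_months": p.maternal_age_months,
        "litter_id": p.litter_id, "litter_size": p.litter_size,
    } for p in pairs])


def oocytes_to_frame(records: Iterable[OocyteRecord]) -> pd.DataFrame:
    return pd.DataFrame([{
        "mouse_id": r.mouse_id, "mother_h": r.mother_h,
        "stage_or_day": r.stage if r.stage is not None else r.day,
        "group": r.group, "h": r.h,
        "wt_copies": r.wt_copies, "mut_copies": r.mut_copies,
    } for r in records])


# ---------------------------------------------------------------------------
# Atomic writing and fingerprints
# ---------------------------------------------------------------------------

def atomic_write_text(path: str | Path, text: str) -> None:
    """Write via a temp file in the target directory, then rename."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_tsv(df: pd.DataFrame, path: str | Path,
              header_comments: Iterable[str] = ()) -> None:
    lines = [f"# {c}" for c in header_comments]
    body = df.to_csv(sep="\t", index=False)
    atomic_write_text(path, "\n".join(lines) + ("\n" if lines else "") + body)


def write_json_report(payload: dict, path: str | Path) -> None:
    atomic_write_text(path, json.dumps(payload, indent=2, sort_keys=True,
                                       default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def input_fingerprint(path: str | Path) -> dict:
    """Row count plus content checksum for report provenance."""
    path = Path(path)
    data = path.read_bytes()
    n_rows = max(0, sum(1 for line in data.splitlines()
                        if line and not line.startswith(b"#")) - 1)
    return {"path": str(path), "rows": n_rows,
            "sha256": hashlib.sha256(data).hexdigest()}
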