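"""Reading and writing study datasets.

All files are comma-separated UTF-8 with a mandatory header, '.' decimal
separator and BLQ encoded as 0/1 — the long-format convention of population
PK datasets (one row per observation).  Canonical column orders:

* pk:        ID,BATCH,ARM,ANALYTE,TIME,DV,WT,BLQ   (DV in ng, WT in mg)
* linearity: CONC,AMOUNT,WT
* effects:   ARM,REPLICATE,N0,ALIVE24,ALIVE48,ALIVE72,ALIVE96,EGGS,EGGS_ASSAYED,HATCHED

Unknown columns are carried through untouched on read and appended after the
canonical columns on write.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .datamodel import (EffectsRecord, LinearityRecord, MosquitoRecord,
                        SchemaError, ValidationError, validate_records)

PK_COLUMNS = ["ID", "BATCH", "ARM", "ANALYTE", "TIME", "DV", "WT", "BLQ"]
LINEARITY_COLUMNS = ["CONC", "AMOUNT", "WT"]
EFFECTS_COLUMNS = ["ARM", "REPLICATE", "N0", "ALIVE24", "ALIVE48", "ALIVE72",
                   "ALIVE96", "EGGS", "EGGS_ASSAYED", "HATCHED"]

_MANDATORY = {
    "pk": [c for c in PK_COLUMNS if c != "ANALYTE"],
    "linearity": LINEARITY_COLUMNS,
    "effects": EFFECTS_COLUMNS,
}

Records = Union[Sequence[MosquitoRecord], Sequence[LinearityRecord],
                Sequence[EffectsRecord]]


def _check_header(df: pd.DataFrame, schema: str) -> None:
    missing = [c for c in _MANDATORY[schema] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"dataset is missing mandatory column(s) {', '.join(missing)} "
            f"for schema {schema!r}")


def read_dataset(path, schema: str = "pk") -> list:
    """Read a study CSV into typed, validated records (row order preserved)."""
    if schema not in _MANDATORY:
        raise ValueError(f"unknown schema {schema!r}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    # round_trip parsing: writing and re-reading a dataset must reproduce
    # every float bit-for-bit (the fast parser can be off by one ulp)
    df = pd.read_csv(path, float_precision="round_trip")
    _check_header(df, schema)
    if schema == "pk":
        return _pk_from_frame(df)
    if schema == "linearity":
        records = [LinearityRecord(blood_conc_ug_ml=float(r.CONC),
                                   amount_ng=float(r.AMOUNT),
                                   weight_mg=float(r.WT))
                   for r in df.itertuples()]
        for i, rec in enumerate(records):
            rec.validate(index=i)
        return records
    records = [EffectsRecord(arm=str(r.ARM), replicate=str(r.REPLICATE),
                             n_initial=int(r.N0), alive_24h=int(r.ALIVE24),
                             alive_48h=int(r.ALIVE48), alive_72h=int(r.ALIVE72),
                             alive_96h=int(r.ALIVE96), eggs=float(r.EGGS),
                             eggs_assayed=int(r.EGGS_ASSAYED),
                             hatched=int(r.HATCHED))
               for r in df.itertuples()]
    for i, rec in enumerate(records):
        rec.validate(index=i)
    return records


def _pk_from_frame(df: pd.DataFrame) -> list[MosquitoRecord]:
    extras = [c for c in df.columns if c not in PK_COLUMNS]
    records = []
    for i, row in enumerate(df.to_dict("records")):
        blq = bool(int(row["BLQ"]))
        dv = row.get("DV")
        amount = None
        if not blq and dv is not None and not (isinstance(dv, float) and math.isnan(dv)):
            amount = float(dv)
        rec = MosquitoRecord(
            mosquito_id=str(row["ID"]), batch_id=str(row["BATCH"]),
            arm=str(row["ARM"]),
            analyte=str(row.get("ANALYTE", "IVM") or "IVM"),
            time_h=float(row["TIME"]), weight_mg=float(row["WT"]),
            amount_ng=amount, blq=blq,
            extra={c: row[c] for c in extras})
        records.append(rec)
    validate_records(records)
    return records


def records_to_frame(records: Records) -> pd.DataFrame:
    """Convert typed records into the canonical long-format table."""
    if len(records) == 0:
        raise ValueError("cannot infer schema from an empty record list; "
                         "use write_dataset(..., schema=...)")
    first = records[0]
    if isinstance(first, MosquitoRecord):
        rows = []
        extras: list[str] = []
        for rec in records:
            for c in rec.extra:
                if c not in extras:
                    extras.append(c)
            rows.append({"ID": rec.mosquito_id, "BATCH": rec.batch_id,
                         "ARM": rec.arm, "ANALYTE": rec.analyte,
                         "TIME": rec.time_h,
                         "DV": (float("nan") if rec.blq else rec.amount_ng),
                         "WT": rec.weight_mg, "BLQ": int(rec.blq),
                         **rec.extra})
        return pd.DataFrame(rows, columns=PK_COLUMNS + extras)
    if isinstance(first, LinearityRecord):
        return pd.DataFrame(
            [{"CONC": r.blood_conc_ug_ml, "AMOUNT": r.amount_ng, "WT": r.weight_mg}
             for r in records], columns=LINEARITY_COLUMNS)
    if isinstance(first, EffectsRecord):
        return pd.DataFrame(
            [{"ARM": r.arm, "REPLICATE": r.replicate, "N0": r.n_initial,
              "ALIVE24": r.alive_24h, "ALIVE48": r.alive_48h,
              "ALIVE72": r.alive_72h, "ALIVE96": r.alive_96h, "EGGS": r.eggs,
              "EGGS_ASSAYED": r.eggs_assayed, "HATCHED": r.hatched}
             for r in records], columns=EFFECTS_COLUMNS)
    raise TypeError(f"unsupported record type {type(first).__name__}")


def frame_to_records(df: pd.DataFrame) -> list[MosquitoRecord]:
    """Typed view of a canonical PK frame (validates on the way)."""
    _check_header(df, "pk")
    return _pk_from_frame(df.reset_index(drop=True))


def write_dataset(records: Records, path, schema: str | None = None) -> Path:
    """Write records as a canonical CSV; empty collections give a header-only
    file (``schema`` is then required)."""
    path = Path(path)
    if len(records) == 0:
        if schema is None:
            raise ValueError("schema required to write an empty dataset")
        header = {"pk": PK_COLUMNS, "linearity": LINEARITY_COLUMNS,
                  "effects": EFFECTS_COLUMNS}[schema]
        df = pd.DataFrame(columns=header)
    else:
        if isinstance(records, pd.DataFrame):
            records = frame_to_records(records)
        if isinstance(records[0], MosquitoRecord):
            validate_records(records)
        df = records_to_frame(records)
    df.to_csv(path, index=False, na_rep="")
    return path
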