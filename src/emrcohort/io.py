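"""Readers and writers for the CSV interchange formats.

An extract directory holds ``patients.csv`` (``patient_key,age,sex``)
and ``journal.csv``
(``patient_key,record_kind,code,date,quantity,daily_dose,days_supply,value,discharge_date``)
with empty fields for non-applicable attributes.  Files are UTF-8 with a
mandatory header row; dates are ISO-8601; both LF and CRLF endings are
accepted.  Reading validates invariants and reports offending rows by
line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .codelist import CodeList
from .core import JOURNAL_COLUMNS, PATIENT_COLUMNS, SourceExtract

__all__ = ["read_extract", "write_extract", "ParseError"]

PATIENT_FILE = "patients.csv"
JOURNAL_FILE = "journal.csv"


class ParseError(ValueError):
    """Malformed extract file; the message names file, row and field."""


def write_extract(extract: SourceExtract, directory: str | Path) -> dict[str, Path]:
    """Write patient and journal CSVs; deterministic row order."""
    directory = Path(directory)
    try:
        directory.mkdir(parents=True, exist_ok=True)
        pat = extract.patients[PATIENT_COLUMNS].sort_values("patient_key")
        ppath = directory / PATIENT_FILE
        pat.to_csv(ppath, index=False)

        j = extract.journal[JOURNAL_COLUMNS].copy()
        j["date"] = j["date"].dt.strftime("%Y-%m-%d")
        j["discharge_date"] = j["discharge_date"].dt.strftime("%Y-%m-%d")
        for c in ("quantity", "daily_dose", "days_supply"):
            j[c] = j[c].map(lambda v: "" if pd.isna(v) else f"{v:g}")
        j["value"] = j["value"].map(lambda v: "" if v is None or (isinstance(v, float)
                                                                  and np.isnan(v)) else v)
        j = j.sort_values(JOURNAL_COLUMNS, kind="stable")
        jpath = directory / JOURNAL_FILE
        j.to_csv(jpath, index=False)
    except OSError as exc:
        raise OSError(f"cannot write extract to {directory}: {exc}") from exc
    return {"patients": ppath, "journal": jpath}


def _require_columns(df: pd.DataFrame, wanted: list[str], path: Path) -> None:
    missing = [c for c in wanted if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")


def _parse_dates(raw: pd.Series, path: Path, column: str,
                 required: bool) -> pd.Series:
    stripped = raw.fillna("").astype(str).str.strip()
    out = pd.to_datetime(stripped.where(stripped != "", None),
                         format="%Y-%m-%d", errors="coerce")
    bad = out.isna() & (stripped != "")
    if required:
        bad |= stripped == ""
    if bad.any():
        row = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(f"{path} row {row}: bad {column} value {raw[bad.idxmax()]!r} "
                         "(expected YYYY-MM-DD)")
    return out


def read_extract(directory: str | Path, source_name: str | None = None,
                 codelist: CodeList | None = None) -> SourceExtract:
    """Read an extract directory; validates codes when a code list is given."""
    directory = Path(directory)
    ppath = directory / PATIENT_FILE
    jpath = directory / JOURNAL_FILE
    for p in (ppath, jpath):
        if not p.exists():
            raise ParseError(f"missing extract file: {p}")

    pats = pd.read_csv(ppath, dtype=str).fillna("")
    _require_columns(pats, PATIENT_COLUMNS, ppath)
    bad_sex = ~pats["sex"].isin(["M", "F"])
    if bad_sex.any():
        row = int(bad_sex.idxmax()) + 2
        raise ParseError(f"{ppath} row {row}: sex must be M or F, "
                         f"got {pats['sex'][bad_sex.idxmax()]!r}")
    try:
        pats["age"] = pats["age"].astype(int)
    except ValueError as exc:
        raise ParseError(f"{ppath}: non-integer age: {exc}") from exc

    j = pd.read_csv(jpath, dtype=str)
    _require_columns(j, JOURNAL_COLUMNS, jpath)
    bad_kind = ~j["record_kind"].isin(["prescription", "event"])
    if bad_kind.any():
        row = int(bad_kind.idxmax()) + 2
        raise ParseError(f"{jpath} row {row}: record_kind must be prescription|event, "
                         f"got {j['record_kind'][bad_kind.idxmax()]!r}")
    if codelist is not None:
        unknown = ~j["code"].isin(set(codelist.table["code"]))
        if unknown.any():
            row = int(unknown.idxmax()) + 2
            raise ParseError(f"{jpath} row {row}: unknown code "
                             f"{j['code'][unknown.idxmax()]!r}")
        rx_codes = codelist.prescription_codes()
        mismatch = (j["record_kind"] == "prescription") != j["code"].isin(rx_codes)
        if mismatch.any():
            row = int(mismatch.idxmax()) + 2
            raise ParseError(f"{jpath} row {row}: code {j['code'][mismatch.idxmax()]!r} "
                             "does not belong to the stated record_kind")
    j["date"] = _parse_dates(j["date"], jpath, "date", required=True)
    j["discharge_date"] = _parse_dates(j["discharge_date"], jpath, "discharge_date",
                                       required=False)
    for c in ("quantity", "daily_dose", "days_supply"):
        j[c] = pd.to_numeric(j[c], errors="coerce")
    supply = j["days_supply"]
    if ((supply.notna()) & (supply < 1)).any():
        row = int(((supply.notna()) & (supply < 1)).idxmax()) + 2
        raise ParseError(f"{jpath} row {row}: days_supply must be >= 1 when present")
    disch = j["discharge_date"]
    if (disch.notna() & (disch < j["date"])).any():
        row = int((disch.notna() & (disch < j["date"])).idxmax()) + 2
        raise ParseError(f"{jpath} row {row}: discharge_date precedes date")
    j["value"] = j["value"].where(j["value"].notna(), None)

    name = source_name or directory.name
    return SourceExtract(source_name=name, patients=pats, journal=j)
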