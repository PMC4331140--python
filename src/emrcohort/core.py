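"""Shared containers for extracts and journal records.

A data source delivers two tables per practice: a *patient file*
(pseudonymised key, age, sex) and a *journal file* — the longitudinal
coded record stream, split by kind into prescription rows (quantity,
daily dose, days' supply) and event rows (diagnoses, measurements with a
value, admissions with a discharge date).

Dates are held as pandas datetimes in memory and as ISO-8601 strings on
disk.  All date intervals in this package are half-open ``[start, end)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "JOURNAL_COLUMNS",
    "PATIENT_COLUMNS",
    "SourceExtract",
    "empty_journal",
    "empty_patients",
]

#: on-disk journal schema (record_id is assigned in memory, never written)
JOURNAL_COLUMNS = [
    "patient_key",
    "record_kind",
    "code",
    "date",
    "quantity",
    "daily_dose",
    "days_supply",
    "value",
    "discharge_date",
]

PATIENT_COLUMNS = ["patient_key", "age", "sex"]


def empty_journal() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in JOURNAL_COLUMNS})
    df["date"] = pd.Series(dtype="datetime64[ns]")
    df["discharge_date"] = pd.Series(dtype="datetime64[ns]")
    for c in ("quantity", "daily_dose", "days_supply"):
        df[c] = pd.Series(dtype=float)
    df.insert(0, "record_id", pd.Series(dtype=int))
    return df


def empty_patients() -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in PATIENT_COLUMNS})
    df["age"] = pd.Series(dtype=int)
    return df


def _normalise_journal(journal: pd.DataFrame) -> pd.DataFrame:
    df = journal.copy()
    if "record_id" not in df.columns:
        df.insert(0, "record_id", np.arange(len(df), dtype=int))
    df["date"] = pd.to_datetime(df["date"])
    df["discharge_date"] = pd.to_datetime(df["discharge_date"])
    for c in ("quantity", "daily_dose", "days_supply"):
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df.reset_index(drop=True)


@dataclass
class SourceExtract:
    """One data source's patient file plus journal file.

    ``key_map`` (pseudonym -> ground-truth person id) is carried only on
    extracts derived from the synthetic generator, as an oracle for
    linkage tests; real extracts have no such map.
    """

    source_name: str
    patients: pd.DataFrame
    journal: pd.DataFrame
    key_map: dict[str, int] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.patients = self.patients.reset_index(drop=True)
        self.journal = _normalise_journal(self.journal)
        self.validate()

    def validate(self) -> None:
        missing = [c for c in PATIENT_COLUMNS if c not in self.patients.columns]
        if missing:
            raise ValueError(f"{self.source_name}: patient file missing columns {missing}")
        missing = [c for c in JOURNAL_COLUMNS if c not in self.journal.columns]
        if missing:
            raise ValueError(f"{self.source_name}: journal missing columns {missing}")
        keys = self.patients["patient_key"]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValueError(
                f"{self.source_name}: duplicate patient_key in patient file: {dup!r}"
            )
        if len(self.journal):
            orphan = ~self.journal["patient_key"].isin(set(keys))
            if orphan.any():
                bad = self.journal.loc[orphan, "patient_key"].iloc[0]
                raise ValueError(
                    f"{self.source_name}: journal patient_key {bad!r} absent from patient file"
                )

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def prescriptions(self) -> pd.DataFrame:
        return self.journal[self.journal["record_kind"] == "prescription"]

    def events(self) -> pd.DataFrame:
        return self.journal[self.journal["record_kind"] == "event"]

    def equals(self, other: "SourceExtract") -> bool:
        """Content equality on the on-disk schema (record ids are ignored)."""
        pa = self.patients[PATIENT_COLUMNS].sort_values(PATIENT_COLUMNS).reset_index(drop=True)
        pb = other.patients[PATIENT_COLUMNS].sort_values(PATIENT_COLUMNS).reset_index(drop=True)
        if not pa.astype(str).equals(pb.astype(str)):
            return False
        ja = self.journal[JOURNAL_COLUMNS].sort_values(JOURNAL_COLUMNS).reset_index(drop=True)
        jb = other.journal[JOURNAL_COLUMNS].sort_values(JOURNAL_COLUMNS).reset_index(drop=True)
        return ja.astype(str).equals(jb.astype(str))
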