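"""Simplified clinical code list.

UK primary-care records are coded with Read codes; this package ships a
small synthetic dictionary of ~65 codes grouped into the concepts the
pipeline needs (diagnoses, medication classes, contacts, admissions,
measurements, registration events).  Each code carries the record kind it
may appear under (``prescription`` or ``event``) and, for prescriptions,
a medication class (SABA, LABA, LAMA, ICS, ICS_LABA, LTRA, OCS, ABX).
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["CodeList", "load_codelist"]

_REQUIRED_COLUMNS = ["code", "concept", "record_kind", "class"]


class CodeList:
    """In-memory code dictionary with concept- and class-level lookups."""

    def __init__(self, table: pd.DataFrame):
        missing = [c for c in _REQUIRED_COLUMNS if c not in table.columns]
        if missing:
            raise ValueError(f"code list missing columns: {missing}")
        if table["code"].duplicated().any():
            dupes = table.loc[table["code"].duplicated(), "code"].tolist()
            raise ValueError(f"duplicate codes in code list: {dupes}")
        tab = table.copy()
        tab["class"] = tab["class"].fillna("")
        self.table = tab
        self._concept_of = dict(zip(tab["code"], tab["concept"]))
        self._kind_of = dict(zip(tab["code"], tab["record_kind"]))
        self._class_of = dict(zip(tab["code"], tab["class"]))

    # -- lookups -----------------------------------------------------------
    def codes_for_concept(self, concept: str) -> list[str]:
        if concept not in set(self.table["concept"]):
            raise KeyError(f"unknown concept: {concept!r}")
        return self.table.loc[self.table["concept"] == concept, "code"].tolist()

    def codes_for_concepts(self, concepts) -> list[str]:
        out: list[str] = []
        for c in concepts:
            out.extend(self.codes_for_concept(c))
        return out

    def codes_for_class(self, med_class: str) -> list[str]:
        if med_class not in set(self.table["class"]) or not med_class:
            raise KeyError(f"unknown medication class: {med_class!r}")
        return self.table.loc[self.table["class"] == med_class, "code"].tolist()

    def concept(self, code: str) -> str:
        return self._concept_of[code]

    def kind(self, code: str) -> str:
        return self._kind_of[code]

    def med_class(self, code: str) -> str:
        return self._class_of[code]

    def known(self, code: str) -> bool:
        return code in self._concept_of

    @property
    def concepts(self) -> set[str]:
        return set(self.table["concept"])

    def prescription_codes(self) -> set[str]:
        return set(self.table.loc[self.table["record_kind"] == "prescription", "code"])


def load_codelist(path: str | Path | None = None) -> CodeList:
    """Load the packaged code list, or a user-supplied CSV with the same schema."""
    if path is None:
        with resources.files("emrcohort.data").joinpath("codelist.csv").open("rb") as fh:
            table = pd.read_csv(fh, dtype=str)
    else:
        table = pd.read_csv(path, dtype=str)
    return CodeList(table)
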