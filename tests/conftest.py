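import numpy as np
import pandas as pd
import pytest

from emrcohort.codelist import load_codelist
from emrcohort.core import SourceExtract, empty_journal


@pytest.fixture(scope="session")
def codelist():
    return load_codelist()


def make_journal(rows):
    """Build a journal frame from compact tuples:
    (patient_key, record_kind, code, date, extras-dict)."""
    if not rows:
        return empty_journal()
    recs = []
    for r in rows:
        key, kind, code, d = r[:4]
        extra = r[4] if len(r) > 4 else {}
        recs.append({
            "patient_key": key, "record_kind": kind, "code": code,
            "date": pd.Timestamp(d),
            "quantity": extra.get("quantity", np.nan),
            "daily_dose": extra.get("daily_dose", np.nan),
            "days_supply": extra.get("days_supply", np.nan),
            "value": extra.get("value"),
            "discharge_date": pd.Timestamp(extra["discharge_date"])
            if "discharge_date" in extra else pd.NaT,
        })
    df = pd.DataFrame(recs)
    df.insert(0, "record_id", np.arange(len(df)))
    return df


def make_extract(name, patients, rows):
    """patients: list of (key, age, sex); rows: journal tuples."""
    pat = pd.DataFrame(patients, columns=["patient_key", "age", "sex"])
    return SourceExtract(source_name=name, patients=pat, journal=make_journal(rows))


@pytest.fixture
def tiny_extract():
    patients = [("p1", 45, "F"), ("p2", 30, "M"), ("p3", 70, "M")]
    rows = [
        ("p1", "event", "AST01", "2008-03-01"),
        ("p1", "prescription", "RXS01", "2008-04-01", {"quantity": 1, "days_supply": 28}),
        ("p1", "prescription", "RXS01", "2008-06-01", {"quantity": 1, "days_supply": 28}),
        ("p2", "event", "CPD01", "2007-05-20"),
        ("p2", "event", "GPV01", "2009-02-11"),
        ("p3", "event", "ADR01", "2009-03-05", {"discharge_date": "2009-03-08"}),
        ("p3", "prescription", "RXO01", "2009-03-05", {"quantity": 1, "days_supply": 5}),
    ]
    return make_extract("tiny", patients, rows)
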