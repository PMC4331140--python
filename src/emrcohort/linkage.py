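"""Dual-source verification: patient matching, record merge, agreement.

Two extraction routes from the same practice records should agree almost
perfectly; this module quantifies how nearly they do.  Patients are
matched in two stages — exact pseudonym key (emulating NHS-number
linkage) and, for the residue, exact agreement on an (age, sex,
record-date fingerprint) triple.  Matched patients' prescription records
are merged and deduplicated, diagnosis records are enumerated for
one-source-only residues, and patient-level presence of a condition is
compared with Cohen's kappa.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .codelist import CodeList, load_codelist
from .core import SourceExtract

__all__ = [
    "MatchResult",
    "TwoByTwo",
    "ConcordanceReport",
    "match_patients",
    "merge_prescriptions",
    "compare_condition",
    "cohen_kappa",
    "verification_report",
]

_MERGE_KEY = ["code", "date", "quantity"]


@dataclass
class MatchResult:
    matched_pairs: list[tuple[str, str]]
    unique_a: list[str]
    unique_b: list[str]
    match_method: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def n_matched(self) -> int:
        return len(self.matched_pairs)

    def b_to_a(self) -> dict[str, str]:
        return {b: a for a, b in self.matched_pairs}


@dataclass
class TwoByTwo:
    """Patient-level agreement table: positive/negative in each source."""

    both_pos: int
    a_only: int
    b_only: int
    both_neg: int

    def __post_init__(self) -> None:
        for name in ("both_pos", "a_only", "b_only", "both_neg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    @property
    def total(self) -> int:
        return self.both_pos + self.a_only + self.b_only + self.both_neg


def _fingerprint(journal: pd.DataFrame, keys: pd.Series) -> dict[str, tuple]:
    """(up to) three earliest distinct record dates per patient."""
    fp: dict[str, tuple] = {k: () for k in keys}
    if len(journal):
        dates = journal[["patient_key", "date"]].dropna().drop_duplicates()
        dates = dates.sort_values(["patient_key", "date"])
        top3 = dates.groupby("patient_key", sort=False).head(3)
        for k, grp in top3.groupby("patient_key", sort=False):
            fp[k] = tuple(grp["date"].tolist())
    return fp


def match_patients(a: SourceExtract, b: SourceExtract) -> MatchResult:
    """Two-stage deterministic match.

    Stage 1 pairs identical pseudonym keys present in both patient files
    (sources that share a keyspace).  Stage 2 pairs the remainder on
    exact (age, sex, fingerprint-of-3-earliest-record-dates) agreement;
    a fingerprint that is ambiguous on either side (two or more equally
    good candidates) is left unmatched rather than guessed.
    """
    a.validate()
    b.validate()
    keys_a = list(a.patients["patient_key"])
    keys_b = list(b.patients["patient_key"])
    shared = set(keys_a) & set(keys_b)

    pairs: list[tuple[str, str]] = [(k, k) for k in keys_a if k in shared]
    method = {(k, k): "exact_key" for k in shared}

    rest_a = [k for k in keys_a if k not in shared]
    rest_b = [k for k in keys_b if k not in shared]
    if rest_a and rest_b:
        demo_a = dict(zip(a.patients["patient_key"],
                          zip(a.patients["age"], a.patients["sex"])))
        demo_b = dict(zip(b.patients["patient_key"],
                          zip(b.patients["age"], b.patients["sex"])))
        fp_a = _fingerprint(a.journal, a.patients["patient_key"])
        fp_b = _fingerprint(b.journal, b.patients["patient_key"])

        def sig(demo, fp, k):
            return (*demo[k], fp[k])

        by_sig_a: dict[tuple, list[str]] = {}
        for k in rest_a:
            by_sig_a.setdefault(sig(demo_a, fp_a, k), []).append(k)
        by_sig_b: dict[tuple, list[str]] = {}
        for k in rest_b:
            by_sig_b.setdefault(sig(demo_b, fp_b, k), []).append(k)

        for s, ka in by_sig_a.items():
            kb = by_sig_b.get(s, [])
            if len(ka) == 1 and len(kb) == 1:
                pairs.append((ka[0], kb[0]))
                method[(ka[0], kb[0])] = "demographic"

    in_pairs_a = {p[0] for p in pairs}
    in_pairs_b = {p[1] for p in pairs}
    return MatchResult(
        matched_pairs=pairs,
        unique_a=[k for k in keys_a if k not in in_pairs_a],
        unique_b=[k for k in keys_b if k not in in_pairs_b],
        match_method=method,
    )


def merge_prescriptions(a: SourceExtract, b: SourceExtract,
                        m: MatchResult) -> tuple[pd.DataFrame, dict[str, int]]:
    """Merge matched patients' prescription records and deduplicate.

    Records equal on (matched patient, code, date, quantity) collapse to
    one; the remainder is unique to one source.  Returns the merged
    record set plus counts ``{total_merged, unique_a, unique_b}``.
    """
    a_keys = {p[0] for p in m.matched_pairs}
    remap = m.b_to_a()

    ra = a.prescriptions()
    ra = ra[ra["patient_key"].isin(a_keys)].copy()
    rb = b.prescriptions()
    rb = rb[rb["patient_key"].isin(remap.keys())].copy()
    rb["patient_key"] = rb["patient_key"].map(remap)

    key = ["patient_key"] + _MERGE_KEY
    da = ra.drop_duplicates(subset=key)[key]
    db = rb.drop_duplicates(subset=key)[key]
    merged = da.merge(db, on=key, how="outer", indicator=True)
    counts = {
        "total_merged": len(merged),
        "unique_a": int((merged["_merge"] == "left_only").sum()),
        "unique_b": int((merged["_merge"] == "right_only").sum()),
    }
    return merged.drop(columns="_merge"), counts


def _patients_with_concept(extract: SourceExtract, codes: set[str],
                           keys: set[str]) -> set[str]:
    ev = extract.journal
    hit = ev[ev["code"].isin(codes) & ev["patient_key"].isin(keys)]
    return set(hit["patient_key"])


def compare_condition(a: SourceExtract, b: SourceExtract, m: MatchResult,
                      concept: str, codelist: CodeList | None = None) -> TwoByTwo:
    """Classify each matched patient by presence of any code of ``concept``
    in each source; tabulate agreement."""
    codelist = codelist or load_codelist()
    codes = set(codelist.codes_for_concept(concept))
    a_keys = {p[0] for p in m.matched_pairs}
    b_keys = {p[1] for p in m.matched_pairs}
    pos_a = _patients_with_concept(a, codes, a_keys)
    pos_b_raw = _patients_with_concept(b, codes, b_keys)
    remap = m.b_to_a()
    pos_b = {remap[k] for k in pos_b_raw}

    both = len(pos_a & pos_b)
    a_only = len(pos_a - pos_b)
    b_only = len(pos_b - pos_a)
    return TwoByTwo(both_pos=both, a_only=a_only, b_only=b_only,
                    both_neg=m.n_matched - both - a_only - b_only)


def cohen_kappa(t: TwoByTwo) -> float:
    """Chance-corrected agreement: kappa = (p_o - p_e) / (1 - p_e).

    For the degenerate table where both raters place every patient in
    one class (expected agreement 1), the observed agreement is also
    perfect and 1.0 is returned; a genuinely undefined table cannot
    arise from a 2x2 with p_e = 1 and p_o < 1.
    """
    n = t.total
    if n <= 0:
        raise ValueError("kappa requires a non-empty table")
    po = (t.both_pos + t.both_neg) / n
    row_pos = (t.both_pos + t.a_only) / n
    col_pos = (t.both_pos + t.b_only) / n
    pe = row_pos * col_pos + (1 - row_pos) * (1 - col_pos)
    if math.isclose(pe, 1.0):
        return 1.0 if math.isclose(po, 1.0) else float("nan")
    return (po - pe) / (1 - pe)


@dataclass
class ConcordanceReport:
    """All counts and statistics of one dual-verification run.

    Percentages are stored unrounded; ``formatted()`` renders them at
    the conventional reporting precision (1 d.p., prescription match at
    2 d.p.).
    """

    source_a: str
    source_b: str
    registry_total: int
    n_matched: int
    n_unique_a: int
    n_unique_b: int
    pct_matched: float
    prescription: dict[str, float]
    diagnosis: dict[str, float]
    condition_concept: str
    condition_table: TwoByTwo
    kappa: float
    kappa_degenerate: bool

    def to_dict(self) -> dict:
        d = {
            "source_a": self.source_a,
            "source_b": self.source_b,
            "registry_total": self.registry_total,
            "patients": {
                "n_matched": self.n_matched,
                "unique_a": self.n_unique_a,
                "unique_b": self.n_unique_b,
                "pct_matched": self.pct_matched,
            },
            "prescription": dict(self.prescription),
            "diagnosis": dict(self.diagnosis),
            "condition": {
                "concept": self.condition_concept,
                "both_pos": self.condition_table.both_pos,
                "a_only": self.condition_table.a_only,
                "b_only": self.condition_table.b_only,
                "both_neg": self.condition_table.both_neg,
                "kappa": self.kappa,
                "kappa_degenerate": self.kappa_degenerate,
            },
        }
        return d

    def formatted(self) -> dict[str, str]:
        return {
            "pct_matched": f"{self.pct_matched:.1f}%",
            "pct_rx_matched": f"{self.prescription['pct_matched']:.2f}%",
            "pct_dx_missing_a": f"{self.diagnosis['pct_missing_from_a']:.1f}%",
            "kappa": f"{self.kappa:.2f}",
        }


def verification_report(a: SourceExtract, b: SourceExtract,
                        registry_total: int | None = None,
                        condition_concept: str = "copd_dx",
                        codelist: CodeList | None = None) -> ConcordanceReport:
    """Compose matching, prescription merge, diagnosis-record residue and
    condition agreement into one report.

    ``registry_total`` is the external register count of patients the
    practice should hold (denominator of the match percentage); when
    absent, the union of the two extracts is used.
    """
    codelist = codelist or load_codelist()
    m = match_patients(a, b)
    union = m.n_matched + len(m.unique_a) + len(m.unique_b)
    total = registry_total if registry_total is not None else union
    if total <= 0:
        raise ValueError("registry total must be positive")

    _, rx = merge_prescriptions(a, b, m)
    rx_total = rx["total_merged"]
    rx_pct = (100.0 * (rx_total - rx["unique_a"] - rx["unique_b"]) / rx_total
              if rx_total else 100.0)

    # diagnosis (event) record residue over matched patients
    remap = m.b_to_a()
    a_keys = {p[0] for p in m.matched_pairs}
    ea = a.events()
    ea = ea[ea["patient_key"].isin(a_keys)].copy()
    eb = b.events()
    eb = eb[eb["patient_key"].isin(remap.keys())].copy()
    eb["patient_key"] = eb["patient_key"].map(remap)
    key = ["patient_key", "code", "date"]
    da = ea.drop_duplicates(subset=key)[key]
    db = eb.drop_duplicates(subset=key)[key]
    dx = da.merge(db, on=key, how="outer", indicator=True)
    dx_total = len(dx)
    missing_from_b = int((dx["_merge"] == "left_only").sum())  # A holds, B lacks
    missing_from_a = int((dx["_merge"] == "right_only").sum())
    diagnosis = {
        "total": dx_total,
        "missing_from_a": missing_from_a,
        "missing_from_b": missing_from_b,
        "pct_missing_from_a": 100.0 * missing_from_a / dx_total if dx_total else 0.0,
    }

    table = compare_condition(a, b, m, condition_concept, codelist)
    degenerate = table.a_only == 0 and table.b_only == 0 and (
        table.both_pos == 0 or table.both_neg == 0)
    kappa = cohen_kappa(table)

    return ConcordanceReport(
        source_a=a.source_name,
        source_b=b.source_name,
        registry_total=total,
        n_matched=m.n_matched,
        n_unique_a=len(m.unique_a),
        n_unique_b=len(m.unique_b),
        pct_matched=100.0 * m.n_matched / total,
        prescription={"total_merged": rx_total, "unique_a": rx["unique_a"],
                      "unique_b": rx["unique_b"], "pct_matched": rx_pct},
        diagnosis=diagnosis,
        condition_concept=condition_concept,
        condition_table=table,
        kappa=kappa,
        kappa_degenerate=degenerate,
    )
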