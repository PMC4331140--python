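"""Asthma and COPD cohort phenotyping and baseline characterisation.

Eligibility for either cohort requires, in order: a coded diagnosis on
or before the end of the baseline year; at least two bronchodilator
prescriptions (short- or long-acting, counting the bronchodilator
content of ICS/LABA combination inhalers) in the qualifying window
Oct 2007 – Dec 2008; minimum age (18 asthma, 40 COPD) at the reference
date; no exclusion diagnosis (cystic fibrosis, lung cancer,
bronchiectasis, fibrotic lung disease) during 2008–2009.  The asthma
cohort additionally excludes severe asthma (more than 90 days' supply of
oral corticosteroid during 2008, counting calendar coverage rather than
script counts) and any COPD co-diagnosis; the COPD cohort flags, but
keeps, patients with co-morbid asthma.

Every exclusion is logged with the rule(s) that fired, and a flow
account (candidates in, patients out at each gate) is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .codelist import CodeList, load_codelist
from .core import SourceExtract

__all__ = [
    "CohortSpec",
    "Cohort",
    "PrevalenceTable",
    "build_cohort",
    "classify_medications",
    "gold_stage",
    "prevalence",
    "baseline_table",
    "ocs_supply_days",
]

BRONCHODILATOR_CLASSES = ("SABA", "LABA", "LAMA", "ICS_LABA")

EXCLUSION_CONCEPTS = (
    "cystic_fibrosis_dx",
    "lung_cancer_dx",
    "bronchiectasis_dx",
    "fibrotic_lung_disease_dx",
)

RULE_DIAGNOSIS = "no qualifying diagnosis"
RULE_RX = "fewer than required bronchodilator prescriptions in window"
RULE_AGE = "below minimum age"
RULE_EXCLUSION_DX = "exclusion diagnosis in 2008-2009"
RULE_SEVERE_ASTHMA = "severe asthma (>90 days' supply of OCS during 2008)"
RULE_COPD_CODX = "co-diagnosis of COPD"


class CohortSpec(BaseModel):
    """Declarative phenotype definition for one disease cohort."""

    disease: str
    diagnosis_concepts: list[str]
    min_bronchodilator_rx: int = Field(default=2, ge=1)
    rx_window: tuple[date, date] = (date(2007, 10, 1), date(2009, 1, 1))
    min_age: int
    age_reference_date: date = date(2008, 12, 31)
    exclusion_concepts: list[str] = Field(default_factory=lambda: list(EXCLUSION_CONCEPTS))
    exclusion_window: tuple[date, date] = (date(2008, 1, 1), date(2010, 1, 1))
    dx_on_or_before: date = date(2008, 12, 31)
    ocs_supply_gt_days: int | None = None       # asthma-only severe-disease rule
    exclude_copd_codx: bool = False             # asthma-only
    flag_asthma_codx: bool = False              # COPD cohort keeps co-morbid asthma

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.rx_window[0] >= self.rx_window[1]:
            raise ValueError("rx_window must be well-ordered")
        if self.exclusion_window[0] >= self.exclusion_window[1]:
            raise ValueError("exclusion_window must be well-ordered")
        return self

    @classmethod
    def asthma(cls, **overrides) -> "CohortSpec":
        kw = dict(disease="asthma", diagnosis_concepts=["asthma_dx"], min_age=18,
                  ocs_supply_gt_days=90, exclude_copd_codx=True)
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def copd(cls, **overrides) -> "CohortSpec":
        kw = dict(disease="copd", diagnosis_concepts=["copd_dx"], min_age=40,
                  flag_asthma_codx=True)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class Cohort:
    spec: CohortSpec
    members: pd.DataFrame            # one row per included patient
    exclusions: pd.DataFrame         # patient_key, rule (all rules that fired)
    flow: dict[str, int]             # sequential gate accounting

    @property
    def n(self) -> int:
        return len(self.members)

    @property
    def keys(self) -> set[str]:
        return set(self.members["patient_key"])


def ocs_supply_days(prescriptions: pd.DataFrame, year_start: pd.Timestamp,
                    year_end: pd.Timestamp) -> pd.Series:
    """Calendar days of OCS coverage per patient within [year_start, year_end).

    Overlapping scripts are merged so coverage never exceeds the calendar;
    a script's interval is ``[date, date + days_supply)`` clipped to the year.
    Scripts without a recorded supply contribute one day.
    """
    out: dict[str, float] = {}
    if not len(prescriptions):
        return pd.Series(out, dtype=float)
    df = prescriptions.copy()
    supply = df["days_supply"].fillna(1.0).clip(lower=1.0)
    df["s"] = df["date"].clip(lower=year_start)
    df["e"] = (df["date"] + pd.to_timedelta(supply, unit="D")).clip(upper=year_end)
    df = df[df["e"] > df["s"]]
    for k, grp in df.sort_values("s").groupby("patient_key", sort=False):
        total = 0.0
        cur_s = cur_e = None
        for s, e in zip(grp["s"], grp["e"]):
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    total += (cur_e - cur_s).days
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        total += (cur_e - cur_s).days
        out[k] = total
    return pd.Series(out, dtype=float)


def classify_medications(records: pd.DataFrame, codelist: CodeList,
                         patient_keys=None) -> pd.DataFrame:
    """Per-patient medication-class flags from one baseline year of scripts.

    ICS+LABA is flagged for a combination product or for co-prescription
    of separate ICS and LABA inhalers within the year; ICS monotherapy
    excludes those patients.  ICS plus LTRA-or-LAMA is ICS co-prescribed
    with LTRA or LAMA in patients not already in the ICS+LABA group.
    """
    rx = records[records["record_kind"] == "prescription"].copy()
    rx["med_class"] = rx["code"].map(codelist.med_class)
    keys = (pd.Index(sorted(set(patient_keys))) if patient_keys is not None
            else pd.Index(sorted(set(rx["patient_key"]))))
    has = pd.DataFrame(False, index=keys,
                       columns=["SABA", "LABA", "LAMA", "LTRA", "ICS", "ICS_LABA",
                                "OCS", "ABX"])
    for cls in has.columns:
        got = set(rx.loc[rx["med_class"] == cls, "patient_key"])
        has.loc[has.index.isin(got), cls] = True

    flags = pd.DataFrame(index=keys)
    flags["saba"] = has["SABA"]
    flags["laba"] = has["LABA"]  # separate LABA inhaler; combinations under ics_laba
    flags["lama"] = has["LAMA"]
    flags["ltra"] = has["LTRA"]
    flags["ics_laba"] = has["ICS_LABA"] | (has["ICS"] & has["LABA"])
    flags["ics_any"] = has["ICS"] | has["ICS_LABA"]
    flags["ics_mono"] = has["ICS"] & ~flags["ics_laba"]
    flags["ics_ltra_or_lama"] = (flags["ics_any"] & (has["LTRA"] | has["LAMA"])
                                 & ~flags["ics_laba"])
    flags.index.name = "patient_key"
    return flags


def gold_stage(fev1_pct_pred) -> str:
    """Spirometric severity grade from FEV1 percent predicted.

    >=80 -> I, 50-79 -> II, 30-49 -> III, <30 -> IV; missing -> unknown.
    """
    if fev1_pct_pred is None or (isinstance(fev1_pct_pred, float) and np.isnan(fev1_pct_pred)):
        return "unknown"
    v = float(fev1_pct_pred)
    if not np.isfinite(v) or v <= 0:
        raise ValueError(f"FEV1 percent predicted must be positive, got {fev1_pct_pred!r}")
    if v >= 80:
        return "I"
    if v >= 50:
        return "II"
    if v >= 30:
        return "III"
    return "IV"


def _bmi_band(v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "unknown"
    v = float(v)
    if v < 18:
        return "<18"
    if v <= 25:
        return "18-25"
    if v <= 30:
        return "26-30"
    return ">30"


def _first_value(events: pd.DataFrame, codes: set[str],
                 lo: pd.Timestamp, hi: pd.Timestamp) -> pd.Series:
    """First recorded value per patient in [lo, hi); ties broken by the
    lowest record id."""
    sel = events[events["code"].isin(codes)
                 & (events["date"] >= lo) & (events["date"] < hi)]
    sel = sel.sort_values(["patient_key", "date", "record_id"])
    first = sel.groupby("patient_key", sort=False).first()
    return pd.to_numeric(first["value"], errors="coerce")


def _latest_value(events: pd.DataFrame, codes: set[str], hi: pd.Timestamp) -> pd.Series:
    sel = events[events["code"].isin(codes) & (events["date"] < hi)]
    sel = sel.sort_values(["patient_key", "date", "record_id"])
    return sel.groupby("patient_key", sort=False).last()["value"]


def build_cohort(extract: SourceExtract, spec: CohortSpec,
                 codelist: CodeList | None = None) -> Cohort:
    """Apply the eligibility algorithm and characterise the members."""
    codelist = codelist or load_codelist()
    for concept in spec.diagnosis_concepts + spec.exclusion_concepts:
        if concept not in codelist.concepts:
            raise KeyError(f"concept {concept!r} missing from the code list")

    pats = extract.patients
    journal = extract.journal
    events = extract.events()
    rx = extract.prescriptions()

    dx_codes = set(codelist.codes_for_concepts(spec.diagnosis_concepts))
    dx_cut = pd.Timestamp(spec.dx_on_or_before) + pd.Timedelta(days=1)
    diagnosed = set(events.loc[events["code"].isin(dx_codes)
                               & (events["date"] < dx_cut), "patient_key"])

    candidates = pats[pats["patient_key"].isin(diagnosed)].copy()
    flow: dict[str, int] = {"candidates_with_diagnosis": len(candidates)}
    rules_fired: list[tuple[str, str]] = []

    # bronchodilator scripts in the qualifying window
    bd_codes: set[str] = set()
    for cls in BRONCHODILATOR_CLASSES:
        bd_codes |= set(codelist.codes_for_class(cls))
    lo, hi = pd.Timestamp(spec.rx_window[0]), pd.Timestamp(spec.rx_window[1])
    in_win = rx[rx["code"].isin(bd_codes) & (rx["date"] >= lo) & (rx["date"] < hi)]
    n_bd = in_win.groupby("patient_key").size()
    enough_rx = set(n_bd[n_bd >= spec.min_bronchodilator_rx].index)

    old_enough = set(candidates.loc[candidates["age"] >= spec.min_age, "patient_key"])

    ex_codes = set(codelist.codes_for_concepts(spec.exclusion_concepts))
    xlo, xhi = pd.Timestamp(spec.exclusion_window[0]), pd.Timestamp(spec.exclusion_window[1])
    excluded_dx = set(events.loc[events["code"].isin(ex_codes)
                                 & (events["date"] >= xlo) & (events["date"] < xhi),
                                 "patient_key"])

    severe: set[str] = set()
    if spec.ocs_supply_gt_days is not None:
        ocs_codes = set(codelist.codes_for_class("OCS"))
        y0, y1 = pd.Timestamp("2008-01-01"), pd.Timestamp("2009-01-01")
        ocs = rx[rx["code"].isin(ocs_codes)]
        days = ocs_supply_days(ocs, y0, y1)
        severe = set(days[days > spec.ocs_supply_gt_days].index)

    copd_codx: set[str] = set()
    if spec.exclude_copd_codx:
        copd_codes = set(codelist.codes_for_concept("copd_dx"))
        copd_codx = set(events.loc[events["code"].isin(copd_codes)
                                   & (events["date"] < dx_cut), "patient_key"])

    # sequential gates for flow accounting; all fired rules are logged
    surviving = set(candidates["patient_key"])
    gates: list[tuple[str, set[str]]] = [
        (RULE_RX, surviving - enough_rx),
        (RULE_AGE, surviving - old_enough),
        (RULE_EXCLUSION_DX, surviving & excluded_dx),
    ]
    if spec.ocs_supply_gt_days is not None:
        gates.append((RULE_SEVERE_ASTHMA, surviving & severe))
    if spec.exclude_copd_codx:
        gates.append((RULE_COPD_CODX, surviving & copd_codx))

    for rule, failing in gates:
        for k in sorted(failing):
            rules_fired.append((k, rule))
        newly = failing & surviving
        flow[f"excluded: {rule}"] = len(newly)
        surviving = surviving - failing
    flow["included"] = len(surviving)

    members = candidates[candidates["patient_key"].isin(surviving)].copy()
    members = members.sort_values("patient_key").reset_index(drop=True)

    # --- baseline characterisation (2008 data) ---
    y0, y1 = pd.Timestamp("2008-01-01"), pd.Timestamp("2009-01-01")
    idx = members["patient_key"]

    smoking = _latest_value(events, set(codelist.codes_for_concept("smoking_status")), y1)
    members["smoking"] = idx.map(smoking).fillna("unknown").values

    bmi = pd.to_numeric(
        _latest_value(events, set(codelist.codes_for_concept("bmi")), y1), errors="coerce")
    members["bmi_category"] = [_bmi_band(v) for v in idx.map(bmi)]

    fev1 = _first_value(events, set(codelist.codes_for_concept("fev1")), y0, y1)
    members["fev1_L"] = idx.map(fev1).values
    fevp = _first_value(events, set(codelist.codes_for_concept("fev1_pct_pred")), y0, y1)
    members["fev1_pct_pred"] = idx.map(fevp).values
    members["gold_stage"] = [gold_stage(v) for v in members["fev1_pct_pred"]]
    pef = _first_value(events, set(codelist.codes_for_concept("pef")), y0, y1)
    members["pef"] = idx.map(pef).values

    base_rx = rx[(rx["date"] >= y0) & (rx["date"] < y1)]
    med = classify_medications(base_rx, codelist, patient_keys=idx)
    for col in med.columns:
        members[col] = idx.map(med[col]).fillna(False).values

    cv_cut = pd.Timestamp("2010-01-01")  # "present before 31 December 2009"
    for concept in ("mi", "hypertension", "stroke", "heart_failure"):
        got = set(events.loc[events["code"].isin(codelist.codes_for_concept(concept))
                             & (events["date"] < cv_cut), "patient_key"])
        members[f"cv_{concept}"] = members["patient_key"].isin(got)
    members["cv_any"] = members[[f"cv_{c}" for c in
                                 ("mi", "hypertension", "stroke", "heart_failure")]].any(axis=1)

    if spec.flag_asthma_codx:
        asthma_codes = set(codelist.codes_for_concept("asthma_dx"))
        got = set(events.loc[events["code"].isin(asthma_codes)
                             & (events["date"] < dx_cut), "patient_key"])
        members["comorbid_asthma"] = members["patient_key"].isin(got)

    # baseline (2008) exacerbation count, by the episode algorithm
    from .outcomes import ExacerbationDefinition, identify_exacerbations
    defn = ExacerbationDefinition.for_disease(spec.disease)
    journal_members = journal[journal["patient_key"].isin(surviving)]
    episodes = identify_exacerbations(journal_members, defn, (y0, y1), codelist=codelist)
    n_base = episodes.groupby("patient_key").size() if len(episodes) else pd.Series(dtype=int)
    members["baseline_exacerbation_count"] = (
        members["patient_key"].map(n_base).fillna(0).astype(int))

    exclusions = pd.DataFrame(rules_fired, columns=["patient_key", "rule"])
    return Cohort(spec=spec, members=members, exclusions=exclusions, flow=flow)


@dataclass
class PrevalenceTable:
    cases: dict[str, int]        # overall / male / female numerators
    population: dict[str, int]   # matching denominators
    proportions: dict[str, float] = field(init=False)

    def __post_init__(self) -> None:
        self.proportions = {}
        for k, num in self.cases.items():
            den = self.population[k]
            if den <= 0:
                raise ValueError(f"zero denominator for {k!r}")
            if num > den:
                raise ValueError(f"{k}: numerator {num} exceeds denominator {den}")
            self.proportions[k] = num / den

    def pct(self, key: str, ndigits: int = 1) -> float:
        return round(100.0 * self.proportions[key], ndigits)


def prevalence(n_cases_total: int, n_cases_male: int,
               pop_total: int, pop_male: int) -> PrevalenceTable:
    """Crude prevalence overall and by sex from case and population counts."""
    return PrevalenceTable(
        cases={"overall": n_cases_total, "male": n_cases_male,
               "female": n_cases_total - n_cases_male},
        population={"overall": pop_total, "male": pop_male,
                    "female": pop_total - pop_male},
    )


def baseline_table(cohort: Cohort) -> pd.DataFrame:
    """Summary rows (n, %, mean, SD) of the baseline characteristics."""
    m = cohort.members
    n = len(m)
    if n == 0:
        raise ValueError("cohort is empty")
    rows: list[dict] = []

    def count_row(label, mask):
        k = int(mask.sum())
        rows.append({"row": label, "n": k, "pct": 100.0 * k / n,
                     "mean": np.nan, "sd": np.nan})

    def mean_row(label, series):
        s = pd.to_numeric(series, errors="coerce").dropna()
        rows.append({"row": label, "n": int(s.size), "pct": np.nan,
                     "mean": s.mean() if s.size else np.nan,
                     "sd": s.std(ddof=1) if s.size > 1 else np.nan})

    mean_row("age (years)", m["age"])
    count_row("male sex", m["sex"] == "M")
    for cat in ("current", "former", "never", "unknown"):
        count_row(f"smoking: {cat}", m["smoking"] == cat)
    for band in ("<18", "18-25", "26-30", ">30", "unknown"):
        count_row(f"bmi: {band}", m["bmi_category"] == band)
    mean_row("FEV1 (L)", m["fev1_L"])
    mean_row("FEV1 % predicted", m["fev1_pct_pred"])
    if cohort.spec.disease == "copd":
        for st in ("I", "II", "III", "IV", "unknown"):
            count_row(f"GOLD stage {st}", m["gold_stage"] == st)
    if cohort.spec.disease == "asthma":
        mean_row("peak expiratory flow", m["pef"])
    med_rows = [("SABA", "saba"), ("LABA", "laba"), ("LAMA", "lama"), ("LTRA", "ltra"),
                ("ICS monotherapy", "ics_mono"), ("ICS plus LABA", "ics_laba"),
                ("ICS plus LTRA or LAMA", "ics_ltra_or_lama")]
    for label, col in med_rows:
        count_row(f"medication: {label}", m[col])
    cv_rows = [("any", "cv_any"), ("acute MI", "cv_mi"), ("hypertension", "cv_hypertension"),
               ("stroke", "cv_stroke"), ("heart failure", "cv_heart_failure")]
    for label, col in cv_rows:
        count_row(f"cardiovascular: {label}", m[col])
    return pd.DataFrame(rows)
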