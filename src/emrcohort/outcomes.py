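"""Exacerbation episodes, person-time and resource-utilisation rates.

Treated exacerbations are reconstructed from their footprint in the
record: OCS prescriptions (plus antibiotics for COPD) and respiratory
admissions.  Trigger records within a configurable merge window (default
14 days, the prevailing pharmacoepidemiology convention for separating
episodes) collapse into one episode; an episode containing a respiratory
admission is *severe*, otherwise *moderate*.

Follow-up for outcome rates runs through calendar 2009, censored at
death or deregistration; person-years use a 365.25-day year and
half-open date intervals, so an uncensored patient contributes
365/365.25 years.  Rates are reported per 100 person-years.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .codelist import CodeList, load_codelist
from .phenotyping import Cohort

__all__ = [
    "ExacerbationDefinition",
    "identify_exacerbations",
    "person_time",
    "hru_rates",
    "stratify_by_baseline_exacerbations",
    "medication_subset",
    "hospital_days_summary",
    "FOLLOWUP_ENTRY",
    "FOLLOWUP_ADMIN_END",
]

FOLLOWUP_ENTRY = pd.Timestamp("2009-01-01")
FOLLOWUP_ADMIN_END = pd.Timestamp("2010-01-01")  # exclusive bound: through 2009-12-31
DAYS_PER_YEAR = 365.25

#: HRU outcome columns; "short courses" of OCS are scripts of <=21 days' supply
SHORT_COURSE_MAX_DAYS = 21
OCS_OUTLIER_SCRIPTS_2008 = 12


@dataclass(frozen=True)
class ExacerbationDefinition:
    """Trigger concepts that mark a treated exacerbation."""

    disease: str
    trigger_concepts: tuple[str, ...]
    merge_window_days: float = 14.0

    def __post_init__(self) -> None:
        if self.merge_window_days < 0:
            raise ValueError("merge_window_days must be >= 0")

    @classmethod
    def for_disease(cls, disease: str, merge_window_days: float = 14.0
                    ) -> "ExacerbationDefinition":
        if disease == "asthma":
            concepts = ("ocs", "resp_admission")
        elif disease == "copd":
            concepts = ("ocs", "antibiotic", "resp_admission")
        else:
            raise ValueError(f"unknown disease: {disease!r}")
        return cls(disease=disease, trigger_concepts=concepts,
                   merge_window_days=merge_window_days)


def identify_exacerbations(journal: pd.DataFrame, defn: ExacerbationDefinition,
                           window: tuple[date, date] | tuple[pd.Timestamp, pd.Timestamp],
                           codelist: CodeList | None = None) -> pd.DataFrame:
    """Group trigger records into episodes.

    A trigger record whose date is at most ``merge_window_days`` after
    the running episode's end joins that episode (extending its end);
    otherwise it opens a new one.  Returns one row per episode with
    patient_key, start_date, end_date, severity and component record ids.
    """
    codelist = codelist or load_codelist()
    lo, hi = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    codes = set(codelist.codes_for_concepts(defn.trigger_concepts))
    severe_codes = set(codelist.codes_for_concept("resp_admission")) & codes

    trig = journal[journal["code"].isin(codes)
                   & (journal["date"] >= lo) & (journal["date"] < hi)]
    if not len(trig):
        return pd.DataFrame(columns=["patient_key", "start_date", "end_date",
                                     "severity", "component_record_ids"])
    trig = trig.sort_values(["patient_key", "date", "record_id"])
    gap = defn.merge_window_days

    episodes: list[dict] = []
    for key, grp in trig.groupby("patient_key", sort=False):
        start = end = None
        ids: list[int] = []
        severe = False

        def flush():
            episodes.append({"patient_key": key, "start_date": start, "end_date": end,
                             "severity": "severe" if severe else "moderate",
                             "component_record_ids": tuple(ids)})

        for row in grp.itertuples():
            d = row.date
            rec_end = row.discharge_date if pd.notna(row.discharge_date) else d
            if start is None:
                start, end, ids, severe = d, rec_end, [row.record_id], row.code in severe_codes
            elif math.isinf(gap) or (d - end).days <= gap:
                end = max(end, rec_end)
                ids.append(row.record_id)
                severe = severe or row.code in severe_codes
            else:
                flush()
                start, end, ids, severe = d, rec_end, [row.record_id], row.code in severe_codes
        flush()
    return pd.DataFrame(episodes)


@dataclass
class FollowUp:
    patient_key: str
    entry_date: pd.Timestamp
    exit_date: pd.Timestamp       # exclusive bound of follow-up
    exit_reason: str              # death | deregistration | admin_end
    person_years: float
    flagged_zero: bool = False


def person_time(journal: pd.DataFrame, patient_keys,
                entry: pd.Timestamp = FOLLOWUP_ENTRY,
                admin_end: pd.Timestamp = FOLLOWUP_ADMIN_END,
                codelist: CodeList | None = None) -> pd.DataFrame:
    """Follow-up per patient: exit at the earliest of death,
    deregistration, or the administrative end of 2009.

    Follow-up is the half-open interval [entry, exit); a death on
    2009-07-02 therefore contributes 182/365.25 person-years and an
    uncensored patient 365/365.25.  Exit before entry yields zero
    person-years and is flagged.
    """
    codelist = codelist or load_codelist()
    death_codes = set(codelist.codes_for_concept("death"))
    dereg_codes = set(codelist.codes_for_concept("deregistration"))

    ev = journal[journal["code"].isin(death_codes | dereg_codes)]
    death = ev[ev["code"].isin(death_codes)].groupby("patient_key")["date"].min()
    dereg = ev[ev["code"].isin(dereg_codes)].groupby("patient_key")["date"].min()

    rows = []
    for k in sorted(set(patient_keys)):
        d_death = death.get(k, pd.NaT)
        d_dereg = dereg.get(k, pd.NaT)
        exit_date, reason = admin_end, "admin_end"
        if pd.notna(d_dereg) and d_dereg < exit_date:
            exit_date, reason = d_dereg, "deregistration"
        if pd.notna(d_death) and d_death < exit_date:
            exit_date, reason = d_death, "death"
        days = (exit_date - entry).days
        flagged = days <= 0
        rows.append({"patient_key": k, "entry_date": entry,
                     "exit_date": max(exit_date, entry), "exit_reason": reason,
                     "person_years": max(days, 0) / DAYS_PER_YEAR,
                     "flagged_zero": flagged})
    return pd.DataFrame(rows)


def _count_events(journal: pd.DataFrame, codes: set[str],
                  followup: pd.DataFrame, dedup_daily: bool = False) -> pd.Series:
    """Events per patient with date inside that patient's follow-up."""
    fu = followup.set_index("patient_key")
    sel = journal[journal["code"].isin(codes)
                  & journal["patient_key"].isin(fu.index)].copy()
    if not len(sel):
        return pd.Series(dtype=int)
    entry = sel["patient_key"].map(fu["entry_date"])
    exit_ = sel["patient_key"].map(fu["exit_date"])
    sel = sel[(sel["date"] >= entry) & (sel["date"] < exit_)]
    if dedup_daily:
        sel = sel.drop_duplicates(subset=["patient_key", "date"])
    return sel.groupby("patient_key").size()


def hru_rates(cohort: Cohort, journal: pd.DataFrame,
              strata: dict[str, set[str]] | None = None,
              codelist: CodeList | None = None,
              followup: pd.DataFrame | None = None) -> pd.DataFrame:
    """Events, person-years and rates per 100 person-years by stratum.

    Outcomes: OCS short courses (days' supply <= 21; patients with >12
    OCS scripts during 2008 are dropped from this row as outliers, from
    numerator and denominator alike), antibiotic scripts, all-cause GP
    visits (one per patient-day), all-cause and respiratory admissions.
    An empty stratum is emitted with zero person-years and no rate.
    """
    codelist = codelist or load_codelist()
    keys = cohort.keys
    if strata is None:
        strata = {"total": keys}
    if followup is None:
        followup = person_time(journal, keys, codelist=codelist)
    fu = followup.set_index("patient_key")

    ocs_codes = set(codelist.codes_for_class("OCS"))
    rx = journal[journal["record_kind"] == "prescription"]
    ocs = rx[rx["code"].isin(ocs_codes)]
    short = ocs[ocs["days_supply"].fillna(1.0) <= SHORT_COURSE_MAX_DAYS]
    y0, y1 = pd.Timestamp("2008-01-01"), pd.Timestamp("2009-01-01")
    n_2008 = ocs[(ocs["date"] >= y0) & (ocs["date"] < y1)].groupby("patient_key").size()
    outliers = set(n_2008[n_2008 > OCS_OUTLIER_SCRIPTS_2008].index)

    abx_codes = set(codelist.codes_for_class("ABX"))
    gp_codes = set(codelist.codes_for_concept("gp_visit"))
    resp_codes = set(codelist.codes_for_concept("resp_admission"))
    all_adm_codes = resp_codes | set(codelist.codes_for_concept("nonresp_admission"))

    counters = {
        "ocs_short_courses": _count_events(short, ocs_codes, followup),
        "antibiotics": _count_events(journal, abx_codes, followup),
        "gp_visits_all_cause": _count_events(journal, gp_codes, followup, dedup_daily=True),
        "hospitalisations_all_cause": _count_events(journal, all_adm_codes, followup),
        "hospitalisations_respiratory": _count_events(journal, resp_codes, followup),
    }

    rows = []
    for stratum, skeys in strata.items():
        skeys = set(skeys) & keys
        for outcome, counts in counters.items():
            use = skeys - outliers if outcome == "ocs_short_courses" else skeys
            py = float(fu.loc[fu.index.isin(use), "person_years"].sum())
            ev = int(counts[counts.index.isin(use)].sum())
            rate = 100.0 * ev / py if py > 0 else np.nan
            rows.append({"stratum": stratum, "outcome": outcome, "n_patients": len(use),
                         "events": ev, "person_years": py, "rate_per_100py": rate,
                         "zero_person_years": py == 0.0})
    return pd.DataFrame(rows)


def stratify_by_baseline_exacerbations(cohort: Cohort) -> dict[str, set[str]]:
    """Partition members into infrequent (<=1) and frequent (>=2)
    baseline-year exacerbators."""
    m = cohort.members
    le1 = set(m.loc[m["baseline_exacerbation_count"] <= 1, "patient_key"])
    ge2 = set(m.loc[m["baseline_exacerbation_count"] >= 2, "patient_key"])
    return {"le1_exac": le1, "ge2_exac": ge2}


def medication_subset(cohort: Cohort) -> set[str]:
    """The maintenance-therapy subset reported alongside the strata:
    ICS or ICS/LABA for asthma; ICS/LABA, LABA or LAMA for COPD."""
    m = cohort.members
    if cohort.spec.disease == "asthma":
        mask = m["ics_any"] | m["ics_laba"]
    else:
        mask = m["ics_laba"] | m["laba"] | m["lama"]
    return set(m.loc[mask, "patient_key"])


def hospital_days_summary(cohort: Cohort, journal: pd.DataFrame,
                          codelist: CodeList | None = None,
                          followup: pd.DataFrame | None = None) -> dict[str, float]:
    """Mean inpatient days per patient-year and the respiratory share.

    Stays are clipped to each patient's follow-up interval; a discharge
    before admission is rejected.
    """
    codelist = codelist or load_codelist()
    keys = cohort.keys
    if followup is None:
        followup = person_time(journal, keys, codelist=codelist)
    fu = followup.set_index("patient_key")

    resp_codes = set(codelist.codes_for_concept("resp_admission"))
    adm_codes = resp_codes | set(codelist.codes_for_concept("nonresp_admission"))
    adm = journal[journal["code"].isin(adm_codes)
                  & journal["patient_key"].isin(keys)].copy()
    if (adm["discharge_date"].notna() & (adm["discharge_date"] < adm["date"])).any():
        bad = adm[adm["discharge_date"] < adm["date"]].iloc[0]
        raise ValueError(
            f"discharge before admission for patient {bad['patient_key']!r} "
            f"on {bad['date'].date()}")
    adm["discharge_date"] = adm["discharge_date"].fillna(adm["date"])

    entry = adm["patient_key"].map(fu["entry_date"])
    exit_ = adm["patient_key"].map(fu["exit_date"])
    s = np.maximum(adm["date"].values, entry.values)
    e = np.minimum(adm["discharge_date"].values, exit_.values)
    days = ((e - s) / np.timedelta64(1, "D")).clip(min=0)
    total_days = float(days.sum())
    resp_days = float(days[adm["code"].isin(resp_codes).values].sum())

    py = float(fu["person_years"].sum())
    return {
        "total_inpatient_days": total_days,
        "respiratory_inpatient_days": resp_days,
        "person_years": py,
        "mean_days_per_patient_year": total_days / py if py > 0 else np.nan,
        "respiratory_share": resp_days / total_days if total_days > 0 else np.nan,
    }
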