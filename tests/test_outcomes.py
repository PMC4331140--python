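"""Exacerbation episodes, person-time and rate tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_extract, make_journal
from emrcohort.codelist import load_codelist
from emrcohort.outcomes import (ExacerbationDefinition, hospital_days_summary,
                                hru_rates, identify_exacerbations,
                                medication_subset, person_time,
                                stratify_by_baseline_exacerbations)
from emrcohort.phenotyping import CohortSpec, build_cohort

WINDOW_2009 = (pd.Timestamp("2009-01-01"), pd.Timestamp("2010-01-01"))


@pytest.fixture(scope="module")
def cl():
    return load_codelist()


# --- episode construction ---------------------------------------------------

def test_no_triggers_no_episodes(cl):
    j = make_journal([("p", "event", "GPV01", "2009-05-01")])
    defn = ExacerbationDefinition.for_disease("copd")
    assert len(identify_exacerbations(j, defn, WINDOW_2009, cl)) == 0


def test_ocs_then_antibiotic_within_window_one_moderate_episode(cl):
    j = make_journal([
        ("p", "prescription", "RXO01", "2009-03-01", {"days_supply": 5}),
        ("p", "prescription", "RXA01", "2009-03-06", {"days_supply": 7}),
    ])
    defn = ExacerbationDefinition.for_disease("copd", merge_window_days=14)
    eps = identify_exacerbations(j, defn, WINDOW_2009, cl)
    assert len(eps) == 1
    assert eps.loc[0, "severity"] == "moderate"
    assert len(eps.loc[0, "component_record_ids"]) == 2


def test_ocs_then_admission_one_severe_episode(cl):
    j = make_journal([
        ("p", "prescription", "RXO01", "2009-03-01", {"days_supply": 5}),
        ("p", "event", "ADR01", "2009-03-04", {"discharge_date": "2009-03-09"}),
    ])
    defn = ExacerbationDefinition.for_disease("asthma", merge_window_days=14)
    eps = identify_exacerbations(j, defn, WINDOW_2009, cl)
    assert len(eps) == 1
    assert eps.loc[0, "severity"] == "severe"
    assert eps.loc[0, "end_date"] == pd.Timestamp("2009-03-09")


def test_antibiotic_not_an_asthma_trigger(cl):
    j = make_journal([("p", "prescription", "RXA01", "2009-03-01", {"days_supply": 7})])
    asthma = ExacerbationDefinition.for_disease("asthma")
    copd = ExacerbationDefinition.for_disease("copd")
    assert len(identify_exacerbations(j, asthma, WINDOW_2009, cl)) == 0
    assert len(identify_exacerbations(j, copd, WINDOW_2009, cl)) == 1


def test_gap_beyond_merge_window_splits_episodes(cl):
    j = make_journal([
        ("p", "prescription", "RXO01", "2009-03-01", {"days_supply": 5}),
        ("p", "prescription", "RXO01", "2009-03-20", {"days_supply": 5}),
    ])
    defn = ExacerbationDefinition.for_disease("asthma", merge_window_days=14)
    assert len(identify_exacerbations(j, defn, WINDOW_2009, cl)) == 2


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(min_value=0, max_value=360), min_size=0, max_size=25))
def test_episode_merge_window_invariants(day_offsets):
    """merge_window=0 gives one episode per distinct trigger date;
    merge_window=inf gives at most one per patient; episode count never
    exceeds trigger count."""
    cl = load_codelist()
    rows = [("p", "prescription", "RXO01",
             pd.Timestamp("2009-01-01") + pd.Timedelta(days=d), {"days_supply": 5})
            for d in day_offsets]
    j = make_journal(rows)
    zero = identify_exacerbations(
        j, ExacerbationDefinition("asthma", ("ocs",), 0.0), WINDOW_2009, cl)
    assert len(zero) == len(set(day_offsets))
    inf = identify_exacerbations(
        j, ExacerbationDefinition("asthma", ("ocs",), math.inf), WINDOW_2009, cl)
    assert len(inf) == (1 if day_offsets else 0)
    fourteen = identify_exacerbations(
        j, ExacerbationDefinition("asthma", ("ocs",), 14.0), WINDOW_2009, cl)
    assert len(fourteen) <= len(day_offsets)


# --- person-time ------------------------------------------------------------

def test_full_year_person_time(cl):
    j = make_journal([("p", "event", "GPV01", "2009-06-01")])
    fu = person_time(j, ["p"], codelist=cl)
    assert fu.loc[0, "exit_reason"] == "admin_end"
    assert fu.loc[0, "person_years"] == pytest.approx(365 / 365.25)


def test_death_mid_year_person_time(cl):
    j = make_journal([("p", "event", "XDE01", "2009-07-02")])
    fu = person_time(j, ["p"], codelist=cl)
    assert fu.loc[0, "exit_reason"] == "death"
    assert fu.loc[0, "person_years"] == pytest.approx(182 / 365.25)


def test_death_before_entry_flagged_zero(cl):
    j = make_journal([("p", "event", "XDE01", "2008-06-01")])
    fu = person_time(j, ["p"], codelist=cl)
    assert fu.loc[0, "person_years"] == 0.0
    assert bool(fu.loc[0, "flagged_zero"])


def test_exit_is_earliest_event_min_oracle(cl):
    """Random death/deregistration sets: exit equals the min() oracle."""
    rng = np.random.default_rng(81)
    rows, expected = [], {}
    admin = pd.Timestamp("2010-01-01")
    for i in range(40):
        key = f"p{i:02d}"
        dates = []
        for code in ("XDE01", "XDR01"):
            if rng.random() < 0.5:
                d = pd.Timestamp("2009-01-01") + pd.Timedelta(days=int(rng.integers(0, 500)))
                rows.append((key, "event", code, d))
                dates.append(d)
        expected[key] = min([d for d in dates if d < admin], default=admin)
        rows.append((key, "event", "GPV01", "2009-02-01"))
    fu = person_time(make_journal(rows), expected.keys(), codelist=cl).set_index("patient_key")
    for key, want in expected.items():
        assert fu.loc[key, "exit_date"] == max(want, pd.Timestamp("2009-01-01"))


# --- rates ------------------------------------------------------------------

def _rate_fixture(cl):
    patients = [("p1", 30, "F"), ("p2", 40, "M")]
    rows = []
    for key in ("p1", "p2"):
        rows.append((key, "event", "AST01", "2008-01-10"))
        rows.append((key, "prescription", "RXS01", "2008-02-01", {"days_supply": 28}))
        rows.append((key, "prescription", "RXS01", "2008-04-01", {"days_supply": 28}))
    # 3 OCS short courses during 2009 across the two patients
    rows.append(("p1", "prescription", "RXO01", "2009-02-01", {"days_supply": 5}))
    rows.append(("p1", "prescription", "RXO01", "2009-06-01", {"days_supply": 5}))
    rows.append(("p2", "prescription", "RXO01", "2009-09-01", {"days_supply": 5}))
    ex = make_extract("A", patients, rows)
    cohort = build_cohort(ex, CohortSpec.asthma(), cl)
    return ex, cohort


def test_rate_arithmetic_three_scripts_two_person_years(cl):
    ex, cohort = _rate_fixture(cl)
    rates = hru_rates(cohort, ex.journal, codelist=cl).set_index("outcome")
    row = rates.loc["ocs_short_courses"]
    assert row["events"] == 3
    assert row["person_years"] == pytest.approx(2 * 365 / 365.25)
    assert row["rate_per_100py"] == pytest.approx(300 / (2 * 365 / 365.25))


def test_ocs_outlier_excluded_from_ocs_row_only(cl):
    patients = [("p1", 30, "F"), ("p2", 40, "M")]
    rows = []
    for key in ("p1", "p2"):
        rows.append((key, "event", "AST01", "2008-01-10"))
        rows.append((key, "prescription", "RXS01", "2008-02-01", {"days_supply": 28}))
        rows.append((key, "prescription", "RXS01", "2008-04-01", {"days_supply": 28}))
    # p2 gets 13 OCS scripts in 2008 -> outlier for the OCS row
    for wk in range(13):
        rows.append(("p2", "prescription", "RXO01",
                     pd.Timestamp("2008-03-01") + pd.Timedelta(weeks=wk),
                     {"days_supply": 3}))
    rows.append(("p2", "prescription", "RXO01", "2009-05-01", {"days_supply": 5}))
    rows.append(("p2", "event", "GPV01", "2009-05-02"))
    ex = make_extract("A", patients, rows)
    cohort = build_cohort(ex, CohortSpec.asthma(), cl)
    assert cohort.n == 2  # 13 x 3-day supply = 39 days, under the 90-day rule
    rates = hru_rates(cohort, ex.journal, codelist=cl).set_index("outcome")
    assert rates.loc["ocs_short_courses", "n_patients"] == 1
    assert rates.loc["ocs_short_courses", "events"] == 0
    assert rates.loc["gp_visits_all_cause", "n_patients"] == 2
    assert rates.loc["gp_visits_all_cause", "events"] == 1


def test_empty_stratum_emits_flagged_row(cl):
    ex, cohort = _rate_fixture(cl)
    rates = hru_rates(cohort, ex.journal, {"none": set()}, codelist=cl)
    assert (rates["zero_person_years"]).all()
    assert rates["rate_per_100py"].isna().all()


def test_person_years_constant_across_outcomes(cl):
    ex, cohort = _rate_fixture(cl)
    rates = hru_rates(cohort, ex.journal, codelist=cl)
    assert rates["person_years"].nunique() == 1


def test_gp_visits_deduplicated_per_day(cl):
    patients = [("p1", 30, "F")]
    rows = [("p1", "event", "AST01", "2008-01-10"),
            ("p1", "prescription", "RXS01", "2008-02-01", {"days_supply": 28}),
            ("p1", "prescription", "RXS01", "2008-04-01", {"days_supply": 28}),
            ("p1", "event", "GPV01", "2009-03-03"),
            ("p1", "event", "GPV02", "2009-03-03"),
            ("p1", "event", "GPV01", "2009-03-04")]
    ex = make_extract("A", patients, rows)
    cohort = build_cohort(ex, CohortSpec.asthma(), cl)
    rates = hru_rates(cohort, ex.journal, codelist=cl).set_index("outcome")
    assert rates.loc["gp_visits_all_cause", "events"] == 2


# --- stratification ---------------------------------------------------------

def test_stratification_partitions_cohort(cl):
    ex, cohort = _rate_fixture(cl)
    cohort.members["baseline_exacerbation_count"] = [0, 2]
    strata = stratify_by_baseline_exacerbations(cohort)
    assert strata["le1_exac"] | strata["ge2_exac"] == cohort.keys
    assert not strata["le1_exac"] & strata["ge2_exac"]


def test_stratify_counts_example(cl):
    ex, cohort = _rate_fixture(cl)
    members = cohort.members.iloc[[0, 1, 0, 1]].copy().reset_index(drop=True)
    members["patient_key"] = ["a", "b", "c", "d"]
    members["baseline_exacerbation_count"] = [0, 1, 2, 5]
    cohort.members = members
    strata = stratify_by_baseline_exacerbations(cohort)
    assert len(strata["le1_exac"]) == 2 and len(strata["ge2_exac"]) == 2


def test_medication_subsets_by_disease(cl):
    ex, cohort = _rate_fixture(cl)
    cohort.members["ics_any"] = [True, False]
    cohort.members["ics_laba"] = [False, False]
    cohort.members["laba"] = [False, True]
    cohort.members["lama"] = [False, False]
    assert medication_subset(cohort) == {"p1"}          # asthma: ICS or ICS/LABA
    cohort.spec = CohortSpec.copd()
    assert medication_subset(cohort) == {"p2"}          # copd: ICS/LABA, LABA or LAMA


# --- hospital days ----------------------------------------------------------

def test_hospital_days_simple_stay(cl):
    patients = [("p1", 30, "F")]
    rows = [("p1", "event", "AST01", "2008-01-10"),
            ("p1", "prescription", "RXS01", "2008-02-01", {"days_supply": 28}),
            ("p1", "prescription", "RXS01", "2008-04-01", {"days_supply": 28}),
            ("p1", "event", "ADR01", "2009-03-01", {"discharge_date": "2009-03-04"})]
    ex = make_extract("A", patients, rows)
    cohort = build_cohort(ex, CohortSpec.asthma(), cl)
    s = hospital_days_summary(cohort, ex.journal, cl)
    assert s["total_inpatient_days"] == 3.0
    assert s["respiratory_share"] == 1.0
    assert s["mean_days_per_patient_year"] == pytest.approx(3.0 / (365 / 365.25))


def test_stay_clipped_at_exit(cl):
    patients = [("p1", 30, "F")]
    rows = [("p1", "event", "AST01", "2008-01-10"),
            ("p1", "prescription", "RXS01", "2008-02-01", {"days_supply": 28}),
            ("p1", "prescription", "RXS01", "2008-04-01", {"days_supply": 28}),
            ("p1", "event", "ADN01", "2009-12-28", {"discharge_date": "2010-01-10"})]
    ex = make_extract("A", patients, rows)
    cohort = build_cohort(ex, CohortSpec.asthma(), cl)
    s = hospital_days_summary(cohort, ex.journal, cl)
    assert s["total_inpatient_days"] == 4.0  # 12-28 .. 01-01 exclusive


def test_discharge_before_admission_rejected(cl):
    ex, cohort = _rate_fixture(cl)
    bad = make_journal([("p1", "event", "ADR01", "2009-03-05",
                         {"discharge_date": "2009-03-01"})])
    j = pd.concat([ex.journal, bad], ignore_index=True)
    with pytest.raises(ValueError, match="discharge before admission"):
        hospital_days_summary(cohort, j, cl)


def test_hospital_days_interval_sum_oracle(cl):
    """Random stays: clipped-interval sums equal a direct oracle."""
    rng = np.random.default_rng(91)
    patients = [(f"p{i}", 50, "M") for i in range(15)]
    rows, oracle = [], 0.0
    entry, exit_ = pd.Timestamp("2009-01-01"), pd.Timestamp("2010-01-01")
    for key, _, _ in patients:
        rows.append((key, "event", "AST01", "2008-01-10"))
        rows.append((key, "prescription", "RXS01", "2008-02-01", {"days_supply": 28}))
        rows.append((key, "prescription", "RXS01", "2008-04-01", {"days_supply": 28}))
        for _ in range(rng.integers(0, 4)):
            start = pd.Timestamp("2008-11-01") + pd.Timedelta(days=int(rng.integers(0, 450)))
            end = start + pd.Timedelta(days=int(rng.integers(0, 20)))
            rows.append((key, "event", "ADN01", start, {"discharge_date": end}))
            oracle += max(0.0, (min(end, exit_) - max(start, entry)).days)
    ex = make_extract("A", patients, rows)
    cohort = build_cohort(ex, CohortSpec.asthma(), cl)
    s = hospital_days_summary(cohort, ex.journal, cl)
    assert s["total_inpatient_days"] == pytest.approx(oracle)
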