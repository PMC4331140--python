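"""Synthetic two-source primary-care EMR generator.

The generator builds a ground-truth adult population with coded asthma
and COPD diagnoses, respiratory prescribing by medication class, treated
exacerbations (OCS/antibiotic courses), GP visits, hospital admissions
with lengths of stay, and deaths/deregistrations.  Two independently
corrupted *source extracts* are then derived from the same truth, so the
downstream linkage, phenotyping and outcome stages can be tested end to
end without any real patient data.

Model summary
-------------
* Disease labels are Bernoulli draws: asthma at its marginal prevalence
  over all adults, COPD at its prevalence among adults aged >=40.  A
  configurable fraction of COPD patients carries a co-morbid asthma
  label; the non-COPD asthma probability is adjusted downward so the
  marginal asthma prevalence is preserved.
* Exacerbation heterogeneity is a two-class Poisson mixture: a
  ``frequent_fraction`` of diseased patients exacerbate at
  ``exac_rate_frequent`` events/person-year and the rest at
  ``exac_rate_infrequent``.  Each event is recorded as the prescriptions
  that treat it (asthma: an OCS course; COPD: OCS and/or antibiotics).
* GP visits and admissions are homogeneous Poisson processes; death and
  deregistration are exponential hazards censoring every record stream.

All randomness flows from ``params.seed`` through a single
``numpy.random.Generator``; identical parameters give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .codelist import CodeList, load_codelist
from .core import JOURNAL_COLUMNS, SourceExtract

__all__ = [
    "GeneratorParams",
    "CorruptionProfile",
    "GroundTruthEMR",
    "generate_population",
    "corrupt_to_source",
    "build_verification_pair",
]

AGE_REFERENCE_DATE = pd.Timestamp("2008-12-31")
DAYS_PER_YEAR = 365.25

_DEFAULT_AGES: dict[str, dict[str, Any]] = {
    "background": {"dist": "uniform", "low": 18.0, "high": 90.0},
    "asthma": {"dist": "truncnorm", "mean": 33.1, "sd": 20.0, "low": 18.0, "high": 95.0},
    "copd": {"dist": "truncnorm", "mean": 61.1, "sd": 12.9, "low": 40.0, "high": 95.0},
}

# per-disease probability that a patient is on each medication class at all;
# flagged classes are issued as 28-day repeat prescriptions
_DEFAULT_PRESCRIBING: dict[str, dict[str, float]] = {
    "asthma": {
        "SABA": 0.94, "LABA": 0.10, "LAMA": 0.01, "LTRA": 0.04,
        "ICS": 0.42, "ICS_LABA": 0.40, "OCS_MAINT": 0.02,
    },
    "copd": {
        "SABA": 0.94, "LABA": 0.12, "LAMA": 0.36, "LTRA": 0.03,
        "ICS": 0.15, "ICS_LABA": 0.55, "OCS_MAINT": 0.03,
    },
}

_SMOKING_PROBS = {
    "asthma": (("current", 0.27), ("former", 0.32), ("never", 0.41)),
    "copd": (("current", 0.40), ("former", 0.52), ("never", 0.08)),
}

_CV_PROBS = {
    "background": {"mi": 0.02, "hypertension": 0.15, "stroke": 0.01, "heart_failure": 0.02},
    "asthma": {"mi": 0.03, "hypertension": 0.25, "stroke": 0.01, "heart_failure": 0.02},
    "copd": {"mi": 0.11, "hypertension": 0.50, "stroke": 0.05, "heart_failure": 0.10},
}

_FEV1 = {"asthma": (2.42, 0.83), "copd": (1.45, 0.60)}
_FEV1_PCT = {"asthma": (86.0, 18.4), "copd": (61.0, 19.7)}
_PEF_ASTHMA = (393.7, 123.8)


class GeneratorParams(BaseModel):
    """Tunable parameters of the synthetic population."""

    n_adults: int = Field(default=3504, ge=1)
    sex_fraction_male: float = Field(default=0.5025, ge=0.0, le=1.0)
    asthma_prevalence: float = Field(default=0.044, ge=0.0, le=1.0)
    copd_prevalence: float = Field(default=0.045, ge=0.0, le=1.0,
                                   description="prevalence among adults aged >=40")
    comorbid_asthma_given_copd: float = Field(default=0.384, ge=0.0, le=1.0)
    age_distribution: dict[str, dict[str, Any]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_AGES.items()})
    prescribing_probabilities: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PRESCRIBING.items()})
    exac_rate_frequent: float = Field(default=1.4, ge=0.0)
    exac_rate_infrequent: float = Field(default=0.4, ge=0.0)
    frequent_fraction: float = Field(default=0.25, ge=0.0, le=1.0)
    gp_visit_rate: float = Field(default=11.0, ge=0.0)
    hosp_rate_allcause: float = Field(default=0.30, ge=0.0)
    hosp_rate_respiratory: float = Field(default=0.06, ge=0.0)
    los_distribution: dict[str, Any] = Field(
        default_factory=lambda: {"dist": "lognormal", "mu": 1.6, "sigma": 0.8})
    death_hazard: float = Field(default=0.01, ge=0.0)
    transfer_hazard: float = Field(default=0.03, ge=0.0)
    study_window: tuple[date, date] = (date(2007, 1, 1), date(2010, 1, 1))
    measurement_prob: float = Field(default=0.8, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "GeneratorParams":
        if self.study_window[0] >= self.study_window[1]:
            raise ValueError("study_window: start_date must precede end_date")
        if self.hosp_rate_respiratory > self.hosp_rate_allcause:
            raise ValueError("hosp_rate_respiratory cannot exceed hosp_rate_allcause")
        for grp, probs in self.prescribing_probabilities.items():
            for cls, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(
                        f"prescribing_probabilities[{grp}][{cls}] must be in [0,1]")
        return self


class CorruptionProfile(BaseModel):
    """Source-specific record corruption applied to the ground truth."""

    drop_patient_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    drop_record_prob: dict[str, float] = Field(
        default_factory=lambda: {"prescription": 0.0, "event": 0.0})
    duplicate_record_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CorruptionProfile":
        for kind, p in self.drop_record_prob.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"drop_record_prob[{kind}] must be in [0,1]")
        return self


@dataclass
class GroundTruthEMR:
    """The uncorrupted population: patient roster plus full journal."""

    patients: pd.DataFrame
    journal: pd.DataFrame
    params: GeneratorParams = field(repr=False)

    @property
    def truth_links(self) -> dict[int, int]:
        ids = self.patients["person_id"].tolist()
        return {i: i for i in ids}


# ---------------------------------------------------------------------------
# small vectorisation helpers

def _ragged_arange(counts: np.ndarray) -> np.ndarray:
    """Concatenated ``arange(c)`` for each count c (no Python loop)."""
    counts = np.asarray(counts, dtype=int)
    if counts.sum() == 0:
        return np.empty(0, dtype=int)
    csum = np.cumsum(counts)
    out = np.arange(csum[-1]) - np.repeat(csum - counts, counts)
    return out


def _draw_ages(rng: np.random.Generator, spec: dict[str, Any], n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0)
    kind = spec.get("dist", "uniform")
    if kind == "uniform":
        return rng.uniform(spec["low"], spec["high"], n)
    if kind == "truncnorm":
        lo, hi = spec.get("low", 18.0), spec.get("high", 95.0)
        out = rng.normal(spec["mean"], spec["sd"], n)
        bad = (out < lo) | (out > hi)
        while bad.any():  # redraw; acceptance region is wide so this terminates fast
            out[bad] = rng.normal(spec["mean"], spec["sd"], bad.sum())
            bad = (out < lo) | (out > hi)
        return out
    raise ValueError(f"unknown age distribution: {kind!r}")


def _draw_los(rng: np.random.Generator, spec: dict[str, Any], n: int) -> np.ndarray:
    if n == 0:
        return np.empty(0, dtype=int)
    kind = spec.get("dist", "lognormal")
    if kind == "lognormal":
        los = rng.lognormal(spec.get("mu", 1.6), spec.get("sigma", 0.8), n)
    elif kind == "fixed":
        los = np.full(n, float(spec["days"]))
    else:
        raise ValueError(f"unknown LOS distribution: {kind!r}")
    return np.maximum(1, np.rint(los)).astype(int)


class _JournalBuilder:
    """Accumulates journal rows as column arrays; one concat at the end."""

    def __init__(self, start: pd.Timestamp, rng: np.random.Generator, codelist: CodeList):
        self.start = start
        self.rng = rng
        self.codelist = codelist
        self.chunks: list[pd.DataFrame] = []

    def _codes(self, concept: str, n: int) -> np.ndarray:
        pool = np.asarray(self.codelist.codes_for_concept(concept))
        return pool[self.rng.integers(0, len(pool), n)]

    def emit(self, person_ids: np.ndarray, kind: str, concept: str, days: np.ndarray,
             quantity=np.nan, daily_dose=np.nan, days_supply=None,
             value=None, discharge_days=None) -> None:
        n = len(person_ids)
        if n == 0:
            return
        days = np.asarray(days)
        chunk = pd.DataFrame({
            "person_id": np.asarray(person_ids, dtype=int),
            "record_kind": kind,
            "code": self._codes(concept, n),
            "date": self.start + pd.to_timedelta(np.floor(days).astype(int), unit="D"),
            "quantity": np.broadcast_to(np.asarray(quantity, dtype=float), n).copy(),
            "daily_dose": np.broadcast_to(np.asarray(daily_dose, dtype=float), n).copy(),
            "days_supply": (np.full(n, np.nan) if days_supply is None
                            else np.asarray(days_supply, dtype=float)),
            "value": (np.full(n, None, dtype=object) if value is None
                      else np.asarray(value, dtype=object)),
            "discharge_date": (pd.Series([pd.NaT] * n) if discharge_days is None
                               else self.start
                               + pd.to_timedelta(np.floor(discharge_days).astype(int), unit="D")),
        })
        self.chunks.append(chunk)

    def build(self) -> pd.DataFrame:
        if not self.chunks:
            cols = ["person_id"] + JOURNAL_COLUMNS[1:]
            return pd.DataFrame(columns=cols)
        df = pd.concat(self.chunks, ignore_index=True)
        df = df.sort_values(["person_id", "date", "record_kind", "code"],
                            kind="stable").reset_index(drop=True)
        df.insert(0, "record_id", np.arange(len(df), dtype=int))
        return df


# ---------------------------------------------------------------------------

def generate_population(params: GeneratorParams,
                        codelist: CodeList | None = None) -> GroundTruthEMR:
    """Generate the ground-truth roster and journal for one population."""
    codelist = codelist or load_codelist()
    rng = np.random.default_rng(params.seed)
    n = params.n_adults
    start = pd.Timestamp(params.study_window[0])
    end = pd.Timestamp(params.study_window[1])
    t_days = (end - start).days

    male = rng.random(n) < params.sex_fraction_male
    age = _draw_ages(rng, params.age_distribution["background"], n)

    copd = (age >= 40.0) & (rng.random(n) < params.copd_prevalence)
    copd_share = copd.mean()
    eff_comorbid = params.comorbid_asthma_given_copd if params.asthma_prevalence > 0 else 0.0
    if copd_share > 0:
        eff_comorbid = min(eff_comorbid, params.asthma_prevalence / copd_share)
    # adjust the non-COPD asthma probability so the marginal prevalence holds
    if copd_share < 1.0:
        p_non = (params.asthma_prevalence - copd_share * eff_comorbid) / (1.0 - copd_share)
    else:
        p_non = 0.0
    p_non = float(np.clip(p_non, 0.0, 1.0))
    u = rng.random(n)
    asthma = np.where(copd, u < eff_comorbid, u < p_non)

    # re-draw ages of diseased patients from their disease-specific distributions
    asthma_only = asthma & ~copd
    age[asthma_only] = _draw_ages(rng, params.age_distribution["asthma"], asthma_only.sum())
    age[copd] = _draw_ages(rng, params.age_distribution["copd"], copd.sum())
    diseased = asthma | copd

    birth = AGE_REFERENCE_DATE - pd.to_timedelta(np.floor(age * DAYS_PER_YEAR).astype(int),
                                                 unit="D")

    # censoring: exponential death / deregistration hazards from window start
    with np.errstate(divide="ignore"):
        t_death = (rng.exponential(1.0 / params.death_hazard, n) * DAYS_PER_YEAR
                   if params.death_hazard > 0 else np.full(n, np.inf))
        t_transfer = (rng.exponential(1.0 / params.transfer_hazard, n) * DAYS_PER_YEAR
                      if params.transfer_hazard > 0 else np.full(n, np.inf))
    active_end = np.minimum(np.minimum(t_death, t_transfer), float(t_days))
    active_end = np.maximum(active_end, 1.0)  # every patient contributes >=1 day
    active_years = active_end / DAYS_PER_YEAR
    died = (t_death <= t_transfer) & (t_death < t_days)
    transferred = (t_transfer < t_death) & (t_transfer < t_days)

    person_ids = np.arange(1, n + 1)
    jb = _JournalBuilder(start, rng, codelist)

    def _uniform_days(idx: np.ndarray, counts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        rep = np.repeat(idx, counts)
        days = rng.random(rep.size) * np.repeat(active_end[idx], counts)
        return rep, days

    # --- diagnoses (on or before 2008-12-31, within the journal window) ---
    dx_cutoff = min(float((AGE_REFERENCE_DATE - start).days + 1), float(t_days))
    for mask, concept in ((asthma, "asthma_dx"), (copd, "copd_dx")):
        idx = np.where(mask)[0]
        hi = np.minimum(active_end[idx], dx_cutoff)
        jb.emit(person_ids[idx], "event", concept, rng.random(idx.size) * hi)

    # --- repeat prescriptions by medication class ---
    class_concept = {"SABA": "saba", "LABA": "laba", "LAMA": "lama", "LTRA": "ltra",
                     "ICS": "ics", "ICS_LABA": "ics_laba", "OCS_MAINT": "ocs"}
    group = np.where(copd, "copd", np.where(asthma, "asthma", "none"))
    for grp in ("asthma", "copd"):
        probs = params.prescribing_probabilities.get(grp, {})
        in_grp = np.where(group == grp)[0]
        if in_grp.size == 0:
            continue
        for cls, p in probs.items():
            if cls not in class_concept:
                raise ValueError(f"unknown medication class in prescribing map: {cls!r}")
            flagged = in_grp[rng.random(in_grp.size) < p]
            if flagged.size == 0:
                continue
            if cls == "ICS_LABA":
                # most combination therapy is a single combined inhaler, the
                # rest is co-prescription of separate ICS and LABA inhalers
                combo = rng.random(flagged.size) < 0.8
                _emit_repeats(jb, rng, person_ids, active_end, flagged[combo], "ics_laba",
                              days_supply=28)
                sep = flagged[~combo]
                _emit_repeats(jb, rng, person_ids, active_end, sep, "ics", days_supply=28)
                _emit_repeats(jb, rng, person_ids, active_end, sep, "laba", days_supply=28)
            elif cls == "OCS_MAINT":
                _emit_repeats(jb, rng, person_ids, active_end, flagged, "ocs", days_supply=28)
            else:
                _emit_repeats(jb, rng, person_ids, active_end, flagged, class_concept[cls],
                              days_supply=28)

    # --- treated exacerbations: two-class Poisson mixture ---
    frequent = diseased & (rng.random(n) < params.frequent_fraction)
    lam = np.where(frequent, params.exac_rate_frequent, params.exac_rate_infrequent)
    ex_counts = np.where(diseased, rng.poisson(lam * active_years), 0)
    idx = np.where(ex_counts > 0)[0]
    rep, days = _uniform_days(idx, ex_counts[idx])
    is_copd_ev = copd[rep]
    # asthma events: an OCS course; COPD events: OCS and/or antibiotics
    comp = rng.random(rep.size)
    ocs_ev = ~is_copd_ev | (comp < 0.6)            # both (0.3) or OCS-only (0.3)
    abx_ev = is_copd_ev & ((comp < 0.3) | (comp >= 0.6))
    jb.emit(person_ids[rep[ocs_ev]], "prescription", "ocs", days[ocs_ev],
            quantity=1, daily_dose=40.0,
            days_supply=rng.integers(5, 8, int(ocs_ev.sum())).astype(float))
    jb.emit(person_ids[rep[abx_ev]], "prescription", "antibiotic", days[abx_ev],
            quantity=1, daily_dose=3.0,
            days_supply=np.full(int(abx_ev.sum()), 7.0))

    # --- GP visits (everyone) ---
    counts = rng.poisson(params.gp_visit_rate * active_years)
    idx = np.where(counts > 0)[0]
    rep, days = _uniform_days(idx, counts[idx])
    jb.emit(person_ids[rep], "event", "gp_visit", days)

    # --- admissions ---
    def _admissions(mask: np.ndarray, rate: float, concept: str) -> None:
        if rate <= 0:
            return
        counts = np.where(mask, rng.poisson(rate * active_years), 0)
        idx = np.where(counts > 0)[0]
        rep, days = _uniform_days(idx, counts[idx])
        los = _draw_los(rng, params.los_distribution, rep.size)
        disch = np.minimum(days + los, np.repeat(active_end[idx], counts[idx]))
        disch = np.maximum(disch, days)
        jb.emit(person_ids[rep], "event", concept, days, discharge_days=disch)

    _admissions(np.ones(n, bool), params.hosp_rate_allcause - params.hosp_rate_respiratory,
                "nonresp_admission")
    _admissions(diseased, params.hosp_rate_respiratory, "resp_admission")

    # --- baseline-year measurements for diseased patients ---
    y2008 = float((pd.Timestamp("2008-01-01") - start).days)
    y2008_end = float((pd.Timestamp("2009-01-01") - start).days)

    def _measure(idx: np.ndarray, concept: str, values: np.ndarray) -> None:
        alive = idx[active_end[idx] > y2008]
        if alive.size == 0:
            return
        hi = np.minimum(active_end[alive], y2008_end)
        days = y2008 + rng.random(alive.size) * (hi - y2008)
        jb.emit(person_ids[alive], "event", concept, days,
                value=np.asarray(values[:alive.size], dtype=object))

    for grp in ("asthma", "copd"):
        gi = np.where(group == grp)[0]
        if gi.size == 0:
            continue
        spiro = gi[rng.random(gi.size) < params.measurement_prob]
        m, s = _FEV1[grp]
        _measure(spiro, "fev1", np.round(np.clip(rng.normal(m, s, spiro.size), 0.3, 6.0), 2))
        m, s = _FEV1_PCT[grp]
        _measure(spiro, "fev1_pct_pred",
                 np.round(np.clip(rng.normal(m, s, spiro.size), 10.0, 150.0), 1))
        smk = gi[rng.random(gi.size) < 0.95]
        cats, ps = zip(*_SMOKING_PROBS[grp])
        _measure(smk, "smoking_status",
                 np.asarray(cats, dtype=object)[rng.choice(len(cats), smk.size,
                                                           p=np.asarray(ps) / sum(ps))])
        bmi = gi[rng.random(gi.size) < 0.85]
        _measure(bmi, "bmi", np.round(np.clip(rng.normal(27.5, 6.0, bmi.size), 14, 55), 1))
        if grp == "asthma":
            pef = gi[rng.random(gi.size) < 0.7]
            m, s = _PEF_ASTHMA
            _measure(pef, "pef", np.round(np.clip(rng.normal(m, s, pef.size), 60, 800), 0))

    # --- cardiovascular comorbidity codes (<= 2009-12-31, within activity) ---
    cv_cutoff = float((pd.Timestamp("2010-01-01") - start).days)
    for concept in ("mi", "hypertension", "stroke", "heart_failure"):
        p = np.array([_CV_PROBS[g][concept] for g in
                      np.where(group == "none", "background", group)])
        idx = np.where(rng.random(n) < p)[0]
        hi = np.minimum(active_end[idx], cv_cutoff)
        jb.emit(person_ids[idx], "event", concept, rng.random(idx.size) * hi)

    # --- registration exits ---
    d_idx = np.where(died)[0]
    jb.emit(person_ids[d_idx], "event", "death", active_end[d_idx] - 1e-9)
    x_idx = np.where(transferred)[0]
    jb.emit(person_ids[x_idx], "event", "deregistration", active_end[x_idx] - 1e-9)

    death_date = pd.Series(pd.NaT, index=range(n))
    death_date[died] = start + pd.to_timedelta(np.floor(active_end[died]).astype(int), "D")
    transfer_date = pd.Series(pd.NaT, index=range(n))
    transfer_date[transferred] = start + pd.to_timedelta(
        np.floor(active_end[transferred]).astype(int), "D")

    patients = pd.DataFrame({
        "person_id": person_ids,
        "sex": np.where(male, "M", "F"),
        "birth_date": birth,
        "death_date": death_date.values,
        "transfer_date": transfer_date.values,
        "has_asthma": asthma,
        "has_copd": copd,
        "frequent_exacerbator": frequent,
        "age_at_ref": np.floor(age).astype(int),
    })
    return GroundTruthEMR(patients=patients, journal=jb.build(), params=params)


def _emit_repeats(jb: _JournalBuilder, rng: np.random.Generator, person_ids: np.ndarray,
                  active_end: np.ndarray, idx: np.ndarray, concept: str,
                  days_supply: float, interval: float = 28.0) -> None:
    """28-day repeat prescriptions from a random phase until censoring."""
    if idx.size == 0:
        return
    phase = rng.uniform(0, interval, idx.size)
    counts = np.maximum(0, np.ceil((active_end[idx] - phase) / interval)).astype(int)
    rep = np.repeat(idx, counts)
    k = _ragged_arange(counts)
    days = np.repeat(phase, counts) + interval * k
    jb.emit(person_ids[rep], "prescription", concept, days,
            quantity=1, daily_dose=2.0,
            days_supply=np.full(rep.size, float(days_supply)))


# ---------------------------------------------------------------------------

def corrupt_to_source(truth: GroundTruthEMR, profile: CorruptionProfile,
                      source_name: str) -> SourceExtract:
    """Derive one source extract: drop patients/records, duplicate records,
    and re-key patients with source-specific pseudonyms."""
    rng = np.random.default_rng(profile.seed)
    pats = truth.patients
    n = len(pats)

    keep = rng.random(n) >= profile.drop_patient_prob
    kept = pats[keep].reset_index(drop=True)

    # pseudonyms assigned in a shuffled order so key rank leaks no identity
    order = rng.permutation(len(kept))
    pseudo = np.empty(len(kept), dtype=object)
    pseudo[order] = [f"{source_name}{i + 1:06d}" for i in range(len(kept))]
    key_of = dict(zip(kept["person_id"], pseudo))

    patients = pd.DataFrame({
        "patient_key": pseudo,
        "age": kept["age_at_ref"].astype(int),
        "sex": kept["sex"],
    }).sort_values("patient_key").reset_index(drop=True)

    j = truth.journal[truth.journal["person_id"].isin(set(kept["person_id"]))].copy()
    drop_p = j["record_kind"].map(lambda k: profile.drop_record_prob.get(k, 0.0)).to_numpy()
    j = j[rng.random(len(j)) >= drop_p]
    if profile.duplicate_record_prob > 0 and len(j):
        dup = j[rng.random(len(j)) < profile.duplicate_record_prob]
        j = pd.concat([j, dup], ignore_index=True)
    j = j.copy()
    j["patient_key"] = j["person_id"].map(key_of)
    journal = j[["patient_key"] + JOURNAL_COLUMNS[1:]].sort_values(
        ["patient_key", "date", "record_kind", "code"], kind="stable").reset_index(drop=True)

    return SourceExtract(source_name=source_name, patients=patients, journal=journal,
                         key_map={k: int(p) for p, k in key_of.items()})


# ---------------------------------------------------------------------------

def build_verification_pair(
    n_registry: int = 3504,
    n_matched: int = 3453,
    n_unique_a: int = 27,
    n_unique_b: int = 10,
    n_prescriptions: int = 94_070,
    rx_only_a: int = 10,
    rx_only_b: int = 3,
    n_diagnoses: int = 29_830,
    dx_only_a_condition: int = 2,
    dx_only_b: int = 272,
    condition_both: int = 75,
    source_a: str = "SIR",
    source_b: str = "Apollo",
) -> tuple[SourceExtract, SourceExtract, int]:
    """Deterministically construct a two-source pair with exact discordance
    counts, emulating a dual-verification exercise on one GP practice.

    Defaults reproduce the worked concordance arithmetic: 3453 of 3504
    registered adults matched, 13 of 94,070 merged prescription records
    unmatched, 272 diagnosis records missing from source A, and a COPD
    patient-level agreement table of (75 both, 2 A-only, 1 B-only).
    ``dx_only_b`` includes one COPD record (the B-only COPD patient);
    ``dx_only_a_condition`` COPD records appear in A only.
    Returns ``(extract_a, extract_b, n_registry)``.
    """
    if n_matched + n_unique_a > n_registry or n_matched + n_unique_b > n_registry:
        raise ValueError("source totals cannot exceed the registry total")
    day0 = pd.Timestamp("2008-01-01")

    mkeys = np.array([f"P{i:06d}" for i in range(n_matched)], dtype=object)
    ages = 20 + (np.arange(n_matched) % 70)
    sexes = np.where(np.arange(n_matched) % 2 == 0, "F", "M")

    def _rows(keys, kinds, codes, days, supply=None):
        n = len(keys)
        return pd.DataFrame({
            "patient_key": keys, "record_kind": kinds, "code": codes,
            "date": day0 + pd.to_timedelta(days, unit="D"),
            "quantity": 1.0, "daily_dose": np.nan,
            "days_supply": np.nan if supply is None else float(supply),
            "value": pd.Series([None] * n, dtype=object),
            "discharge_date": pd.Series([pd.NaT] * n),
        })

    def _spread(n_rows: int, day_base: int) -> tuple[np.ndarray, np.ndarray]:
        i = np.arange(n_rows)
        return mkeys[i % n_matched], day_base + i // n_matched

    a_parts, b_parts = [], []

    # prescriptions: shared block plus a handful unique to each source
    n_shared_rx = n_prescriptions - rx_only_a - rx_only_b
    keys, days = _spread(n_shared_rx, 0)
    shared_rx = _rows(keys, "prescription", "RXS01", days, supply=28)
    a_parts.append(shared_rx)
    b_parts.append(shared_rx)
    keys, days = _spread(rx_only_a, 400)
    a_parts.append(_rows(keys, "prescription", "RXI01", days, supply=28))
    keys, days = _spread(rx_only_b, 450)
    b_parts.append(_rows(keys, "prescription", "RXL01", days, supply=28))

    # diagnosis (event) records: COPD concordance is engineered patient-wise
    copd_a_only = dx_only_a_condition
    copd_b_only = 1 if dx_only_b > 0 else 0
    shared_dx = n_diagnoses - dx_only_a_condition - dx_only_b - condition_both
    keys, days = _spread(shared_dx, 100)
    plain = _rows(keys, "event", "CVH01", days)
    a_parts.append(plain)
    b_parts.append(plain)
    copd_shared = _rows(mkeys[:condition_both], "event", "CPD01",
                        np.full(condition_both, 130))
    a_parts.append(copd_shared)
    b_parts.append(copd_shared)
    a_parts.append(_rows(mkeys[condition_both:condition_both + copd_a_only], "event",
                         "CPD02", np.full(copd_a_only, 131)))
    b_parts.append(_rows(mkeys[condition_both + copd_a_only:
                               condition_both + copd_a_only + copd_b_only],
                         "event", "CPD03", np.full(copd_b_only, 132)))
    n_plain_b = dx_only_b - copd_b_only
    keys, days = _spread(n_plain_b, 200)
    b_parts.append(_rows(keys, "event", "CVM01", days))

    # patients seen by only one source each get a single contact record
    akeys_u = np.array([f"UA{i:05d}" for i in range(n_unique_a)], dtype=object)
    bkeys_u = np.array([f"UB{i:05d}" for i in range(n_unique_b)], dtype=object)
    if n_unique_a:
        a_parts.append(_rows(akeys_u, "event", "GPV01", np.full(n_unique_a, 10)))
    if n_unique_b:
        b_parts.append(_rows(bkeys_u, "event", "GPV01", np.full(n_unique_b, 11)))

    pat_matched = pd.DataFrame({"patient_key": mkeys, "age": ages, "sex": sexes})
    pat_a = pd.concat([pat_matched, pd.DataFrame({
        "patient_key": akeys_u, "age": 50, "sex": "F"})], ignore_index=True)
    pat_b = pd.concat([pat_matched, pd.DataFrame({
        "patient_key": bkeys_u, "age": 51, "sex": "M"})], ignore_index=True)

    a = SourceExtract(source_a, pat_a, pd.concat(a_parts, ignore_index=True))
    b = SourceExtract(source_b, pat_b, pd.concat(b_parts, ignore_index=True))
    return a, b, n_registry
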