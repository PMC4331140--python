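"""Rule-based event alerting over daily-batch journal feeds.

The linked database receives 24-hour incremental downloads; an alert
rule watches for selected coded events — optionally with a value
threshold or a count-within-window condition — and fires on the batch in
which the condition is first satisfied.  Ingestion is idempotent:
replaying an identical batch emits no duplicate alerts.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date
from pathlib import Path

import pandas as pd
import yaml
from pydantic import BaseModel, Field, model_validator

from .codelist import CodeList, load_codelist

__all__ = ["AlertRule", "Alert", "AlertEngine", "load_rules"]

_OPS = {
    ">": lambda a, b: a > b,
    ">=": lambda a, b: a >= b,
    "<": lambda a, b: a < b,
    "<=": lambda a, b: a <= b,
    "==": lambda a, b: a == b,
}


class AlertRule(BaseModel):
    """One predicate over the incoming record stream."""

    rule_id: str
    concepts: list[str] = Field(min_length=1)
    value_op: str | None = None
    value_threshold: float | None = None
    count_min: int = Field(default=1, ge=1)
    window_days: int | None = Field(default=None, ge=1)
    cohort_scope: list[str] | None = None   # None = all patients
    active_window: tuple[date, date] | None = None

    @model_validator(mode="after")
    def _check(self) -> "AlertRule":
        if (self.value_op is None) != (self.value_threshold is None):
            raise ValueError(f"rule {self.rule_id}: value_op and value_threshold "
                             "must be given together")
        if self.value_op is not None and self.value_op not in _OPS:
            raise ValueError(f"rule {self.rule_id}: unknown comparator {self.value_op!r}")
        if self.count_min > 1 and self.window_days is None:
            raise ValueError(f"rule {self.rule_id}: count_min > 1 requires window_days")
        if self.active_window and self.active_window[0] >= self.active_window[1]:
            raise ValueError(f"rule {self.rule_id}: active_window must be well-ordered")
        return self


@dataclass(frozen=True)
class Alert:
    rule_id: str
    patient_key: str
    trigger_record_ids: tuple[int, ...]
    fire_date: pd.Timestamp

    def to_dict(self) -> dict:
        return {"rule_id": self.rule_id, "patient_key": self.patient_key,
                "trigger_record_ids": list(self.trigger_record_ids),
                "fire_date": str(self.fire_date.date())}


def load_rules(path: str | Path) -> list[AlertRule]:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or []
    return [AlertRule(**r) for r in raw]


class AlertEngine:
    """Evaluates rules batch by batch, retaining per-(rule, patient)
    event-window state for count-in-window predicates."""

    def __init__(self, rules: list[AlertRule], codelist: CodeList | None = None):
        self.codelist = codelist or load_codelist()
        self.rules = list(rules)
        self._codes: dict[str, set[str]] = {}
        for r in self.rules:
            self._codes[r.rule_id] = set(self.codelist.codes_for_concepts(r.concepts))
        # state: matching records seen so far, keyed by (rule, patient)
        self._seen: dict[tuple[str, str], list[tuple[pd.Timestamp, int]]] = {}
        self._seen_record_ids: dict[str, set[int]] = {r.rule_id: set() for r in self.rules}
        self._emitted: set[tuple[str, str, tuple[int, ...]]] = set()
        self.alerts: list[Alert] = []

    # -- ingestion ---------------------------------------------------------
    def ingest_batch(self, records: pd.DataFrame, batch_date) -> list[Alert]:
        batch_date = pd.Timestamp(batch_date)
        if len(records) and (records["date"] > batch_date).any():
            bad = records.loc[records["date"] > batch_date].iloc[0]
            raise ValueError(
                f"record {int(bad['record_id'])} dated {bad['date'].date()} "
                f"is after batch date {batch_date.date()}")
        new_alerts: list[Alert] = []
        for rule in self.rules:
            sel = records[records["code"].isin(self._codes[rule.rule_id])]
            if rule.active_window is not None:
                lo, hi = (pd.Timestamp(rule.active_window[0]),
                          pd.Timestamp(rule.active_window[1]))
                sel = sel[(sel["date"] >= lo) & (sel["date"] < hi)]
            if rule.cohort_scope is not None:
                sel = sel[sel["patient_key"].isin(set(rule.cohort_scope))]
            if rule.value_op is not None:
                vals = pd.to_numeric(sel["value"], errors="coerce")
                sel = sel[_OPS[rule.value_op](vals, rule.value_threshold).fillna(False)]
            seen_ids = self._seen_record_ids[rule.rule_id]
            sel = sel[~sel["record_id"].isin(seen_ids)]
            for row in sel.sort_values(["patient_key", "date", "record_id"]).itertuples():
                seen_ids.add(row.record_id)
                state_key = (rule.rule_id, row.patient_key)
                buf = self._seen.setdefault(state_key, [])
                buf.append((row.date, row.record_id))
                if rule.window_days is not None:
                    cutoff = row.date - pd.Timedelta(days=rule.window_days)
                    buf[:] = [(d, i) for d, i in buf if d >= cutoff]
                in_window = buf if rule.window_days is not None else [(row.date, row.record_id)]
                if len(in_window) >= rule.count_min:
                    trig = tuple(sorted(i for _, i in in_window[-rule.count_min:]))
                    key = (rule.rule_id, row.patient_key, trig)
                    if key not in self._emitted:
                        self._emitted.add(key)
                        alert = Alert(rule.rule_id, row.patient_key, trig, batch_date)
                        self.alerts.append(alert)
                        new_alerts.append(alert)
        return new_alerts

    # -- reporting ---------------------------------------------------------
    def activity_summary(self, on_date) -> dict:
        """Per-rule alert counts and patient lists for one batch day."""
        on_date = pd.Timestamp(on_date)
        todays = [a for a in self.alerts if a.fire_date == on_date]
        per_rule: dict[str, dict] = {}
        for a in todays:
            entry = per_rule.setdefault(a.rule_id, {"count": 0, "patients": []})
            entry["count"] += 1
            if a.patient_key not in entry["patients"]:
                entry["patients"].append(a.patient_key)
        return {"date": str(on_date.date()), "total_alerts": len(todays),
                "rules": per_rule}
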