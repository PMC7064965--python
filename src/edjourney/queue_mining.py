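"""Leakage-free queueing features from an event log.

A :class:`FeatureVector` is a snapshot of everything the waiting-time
model may know about one (patient, procedure) at time ``t``: time and
patient statics, journey state (completed and anticipated procedures),
and dynamic workload (queue length, service rate, the last wait that
ended, ED census).  Every field is computed exclusively from records
with timestamps <= t, so a snapshot on the full log equals the snapshot
on the t-truncated log.

Definitions
-----------
queue membership  ordered, not yet started (and not yet completed);
census            arrived and not yet discharged;
wait              minutes from order to service start by default,
                  configurable to order -> completion for logs that
                  record only completions;
service rate      completions/hour in the trailing window W (default
                  2 h); when the window is empty it falls back to the
                  long-run rate over the whole log so far, flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .discovery import AnticipationRule
from .event_log import EventLog

DEFAULT_WINDOW = timedelta(hours=2)

FEATURE_COLUMNS = [
    "hour_of_day",
    "weekday",
    "triage",
    "arrival_mode",
    "age",
    "gender",
    "n_completed",
    "n_anticipated",
    "queue_length",
    "service_rate",
    "last_wait",
    "ed_census",
]


class PreconditionError(ValueError):
    """The focal patient is not present in the ED at time t."""


@dataclass
class FeatureVector:
    hour_of_day: int
    weekday: int
    triage: int
    arrival_mode: str
    age: int
    gender: str
    completed_procedures: frozenset = frozenset()
    anticipated_procedures: frozenset = frozenset()
    queue_length: int = 0
    service_rate: float = 0.0
    last_wait: float = 0.0
    ed_census: int = 1
    service_rate_fallback: bool = False

    def to_row(self) -> dict:
        """Numeric encoding used by the learning model."""
        return {
            "hour_of_day": self.hour_of_day,
            "weekday": self.weekday,
            "triage": self.triage,
            "arrival_mode": 1 if self.arrival_mode == "ambulance" else 0,
            "age": self.age,
            "gender": 1 if self.gender == "M" else 0,
            "n_completed": len(self.completed_procedures),
            "n_anticipated": len(self.anticipated_procedures),
            "queue_length": self.queue_length,
            "service_rate": self.service_rate,
            "last_wait": self.last_wait,
            "ed_census": self.ed_census,
        }


class LogIndex:
    """Vectorized view of a log for fast snapshot computation.

    Building the index once and passing it to :func:`snapshot` or
    :func:`build_training_table` avoids re-scanning the log per call;
    the computed values are identical either way.
    """

    def __init__(self, log: EventLog):
        self.log = log
        nat = np.datetime64("NaT")

        def ts(t):
            return np.datetime64(t, "m") if t is not None else nat

        self.ev_patient = np.array([e.patient_id for e in log.events], dtype=object)
        self.ev_proc = np.array(
            [e.procedure or e.activity for e in log.events], dtype=object
        )
        dt64 = "datetime64[m]"
        self.ev_ordered = np.array([ts(e.ordered_at) for e in log.events], dtype=dt64)
        self.ev_started = np.array([ts(e.started_at) for e in log.events], dtype=dt64)
        self.ev_completed = np.array([ts(e.completed_at) for e in log.events], dtype=dt64)
        pats = list(log.patients.values())
        self.p_id = np.array([p.patient_id for p in pats], dtype=object)
        self.p_arrival = np.array([ts(p.arrival_time) for p in pats], dtype=dt64)
        self.p_discharge = np.array([ts(p.discharge_time) for p in pats], dtype=dt64)
        anchors = self.ev_ordered[~np.isnat(self.ev_ordered)]
        self.t0 = (
            min(anchors.min(), self.p_arrival.min())
            if len(self.p_arrival) and len(anchors)
            else (self.p_arrival.min() if len(self.p_arrival) else None)
        )

    # -- helpers; all comparisons are conditioned on <= t (leakage-free) --
    def _proc_mask(self, procedure: str | None) -> np.ndarray:
        if procedure is None:
            return np.ones(len(self.ev_proc), dtype=bool)
        return self.ev_proc == procedure

    def queue_length(self, procedure: str | None, t: np.datetime64) -> int:
        m = self._proc_mask(procedure)
        queued = (
            (self.ev_ordered <= t)
            & ~(self.ev_started <= t)
            & ~(self.ev_completed <= t)
        )
        return int(np.sum(m & queued))

    def census(self, t: np.datetime64) -> int:
        return int(np.sum((self.p_arrival <= t) & ~(self.p_discharge <= t)))

    def service_rate(
        self, procedure: str | None, t: np.datetime64, window: timedelta
    ) -> tuple[float, bool]:
        m = self._proc_mask(procedure)
        w = np.timedelta64(int(window.total_seconds() // 60), "m")
        recent = m & (self.ev_completed <= t) & (self.ev_completed > t - w)
        n = int(np.sum(recent))
        if n > 0:
            return n / (window.total_seconds() / 3600.0), False
        # cold start: long-run rate over the whole log so far
        ever = m & (self.ev_completed <= t)
        n_ever = int(np.sum(ever))
        hours = (
            float((t - self.t0) / np.timedelta64(1, "m")) / 60.0
            if self.t0 is not None
            else 0.0
        )
        rate = n_ever / hours if hours > 0 else 0.0
        return rate, True

    def last_wait(self, procedure: str | None, t: np.datetime64) -> float:
        m = (
            self._proc_mask(procedure)
            & (self.ev_started <= t)
            & ~np.isnat(self.ev_ordered)
        )
        if not m.any():
            return 0.0
        idx = np.argmax(np.where(m, self.ev_started, np.datetime64("1677-09-22", "m")))
        wait = (self.ev_started[idx] - self.ev_ordered[idx]) / np.timedelta64(1, "m")
        return float(max(wait, 0.0))

    def patient_events(self, patient_id: str) -> np.ndarray:
        return self.ev_patient == patient_id


def snapshot(
    log: EventLog,
    patient_id: str,
    procedure: str | None,
    t: datetime,
    rules: Iterable[AnticipationRule] = (),
    window: timedelta = DEFAULT_WINDOW,
    index: LogIndex | None = None,
) -> FeatureVector:
    """Feature snapshot for one (patient, procedure) at time ``t``.

    ``procedure=None`` yields the ED-level variant (workload aggregated
    over all procedures) used by the length-of-stay model.
    """
    if index is None:
        index = LogIndex(log)
    patient = log.patients.get(patient_id)
    if patient is None:
        raise PreconditionError(f"unknown patient {patient_id!r}")
    if patient.arrival_time > t or (
        patient.discharge_time is not None and patient.discharge_time <= t
    ):
        raise PreconditionError(f"patient {patient_id!r} not present at {t}")

    tt = np.datetime64(t, "m")
    mine = index.patient_events(patient_id)
    completed = frozenset(index.ev_proc[mine & (index.ev_completed <= tt)])
    ordered = frozenset(index.ev_proc[mine & (index.ev_ordered <= tt)])
    anticipated = frozenset(
        r.consequent
        for r in rules
        if r.antecedent in (completed | ordered) and r.consequent not in completed
    )
    rate, fallback = index.service_rate(procedure, tt, window)
    return FeatureVector(
        hour_of_day=t.hour,
        weekday=t.weekday(),
        triage=patient.triage,
        arrival_mode=patient.arrival_mode,
        age=patient.age,
        gender=patient.gender,
        completed_procedures=completed,
        anticipated_procedures=anticipated,
        queue_length=index.queue_length(procedure, tt),
        service_rate=rate,
        last_wait=index.last_wait(procedure, tt),
        ed_census=index.census(tt),
        service_rate_fallback=fallback,
    )


class TrainingTable(NamedTuple):
    frame: pd.DataFrame
    n_rows: int
    n_excluded: int


def build_training_table(
    log: EventLog,
    rules: Iterable[AnticipationRule] = (),
    window: timedelta = DEFAULT_WINDOW,
    wait_endpoint: str = "started",
) -> TrainingTable:
    """One row per (patient, procedure) order: the feature snapshot taken
    at order time plus the realized wait in minutes.

    Rows whose wait endpoint (service start by default, completion with
    ``wait_endpoint='completed'``) is missing are excluded and counted —
    e.g. lab records written only at completion.
    """
    if wait_endpoint not in ("started", "completed"):
        raise ValueError("wait_endpoint must be 'started' or 'completed'")
    index = LogIndex(log)
    rules = list(rules)
    rows = []
    excluded = 0
    for e in log.events:
        proc = e.procedure or e.activity
        endpoint = e.started_at if wait_endpoint == "started" else e.completed_at
        if e.ordered_at is None or endpoint is None:
            # missing wait endpoint (e.g. lab order recorded only at
            # completion): unusable as a supervised example
            excluded += 1
            continue
        if e.patient_id not in log.patients:
            excluded += 1
            continue
        try:
            fv = snapshot(
                log, e.patient_id, proc, e.ordered_at, rules, window, index=index
            )
        except PreconditionError:
            excluded += 1
            continue
        row = fv.to_row()
        row["patient_id"] = e.patient_id
        row["procedure"] = proc
        row["ordered_at"] = e.ordered_at
        row["wait_minutes"] = (endpoint - e.ordered_at).total_seconds() / 60.0
        rows.append(row)
    frame = pd.DataFrame(
        rows,
        columns=FEATURE_COLUMNS + ["patient_id", "procedure", "ordered_at", "wait_minutes"],
    )
    return TrainingTable(frame, len(rows), excluded)


def build_los_table(
    log: EventLog,
    rules: Iterable[AnticipationRule] = (),
    window: timedelta = DEFAULT_WINDOW,
) -> pd.DataFrame:
    """One row per discharged patient: the ED-level snapshot at arrival
    plus the realized length of stay in minutes."""
    index = LogIndex(log)
    rules = list(rules)
    rows = []
    for pid, p in log.patients.items():
        if p.discharge_time is None:
            continue
        fv = snapshot(log, pid, None, p.arrival_time, rules, window, index=index)
        row = fv.to_row()
        row["patient_id"] = pid
        row["los_minutes"] = (p.discharge_time - p.arrival_time).total_seconds() / 60.0
        rows.append(row)
    return pd.DataFrame(rows, columns=FEATURE_COLUMNS + ["patient_id", "los_minutes"])
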