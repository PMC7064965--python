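"""Canonical event-log data model for emergency-department journeys.

An ED event log has one record per procedure occurrence per patient, with
up to three timestamps: when the procedure was ordered, when service
started, and when it completed.  Granular *activities* (e.g. "hemoglobin")
are aggregated into patient-facing *procedures* (e.g. "lab tests").

Timestamps are ISO-8601 at minute resolution in a single implicit
timezone; nulls are serialized as empty CSV fields / JSON nulls.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path
from typing import Iterable, Mapping


TIME_FORMATS = ("%Y-%m-%dT%H:%M", "%Y-%m-%d %H:%M", "%Y-%m-%dT%H:%M:%S")

EVENT_COLUMNS = [
    "patient_id",
    "activity",
    "procedure",
    "ordered_at",
    "started_at",
    "completed_at",
    "location",
]
PATIENT_COLUMNS = [
    "patient_id",
    "arrival_time",
    "discharge_time",
    "triage",
    "arrival_mode",
    "age",
    "gender",
]

ARRIVAL_MODES = ("walk-in", "ambulance")


class SchemaError(ValueError):
    """A required column is missing or a field cannot be parsed."""


class LogValidationError(ValueError):
    """One or more records violate the log invariants."""

    def __init__(self, problems: list[str]):
        self.problems = problems
        super().__init__("; ".join(problems))


def parse_timestamp(text: str | None, *, row: int | None = None) -> datetime | None:
    """Parse an ISO-8601 minute-resolution timestamp; '' / None -> None."""
    if text is None or text == "":
        return None
    for fmt in TIME_FORMATS:
        try:
            return datetime.strptime(text, fmt).replace(second=0, microsecond=0)
        except ValueError:
            continue
    where = f" (row {row})" if row is not None else ""
    raise SchemaError(f"unparseable timestamp {text!r}{where}")


def format_timestamp(t: datetime | None) -> str:
    return "" if t is None else t.strftime("%Y-%m-%dT%H:%M")


@dataclass
class Event:
    """One procedure occurrence for one patient.

    ``activity`` is the granular record label; ``procedure`` the
    aggregated patient-facing label (may be unset before aggregation).
    """

    patient_id: str
    activity: str
    ordered_at: datetime | None
    started_at: datetime | None = None
    completed_at: datetime | None = None
    procedure: str | None = None
    location: str = ""

    def sort_key(self):
        far = datetime.max
        return (
            self.patient_id,
            self.ordered_at or self.started_at or self.completed_at or far,
            self.completed_at or far,
            self.procedure or self.activity,
        )


@dataclass
class Patient:
    patient_id: str
    arrival_time: datetime
    discharge_time: datetime | None = None
    triage: int = 3
    arrival_mode: str = "walk-in"
    age: int = 40
    gender: str = "F"


@dataclass
class EventLog:
    """A validated collection of patients and their procedure events."""

    patients: dict[str, Patient] = field(default_factory=dict)
    events: list[Event] = field(default_factory=list)
    aggregation_map: dict[str, str] = field(default_factory=dict)

    # ------------------------------------------------------------------
    def sort(self) -> "EventLog":
        """Sort events into the canonical order (in place); returns self."""
        self.events.sort(key=Event.sort_key)
        return self

    def validate(self) -> None:
        problems: list[str] = []
        for pid, p in self.patients.items():
            if not pid:
                problems.append("empty patient_id in patient table")
            if not 1 <= int(p.triage) <= 5:
                problems.append(f"patient {pid}: triage {p.triage} outside 1-5")
            if p.discharge_time is not None and p.discharge_time < p.arrival_time:
                problems.append(f"patient {pid}: discharge before arrival")
        for i, e in enumerate(self.events):
            tag = f"event {i} ({e.patient_id}/{e.activity})"
            if not e.patient_id:
                problems.append(f"{tag}: empty patient_id")
            if not e.activity:
                problems.append(f"{tag}: empty activity")
            if e.patient_id not in self.patients:
                problems.append(f"{tag}: unknown patient")
            ts = [t for t in (e.ordered_at, e.started_at, e.completed_at) if t is not None]
            if e.ordered_at is not None and e.started_at is not None and e.started_at < e.ordered_at:
                problems.append(f"{tag}: started_at before ordered_at")
            if e.ordered_at is not None and e.completed_at is not None and e.completed_at < e.ordered_at:
                problems.append(f"{tag}: completed_at before ordered_at")
            if e.started_at is not None and e.completed_at is not None and e.completed_at < e.started_at:
                problems.append(f"{tag}: completed_at before started_at")
            del ts
        if problems:
            raise LogValidationError(problems)

    # ------------------------------------------------------------------
    def truncate(self, t: datetime) -> "EventLog":
        """The log as it would have been recorded at time ``t``.

        Patients arrived after ``t`` and events ordered after ``t`` are
        dropped; start/completion/discharge timestamps after ``t`` are
        masked to None (not yet recorded).
        """
        patients = {}
        for pid, p in self.patients.items():
            if p.arrival_time > t:
                continue
            q = replace(p)
            if q.discharge_time is not None and q.discharge_time > t:
                q.discharge_time = None
            patients[pid] = q
        events = []
        for e in self.events:
            anchor = e.ordered_at or e.started_at or e.completed_at
            if anchor is None or anchor > t:
                continue
            f = replace(e)
            if f.started_at is not None and f.started_at > t:
                f.started_at = None
            if f.completed_at is not None and f.completed_at > t:
                f.completed_at = None
            events.append(f)
        return EventLog(patients, events, dict(self.aggregation_map))


# ----------------------------------------------------------------------
# I/O
# ----------------------------------------------------------------------

def _require_columns(header: Iterable[str], required: Iterable[str], what: str) -> None:
    missing = [c for c in required if c not in header]
    if missing:
        raise SchemaError(f"{what}: missing required column(s) {', '.join(missing)}")


def _events_from_rows(rows: list[dict]) -> list[Event]:
    events = []
    for i, r in enumerate(rows):
        events.append(
            Event(
                patient_id=str(r.get("patient_id") or ""),
                activity=str(r.get("activity") or ""),
                procedure=(str(r["procedure"]) if r.get("procedure") else None),
                ordered_at=parse_timestamp(r.get("ordered_at"), row=i),
                started_at=parse_timestamp(r.get("started_at"), row=i),
                completed_at=parse_timestamp(r.get("completed_at"), row=i),
                location=str(r.get("location") or ""),
            )
        )
    return events


def _patients_from_rows(rows: list[dict]) -> dict[str, Patient]:
    patients = {}
    for i, r in enumerate(rows):
        arrival = parse_timestamp(r.get("arrival_time"), row=i)
        if arrival is None:
            raise SchemaError(f"patient row {i}: arrival_time is required")
        p = Patient(
            patient_id=str(r.get("patient_id") or ""),
            arrival_time=arrival,
            discharge_time=parse_timestamp(r.get("discharge_time"), row=i),
            triage=int(r["triage"]) if r.get("triage") not in (None, "") else 3,
            arrival_mode=str(r.get("arrival_mode") or "walk-in"),
            age=int(r["age"]) if r.get("age") not in (None, "") else 40,
            gender=str(r.get("gender") or "F"),
        )
        patients[p.patient_id] = p
    return patients


def _read_csv_rows(path: Path, required: list[str], what: str) -> list[dict]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise SchemaError(f"{what}: file {path} has no header")
        _require_columns(reader.fieldnames, required, what)
        return list(reader)


def read_log(path: str | Path, format: str | None = None) -> EventLog:
    """Read an event log from ``path``.

    ``format='csv'`` expects a directory with ``events.csv`` and
    ``patients.csv`` (plus optional ``aggregation_map.csv``);
    ``format='json'`` a single JSON file.  Row order in the files does
    not affect the result: events are returned in canonical order.
    """
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "json":
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
        for key in ("patients", "events"):
            if key not in doc:
                raise SchemaError(f"JSON log: missing top-level key {key!r}")
        log = EventLog(
            patients=_patients_from_rows(doc["patients"]),
            events=_events_from_rows(doc["events"]),
            aggregation_map=dict(doc.get("aggregation_map") or {}),
        )
    elif format == "csv":
        event_rows = _read_csv_rows(path / "events.csv", ["patient_id", "activity", "ordered_at"], "events.csv")
        patient_rows = _read_csv_rows(path / "patients.csv", ["patient_id", "arrival_time"], "patients.csv")
        log = EventLog(
            patients=_patients_from_rows(patient_rows),
            events=_events_from_rows(event_rows),
        )
        amap = path / "aggregation_map.csv"
        if amap.exists():
            rows = _read_csv_rows(amap, ["activity", "procedure"], "aggregation_map.csv")
            log.aggregation_map = {r["activity"]: r["procedure"] for r in rows}
    else:
        raise ValueError(f"unknown format {format!r}")
    log.sort()
    log.validate()
    return log


def _event_row(e: Event) -> dict:
    return {
        "patient_id": e.patient_id,
        "activity": e.activity,
        "procedure": e.procedure or "",
        "ordered_at": format_timestamp(e.ordered_at),
        "started_at": format_timestamp(e.started_at),
        "completed_at": format_timestamp(e.completed_at),
        "location": e.location,
    }


def _patient_row(p: Patient) -> dict:
    return {
        "patient_id": p.patient_id,
        "arrival_time": format_timestamp(p.arrival_time),
        "discharge_time": format_timestamp(p.discharge_time),
        "triage": p.triage,
        "arrival_mode": p.arrival_mode,
        "age": p.age,
        "gender": p.gender,
    }


def write_log(log: EventLog, path: str | Path, format: str | None = None) -> None:
    """Write ``log`` so that :func:`read_log` round-trips it exactly."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix == ".json" else "csv"
    if format == "json":
        doc = {
            "patients": [_patient_row(p) for p in log.patients.values()],
            "events": [_event_row(e) for e in log.events],
            "aggregation_map": log.aggregation_map,
        }
        # JSON nulls for missing timestamps
        for row in doc["events"]:
            for k in ("started_at", "completed_at", "ordered_at"):
                if row[k] == "":
                    row[k] = None
        for row in doc["patients"]:
            if row["discharge_time"] == "":
                row["discharge_time"] = None
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)
    elif format == "csv":
        path.mkdir(parents=True, exist_ok=True)
        with open(path / "events.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=EVENT_COLUMNS)
            w.writeheader()
            for e in log.events:
                w.writerow(_event_row(e))
        with open(path / "patients.csv", "w", newline="", encoding="utf-8") as fh:
            w = csv.DictWriter(fh, fieldnames=PATIENT_COLUMNS)
            w.writeheader()
            for p in log.patients.values():
                w.writerow(_patient_row(p))
        if log.aggregation_map:
            with open(path / "aggregation_map.csv", "w", newline="", encoding="utf-8") as fh:
                w = csv.DictWriter(fh, fieldnames=["activity", "procedure"])
                w.writeheader()
                for a, p_ in sorted(log.aggregation_map.items()):
                    w.writerow({"activity": a, "procedure": p_})
    else:
        raise ValueError(f"unknown format {format!r}")


# ----------------------------------------------------------------------
# Activity -> procedure aggregation
# ----------------------------------------------------------------------

def aggregate_activities(
    log: EventLog,
    mapping: Mapping[str, str] | None = None,
    *,
    passthrough: bool = True,
) -> EventLog:
    """Map granular activities to patient-facing procedures and merge
    same-patient same-procedure events whose [ordered_at, completed_at]
    intervals overlap (a missing completion is an open interval).

    Events that already carry a procedure label keep it, which makes the
    operation idempotent.  With ``passthrough`` disabled, an activity
    absent from the mapping raises, listing every unmapped label.
    """
    mapping = dict(mapping) if mapping is not None else dict(log.aggregation_map)
    unmapped = sorted(
        {e.activity for e in log.events if e.procedure is None and e.activity not in mapping}
    )
    if unmapped and not passthrough:
        raise LogValidationError([f"unmapped activity: {a}" for a in unmapped])

    labelled = []
    for e in log.events:
        proc = e.procedure if e.procedure is not None else mapping.get(e.activity, e.activity)
        labelled.append(replace(e, procedure=proc))

    far = datetime.max
    by_group: dict[tuple[str, str], list[Event]] = {}
    for e in labelled:
        by_group.setdefault((e.patient_id, e.procedure), []).append(e)

    merged: list[Event] = []
    for group in by_group.values():
        group.sort(key=lambda e: (e.ordered_at or e.completed_at or far, e.completed_at or far))
        current: list[Event] = []
        current_end: datetime | None = None  # None == open interval

        def flush():
            if not current:
                return
            starts = [e.started_at for e in current if e.started_at is not None]
            completes = [e.completed_at for e in current]
            merged.append(
                Event(
                    patient_id=current[0].patient_id,
                    activity=";".join(dict.fromkeys(e.activity for e in current)),
                    procedure=current[0].procedure,
                    ordered_at=min(e.ordered_at or e.completed_at or far for e in current),
                    started_at=min(starts) if starts else None,
                    completed_at=None if any(c is None for c in completes) else max(completes),
                    location=next((e.location for e in current if e.location), ""),
                )
            )

        for e in group:
            start = e.ordered_at or e.completed_at or far
            if current and (current_end is None or start <= current_end):
                current.append(e)
                if current_end is not None:
                    current_end = (
                        None if e.completed_at is None else max(current_end, e.completed_at)
                    )
            else:
                flush()
                current = [e]
                current_end = e.completed_at
        flush()

    out = EventLog(
        patients={pid: replace(p) for pid, p in log.patients.items()},
        events=merged,
        aggregation_map=mapping,
    )
    out.sort()
    return out
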