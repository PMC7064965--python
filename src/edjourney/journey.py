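"""Patient-facing journey state: Completed / Now / Later views.

``journey_state`` assembles, for one patient at time ``t``:

* **Completed stages** — procedures with a recorded completion;
* **Now – Waiting for** — ordered-but-not-completed procedures, each
  with a predicted waiting-time range ("between X and Y min"); when the
  elapsed wait strictly exceeds the predicted upper bound the range is
  replaced by an overdue fallback (by default the generic cap
  "up to 15 min");
* **Later** — anticipated procedures implied by succession rules, minus
  anything already completed or currently waited for;

plus a total length-of-stay estimate.  Everything is computed from the
t-truncated log, so nothing displayed depends on future records.
Estimates refresh on a fixed tick (default every 5 minutes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from datetime import datetime, timedelta
from typing import Iterable

from .discovery import AnticipationRule
from .event_log import EventLog, format_timestamp, parse_timestamp
from .queue_mining import DEFAULT_WINDOW, LogIndex, snapshot
from .wait_prediction import WaitModel, WaitRange, predict_los, predict_range

DEFAULT_REFRESH_MINUTES = 5
DEFAULT_GENERIC_CAP_MINUTES = 15

# Overdue fallback options; hospital practice favours the generic cap.
FALLBACK_CAP = "cap"  # "up to C min"
FALLBACK_UNAVAILABLE = "unavailable"  # "time estimates are not available"
FALLBACK_ASK_STAFF = "ask-staff"  # "please check with the care team"


class PatientNotFound(KeyError):
    pass


@dataclass
class NowItem:
    procedure: str
    range: WaitRange
    location: str = ""
    fallback_text: str | None = None


@dataclass
class JourneyView:
    patient_id: str
    as_of: datetime
    completed: list[tuple[str, datetime]]
    now: list[NowItem]
    later: list[str]
    los_estimate: WaitRange | None
    discharged: bool = False
    refresh_interval: int = DEFAULT_REFRESH_MINUTES
    generic_cap: int = DEFAULT_GENERIC_CAP_MINUTES


def _fallback_text(option: str, cap: int) -> str:
    if option == FALLBACK_CAP:
        return f"up to {cap} min"
    if option == FALLBACK_UNAVAILABLE:
        return "time estimates are not available"
    if option == FALLBACK_ASK_STAFF:
        return "please check with the care team"
    raise ValueError(f"unknown fallback option {option!r}")


def journey_state(
    log: EventLog,
    rules: Iterable[AnticipationRule],
    model: WaitModel,
    patient_id: str,
    t: datetime,
    los_model: WaitModel | None = None,
    window: timedelta = DEFAULT_WINDOW,
    generic_cap: int = DEFAULT_GENERIC_CAP_MINUTES,
    fallback_option: str = FALLBACK_CAP,
    refresh_interval: int = DEFAULT_REFRESH_MINUTES,
) -> JourneyView:
    """The journey view for ``patient_id`` as of ``t``.

    Deterministic given (log, rules, model, t).  A discharged patient
    gets a final static view; an unknown patient raises
    :class:`PatientNotFound`.
    """
    patient = log.patients.get(patient_id)
    if patient is None:
        raise PatientNotFound(patient_id)
    rules = list(rules)
    truncated = log.truncate(t)
    index = LogIndex(truncated)

    mine = [e for e in truncated.events if e.patient_id == patient_id]
    completed_events = sorted(
        ((e.procedure or e.activity, e.completed_at) for e in mine if e.completed_at is not None),
        key=lambda x: (x[1], x[0]),
    )
    completed = list(dict.fromkeys(completed_events))  # stable, dedup exact repeats
    completed_set = {p for p, _ in completed}

    discharged = patient.discharge_time is not None and patient.discharge_time <= t
    now_items: list[NowItem] = []
    if not discharged:
        for e in mine:
            proc = e.procedure or e.activity
            if e.ordered_at is None or e.completed_at is not None:
                continue
            fv = snapshot(truncated, patient_id, proc, t, rules, window, index=index)
            r = predict_range(model, proc, fv) if proc in model.estimators else WaitRange(0, 0, 0)
            elapsed = (t - e.ordered_at).total_seconds() / 60.0
            fallback = None
            if elapsed > r.upper:
                r = WaitRange(0, generic_cap, generic_cap, fallback_applied=True)
                fallback = _fallback_text(fallback_option, generic_cap)
            now_items.append(NowItem(procedure=proc, range=r, location=e.location, fallback_text=fallback))
        now_items.sort(key=lambda item: (item.range.lower, item.procedure))
    now_set = {item.procedure for item in now_items}

    antecedents = completed_set | now_set
    later_rules = [
        r
        for r in rules
        if r.antecedent in antecedents and r.consequent not in completed_set | now_set
    ]
    later_rules.sort(key=lambda r: (-r.confidence, r.consequent))
    later = list(dict.fromkeys(r.consequent for r in later_rules))
    if discharged:
        later = []

    los = None
    if discharged:
        realized = (patient.discharge_time - patient.arrival_time).total_seconds() / 60.0
        los = WaitRange(round(realized), round(realized), round(realized))
    elif los_model is not None:
        fv = snapshot(truncated, patient_id, None, t, rules, window, index=index)
        elapsed_stay = (t - patient.arrival_time).total_seconds() / 60.0
        los = predict_los(los_model, fv, elapsed_stay)

    return JourneyView(
        patient_id=patient_id,
        as_of=t,
        completed=completed,
        now=now_items,
        later=later,
        los_estimate=los,
        discharged=discharged,
        refresh_interval=refresh_interval,
        generic_cap=generic_cap,
    )


def refresh_schedule(
    start: datetime, horizon_minutes: float, step_minutes: int = DEFAULT_REFRESH_MINUTES
) -> list[datetime]:
    """Refresh ticks: start, start+step, ... up to the horizon (inclusive)."""
    if horizon_minutes < 0:
        raise ValueError("horizon must be nonnegative")
    if step_minutes <= 0:
        raise ValueError("step must be positive")
    out = []
    k = 0
    while k * step_minutes <= horizon_minutes:
        out.append(start + timedelta(minutes=k * step_minutes))
        k += 1
    return out


# ----------------------------------------------------------------------
# Rendering
# ----------------------------------------------------------------------

def format_range(r: WaitRange) -> str:
    if r.lower == r.upper:
        return f"about {int(r.lower)} min"
    return f"between {int(r.lower)} and {int(r.upper)} min"


def render_view(view: JourneyView, format: str = "text") -> str:
    if format == "text":
        lines = [f"Patient {view.patient_id} — as of {format_timestamp(view.as_of)}"]
        if view.discharged:
            lines.append("(discharged)")
        lines.append("Completed stages:")
        for proc, at in view.completed:
            lines.append(f"  - {proc} (completed {at.strftime('%H:%M')})")
        if not view.completed:
            lines.append("  (none yet)")
        lines.append("Now — Waiting for:")
        for item in view.now:
            shown = item.fallback_text or format_range(item.range)
            loc = f" — {item.location}" if item.location else ""
            lines.append(f"  - {item.procedure}: {shown}{loc}")
        if not view.now:
            lines.append("  (nothing at the moment)")
        lines.append("Later:")
        for proc in view.later:
            lines.append(f"  - {proc}")
        if not view.later:
            lines.append("  (nothing anticipated)")
        if view.los_estimate is not None:
            lines.append(f"Estimated total stay: {format_range(view.los_estimate)}")
        return "\n".join(lines) + "\n"
    if format == "json":
        doc = {
            "patient_id": view.patient_id,
            "as_of": format_timestamp(view.as_of),
            "discharged": view.discharged,
            "completed": [
                {"procedure": p, "completed_at": format_timestamp(at)} for p, at in view.completed
            ],
            "now": [
                {
                    "procedure": item.procedure,
                    "lower": item.range.lower,
                    "point": item.range.point,
                    "upper": item.range.upper,
                    "fallback_applied": item.range.fallback_applied,
                    "fallback_text": item.fallback_text,
                    "display": item.fallback_text or format_range(item.range),
                    "location": item.location,
                }
                for item in view.now
            ],
            "later": view.later,
            "los_estimate": None
            if view.los_estimate is None
            else {
                "lower": view.los_estimate.lower,
                "point": view.los_estimate.point,
                "upper": view.los_estimate.upper,
            },
            "refresh_interval": view.refresh_interval,
            "generic_cap": view.generic_cap,
        }
        return json.dumps(doc, indent=1)
    raise ValueError(f"unknown format {format!r}")


def view_from_json(text: str) -> JourneyView:
    doc = json.loads(text)
    return JourneyView(
        patient_id=doc["patient_id"],
        as_of=parse_timestamp(doc["as_of"]),
        completed=[(c["procedure"], parse_timestamp(c["completed_at"])) for c in doc["completed"]],
        now=[
            NowItem(
                procedure=n["procedure"],
                range=WaitRange(n["lower"], n["point"], n["upper"], n["fallback_applied"]),
                location=n["location"],
                fallback_text=n["fallback_text"],
            )
            for n in doc["now"]
        ],
        later=list(doc["later"]),
        los_estimate=None
        if doc["los_estimate"] is None
        else WaitRange(
            doc["los_estimate"]["lower"], doc["los_estimate"]["point"], doc["los_estimate"]["upper"]
        ),
        discharged=doc["discharged"],
        refresh_interval=doc["refresh_interval"],
        generic_cap=doc["generic_cap"],
    )
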