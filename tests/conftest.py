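"""Shared fixtures: hand-built logs and seeded simulator output."""

from datetime import datetime

import pytest

import edjourney as ej
from edjourney.simulator import ProcedureSpec, ServiceSpec, SimConfig


def ts(s: str) -> datetime:
    return datetime.strptime(s, "%Y-%m-%dT%H:%M")


def make_patient(pid, arrival, discharge=None, triage=3, mode="walk-in", age=40, gender="F"):
    return ej.Patient(pid, ts(arrival), ts(discharge) if discharge else None, triage, mode, age, gender)


def make_event(pid, activity, ordered, started=None, completed=None, procedure=None, location=""):
    return ej.Event(
        patient_id=pid,
        activity=activity,
        ordered_at=ts(ordered) if ordered else None,
        started_at=ts(started) if started else None,
        completed_at=ts(completed) if completed else None,
        procedure=procedure,
        location=location,
    )


def single_queue_config(
    seed=17,
    horizon_hours=24 * 7,
    arrivals_per_hour=8.0,
    servers=2,
    service=None,
    name="triage exam",
    arrival_times=None,
):
    """Minimal one-procedure ED: every patient queues once."""
    rates = [[arrivals_per_hour] * 7 for _ in range(24)]
    return SimConfig(
        horizon_hours=horizon_hours,
        arrival_rates=rates,
        triage_mix=[0.03, 0.12, 0.35, 0.35, 0.15],
        procedures=[
            ProcedureSpec(
                name,
                servers=servers,
                service=service or ServiceSpec("exponential", {"mean": 12}),
            )
        ],
        routing={t: [[([name], 1.0)]] for t in range(1, 6)},
        seed=seed,
        arrival_times=arrival_times,
    )


@pytest.fixture(scope="session")
def week_sim():
    """Default ED, seed 17, one simulated week."""
    log, gt = ej.simulate(ej.default_config(horizon_hours=24 * 7, seed=17))
    return log, gt


@pytest.fixture(scope="session")
def week_rules(week_sim):
    log, _ = week_sim
    return ej.mine_rules(ej.extract_journeys(log), min_support=20, min_confidence=0.9)


@pytest.fixture(scope="session")
def week_table(week_sim, week_rules):
    log, _ = week_sim
    return ej.build_training_table(log, week_rules)


@pytest.fixture(scope="session")
def week_model(week_table):
    return ej.train(week_table.frame, ej.TrainParams(seed=17))


@pytest.fixture()
def fig_scenario_log():
    """Hand-built single-patient journey: admitted 12:16, nurse 13:02,
    physician 14:24, CT scan ordered 15:40 and still pending at 15:56."""
    log = ej.EventLog()
    log.patients["p1"] = make_patient("p1", "2018-09-28T12:16", triage=3)
    log.events = [
        make_event("p1", "admission", "2018-09-28T12:16", "2018-09-28T12:16", "2018-09-28T12:16", procedure="admission"),
        make_event("p1", "nurse", "2018-09-28T12:20", "2018-09-28T12:50", "2018-09-28T13:02", procedure="nurse"),
        make_event("p1", "physician", "2018-09-28T13:05", "2018-09-28T14:05", "2018-09-28T14:24", procedure="physician"),
        make_event("p1", "CT scan", "2018-09-28T15:40", procedure="CT scan", location="imaging"),
    ]
    log.sort()
    log.validate()
    return log
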