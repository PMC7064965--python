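"""Seeded discrete-event simulator of an emergency department.

Generates event logs with known ground truth (true waits, queue lengths,
service rates, length of stay) so that queue-mining features and
waiting-time predictors can be validated against a log whose dynamics
are fully known.

Model
-----
Patients arrive by a nonhomogeneous Poisson process with an hour-of-day
x weekday rate table.  Each patient draws a triage level and walks a
per-triage routing plan: a list of stages, each stage a categorical
choice over *branches*, where a branch orders one or more procedures
simultaneously (a fork).  Every procedure is a FIFO multi-server queue.
By default a patient can be *in service* in at most one procedure at a
time (waiting in several queues simultaneously is allowed); this
exclusivity can be switched off.

Deterministic succession pairs (e.g. an ultrasound examination is always
followed by its interpretation) order the consequent the moment the
antecedent completes.

Recorded timestamps are floored to whole minutes, matching the minute
resolution of ED medical records.  ``recording_delay_fraction`` emulates
lab work being written to the record only after completion: for the
affected events the *recorded* order time equals the completion time and
the start time is absent, while the ground truth keeps the real times.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from typing import Any

import numpy as np
import pandas as pd

from .event_log import Event, EventLog, Patient


class ConfigError(ValueError):
    """Invalid simulator configuration."""


# ----------------------------------------------------------------------
# Configuration
# ----------------------------------------------------------------------

@dataclass
class ServiceSpec:
    """Service-time distribution; parameters in minutes."""

    family: str  # exponential | deterministic | lognormal | gamma
    params: dict[str, float]

    def validate(self) -> None:
        p = self.params
        if self.family == "exponential":
            ok = p.get("mean", 0) > 0
        elif self.family == "deterministic":
            ok = p.get("value", 0) > 0
        elif self.family == "lognormal":
            ok = p.get("mean", 0) > 0 and p.get("sigma", 0) > 0
        elif self.family == "gamma":
            ok = p.get("shape", 0) > 0 and p.get("scale", 0) > 0
        else:
            raise ConfigError(f"unknown service-time family {self.family!r}")
        if not ok:
            raise ConfigError(f"non-positive parameter for {self.family} service time: {p}")

    def draw(self, rng: np.random.Generator) -> float:
        p = self.params
        if self.family == "exponential":
            return float(rng.exponential(p["mean"]))
        if self.family == "deterministic":
            return float(p["value"])
        if self.family == "lognormal":
            # mean is the distribution mean; sigma the log-scale sd
            sigma = p["sigma"]
            mu = math.log(p["mean"]) - sigma**2 / 2
            return float(rng.lognormal(mu, sigma))
        if self.family == "gamma":
            return float(rng.gamma(p["shape"], p["scale"]))
        raise ConfigError(f"unknown service-time family {self.family!r}")


@dataclass
class ProcedureSpec:
    name: str
    servers: int
    service: ServiceSpec
    location: str = "ED"
    is_lab: bool = False


# A branch is a list of procedure names ordered simultaneously; a stage is
# a categorical distribution over branches ([] = stage skipped).
Branch = tuple[list[str], float]
Stage = list[Branch]


@dataclass
class SimConfig:
    horizon_hours: float
    arrival_rates: list[list[float]]  # [hour 0..23][weekday 0..6], arrivals/hour
    triage_mix: list[float]  # P(triage=1..5)
    procedures: list[ProcedureSpec]
    routing: dict[int, list[Stage]]  # triage -> stages
    succession_pairs: list[tuple[str, str]] = field(default_factory=list)
    recording_delay_fraction: float = 0.0
    exclusive_service: bool = True
    seed: int = 17
    start_time: datetime = field(default_factory=lambda: datetime(2018, 9, 24, 0, 0))
    arrival_times: list[float] | None = None  # explicit override, minutes from start

    def validate(self) -> None:
        if self.horizon_hours < 0:
            raise ConfigError("horizon must be nonnegative")
        if len(self.arrival_rates) != 24 or any(len(r) != 7 for r in self.arrival_rates):
            raise ConfigError("arrival_rates must be a 24x7 table")
        if any(x < 0 for row in self.arrival_rates for x in row):
            raise ConfigError("arrival rates must be nonnegative")
        if len(self.triage_mix) != 5 or abs(sum(self.triage_mix) - 1.0) > 1e-9:
            raise ConfigError("triage_mix must be 5 probabilities summing to 1")
        names = [p.name for p in self.procedures]
        if len(set(names)) != len(names):
            raise ConfigError("duplicate procedure names")
        for p in self.procedures:
            if p.servers < 1:
                raise ConfigError(f"procedure {p.name}: servers must be >= 1")
            p.service.validate()
        known = set(names)
        for triage, stages in self.routing.items():
            if not 1 <= int(triage) <= 5:
                raise ConfigError(f"routing triage {triage} outside 1-5")
            for stage in stages:
                total = sum(prob for _, prob in stage)
                if abs(total - 1.0) > 1e-9:
                    raise ConfigError(f"stage branch probabilities sum to {total}, not 1")
                for branch, _ in stage:
                    unknown = set(branch) - known
                    if unknown:
                        raise ConfigError(f"routing references unknown procedures {unknown}")
        for a, b in self.succession_pairs:
            if a not in known or b not in known:
                raise ConfigError(f"succession pair ({a}, {b}) references unknown procedure")
        if not 0.0 <= self.recording_delay_fraction <= 1.0:
            raise ConfigError("recording_delay_fraction must be in [0, 1]")

    # -- config file round trip -------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["start_time"] = self.start_time.strftime("%Y-%m-%dT%H:%M")
        d["routing"] = {
            str(t): [[[list(br), prob] for br, prob in stage] for stage in stages]
            for t, stages in self.routing.items()
        }
        d["succession_pairs"] = [list(p) for p in self.succession_pairs]
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimConfig":
        d = dict(d)
        d["procedures"] = [
            ProcedureSpec(
                name=p["name"],
                servers=int(p["servers"]),
                service=ServiceSpec(p["service"]["family"], dict(p["service"]["params"])),
                location=p.get("location", "ED"),
                is_lab=bool(p.get("is_lab", False)),
            )
            for p in d["procedures"]
        ]
        d["routing"] = {
            int(t): [[(list(br), float(prob)) for br, prob in stage] for stage in stages]
            for t, stages in d["routing"].items()
        }
        d["succession_pairs"] = [tuple(p) for p in d.get("succession_pairs", [])]
        if isinstance(d.get("start_time"), str):
            d["start_time"] = datetime.strptime(d["start_time"], "%Y-%m-%dT%H:%M")
        return cls(**d)


def default_config(horizon_hours: float = 24 * 7, seed: int = 17) -> SimConfig:
    """A medium-sized ED: 9 procedures, forked orders, two deterministic
    succession pairs, and a day/night arrival profile peaking mid-day."""
    hour_profile = [
        1.0, 0.8, 0.7, 0.6, 0.6, 0.8,   # 00-05
        1.5, 2.5, 4.0, 5.5, 6.5, 7.0,   # 06-11
        7.0, 6.5, 6.0, 5.5, 5.5, 5.0,   # 12-17
        4.5, 4.0, 3.5, 3.0, 2.0, 1.5,   # 18-23
    ]
    weekday_factor = [1.0, 1.0, 1.0, 1.0, 1.0, 0.85, 0.9]
    rates = [[h * w for w in weekday_factor] for h in hour_profile]

    exp = lambda m: ServiceSpec("exponential", {"mean": m})
    logn = lambda m, s: ServiceSpec("lognormal", {"mean": m, "sigma": s})
    # Staffing sized for moderate peak utilization (~0.5-0.8), so queues
    # form at busy hours and waiting times have realistic spread.
    procedures = [
        ProcedureSpec("nurse", servers=2, service=exp(8), location="triage bay"),
        ProcedureSpec("physician", servers=3, service=logn(15, 0.5), location="exam room"),
        ProcedureSpec("lab tests", servers=4, service=logn(30, 0.4), location="lab", is_lab=True),
        ProcedureSpec("CT scan", servers=1, service=logn(15, 0.3), location="imaging"),
        ProcedureSpec("CT interpretation", servers=1, service=exp(10), location="radiology"),
        ProcedureSpec("US examination", servers=1, service=logn(14, 0.3), location="imaging"),
        ProcedureSpec("US interpretation", servers=1, service=exp(8), location="radiology"),
        ProcedureSpec("x-ray", servers=1, service=logn(10, 0.3), location="imaging"),
        ProcedureSpec("specialist", servers=1, service=logn(20, 0.5), location="consult room"),
    ]

    # All triage levels share the journey shape; urgent patients order
    # more diagnostics and see a specialist more often.
    def stages(p_lab, p_ct, p_us, p_xray, p_spec) -> list[Stage]:
        p_none = max(0.0, 1.0 - p_lab - p_ct - p_us - p_xray)
        return [
            [(["nurse"], 1.0)],
            [(["physician"], 1.0)],
            [
                (["lab tests", "x-ray"], p_xray),
                (["lab tests", "CT scan"], p_ct),
                (["lab tests", "US examination"], p_us),
                (["lab tests"], p_lab),
                ([], p_none),
            ],
            [(["specialist"], p_spec), ([], 1.0 - p_spec)],
        ]

    routing = {
        1: stages(p_lab=0.30, p_ct=0.30, p_us=0.15, p_xray=0.15, p_spec=0.6),
        2: stages(p_lab=0.35, p_ct=0.25, p_us=0.15, p_xray=0.15, p_spec=0.5),
        3: stages(p_lab=0.40, p_ct=0.15, p_us=0.12, p_xray=0.18, p_spec=0.3),
        4: stages(p_lab=0.40, p_ct=0.08, p_us=0.10, p_xray=0.22, p_spec=0.2),
        5: stages(p_lab=0.35, p_ct=0.05, p_us=0.08, p_xray=0.22, p_spec=0.1),
    }

    cfg = SimConfig(
        horizon_hours=horizon_hours,
        arrival_rates=rates,
        triage_mix=[0.03, 0.12, 0.35, 0.35, 0.15],
        procedures=procedures,
        routing=routing,
        succession_pairs=[
            ("US examination", "US interpretation"),
            ("CT scan", "CT interpretation"),
        ],
        recording_delay_fraction=0.0,
        seed=seed,
    )
    cfg.validate()
    return cfg


# ----------------------------------------------------------------------
# Ground truth
# ----------------------------------------------------------------------

@dataclass
class GroundTruth:
    """True (noise-free) quantities behind a simulated log.

    ``waits`` has one row per (patient, procedure) order with the true
    wait in minutes from order to service start; ``queue_lengths`` is
    sampled on a regular grid; ``service_rates`` are realized
    completions/hour over the horizon; ``los`` holds true lengths of
    stay.  All timestamps are floored to whole minutes, the recording
    granularity of the emitted log.
    """

    waits: pd.DataFrame
    queue_lengths: pd.DataFrame
    service_rates: dict[str, float]
    los: pd.DataFrame
    truncated_patients: set[str]


# ----------------------------------------------------------------------
# Simulation engine
# ----------------------------------------------------------------------

class _PatientState:
    __slots__ = (
        "pid", "arrival", "triage", "mode", "age", "gender",
        "stages", "stage_idx", "stage_pending", "pending", "in_service",
        "records", "discharge",
    )

    def __init__(self, pid, arrival, triage, mode, age, gender, stages):
        self.pid = pid
        self.arrival = arrival
        self.triage = triage
        self.mode = mode
        self.age = age
        self.gender = gender
        self.stages = stages
        self.stage_idx = -1
        self.stage_pending: set[str] = set()
        self.pending: set[str] = set()  # ordered, not completed (any source)
        self.in_service: str | None = None
        self.records: list[dict] = []  # per order: proc, ordered, started, completed
        self.discharge: float | None = None


def _floor_minute(t: float) -> float:
    return float(math.floor(t))


def _nhpp_arrivals(cfg: SimConfig, rng: np.random.Generator) -> list[float]:
    """Arrival times (minutes) by thinning, honouring the 24x7 rate table."""
    horizon_min = cfg.horizon_hours * 60.0
    lam_max = max(x for row in cfg.arrival_rates for x in row)
    if lam_max == 0 or horizon_min == 0:
        return []
    out = []
    t = 0.0
    start = cfg.start_time
    while True:
        t += rng.exponential(60.0 / lam_max)
        if t >= horizon_min:
            break
        at = start + timedelta(minutes=t)
        rate = cfg.arrival_rates[at.hour][at.weekday()]
        if rng.random() * lam_max < rate:
            out.append(t)
    return out


def simulate(config: SimConfig) -> tuple[EventLog, GroundTruth]:
    """Run the discrete-event simulation; reproducible given the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    horizon = config.horizon_hours * 60.0
    procs = {p.name: p for p in config.procedures}
    succ: dict[str, list[str]] = {}
    for a, b in config.succession_pairs:
        succ.setdefault(a, []).append(b)

    queues: dict[str, list[str]] = {p: [] for p in procs}  # waiting pids, FIFO
    busy: dict[str, int] = {p: 0 for p in procs}
    patients: dict[str, _PatientState] = {}

    heap: list[tuple[float, int, str, tuple]] = []
    seq = 0

    def push(t, kind, payload):
        nonlocal seq
        heapq.heappush(heap, (t, seq, kind, payload))
        seq += 1

    arrivals = (
        list(config.arrival_times) if config.arrival_times is not None
        else _nhpp_arrivals(config, rng)
    )
    for i, t in enumerate(sorted(arrivals)):
        if t <= horizon:
            push(t, "arrival", (i,))

    def order(ps: _PatientState, proc: str, t: float):
        ps.records.append({"procedure": proc, "ordered": t, "started": None, "completed": None})
        ps.pending.add(proc)
        queues[proc].append(ps.pid)
        try_start(proc, t)

    def try_start(proc: str, t: float):
        spec = procs[proc]
        while busy[proc] < spec.servers:
            candidate = None
            for pid in queues[proc]:
                if not config.exclusive_service or patients[pid].in_service is None:
                    candidate = pid
                    break
            if candidate is None:
                return
            queues[proc].remove(candidate)
            ps = patients[candidate]
            busy[proc] += 1
            if config.exclusive_service:
                ps.in_service = proc
            for rec in ps.records:
                if rec["procedure"] == proc and rec["started"] is None and rec["completed"] is None:
                    rec["started"] = t
                    break
            push(t + spec.service.draw(rng), "service_end", (candidate, proc))

    def begin_stage(ps: _PatientState, t: float):
        while True:
            ps.stage_idx += 1
            if ps.stage_idx >= len(ps.stages):
                if not ps.pending:
                    ps.discharge = t
                return
            stage = ps.stages[ps.stage_idx]
            probs = [prob for _, prob in stage]
            idx = rng.choice(len(stage), p=probs)
            branch = stage[idx][0]
            if branch:
                ps.stage_pending = set(branch)
                for proc in branch:
                    order(ps, proc, t)
                return
            # empty branch: stage skipped, fall through to the next one

    def on_complete(ps: _PatientState, proc: str, t: float):
        ps.pending.discard(proc)
        ps.stage_pending.discard(proc)
        for consequent in succ.get(proc, []):
            order(ps, consequent, t)
        if ps.stage_idx >= 0 and not ps.stage_pending and ps.stage_idx < len(ps.stages):
            begin_stage(ps, t)
        elif ps.stage_idx >= len(ps.stages) and not ps.pending and ps.discharge is None:
            ps.discharge = t

    while heap:
        t, _, kind, payload = heapq.heappop(heap)
        if t > horizon:
            break
        if kind == "arrival":
            (i,) = payload
            pid = f"p{i + 1:05d}"
            triage = int(rng.choice(5, p=config.triage_mix)) + 1
            mode = "ambulance" if rng.random() < (0.35 if triage <= 2 else 0.08) else "walk-in"
            age = int(rng.integers(18, 91))
            gender = "F" if rng.random() < 0.52 else "M"
            stages = config.routing.get(triage) or next(iter(config.routing.values()))
            ps = _PatientState(pid, t, triage, mode, age, gender, stages)
            patients[pid] = ps
            begin_stage(ps, t)
        elif kind == "service_end":
            pid, proc = payload
            ps = patients[pid]
            busy[proc] -= 1
            if config.exclusive_service:
                ps.in_service = None
            for rec in ps.records:
                if rec["procedure"] == proc and rec["started"] is not None and rec["completed"] is None:
                    rec["completed"] = t
                    break
            on_complete(ps, proc, t)
            try_start(proc, t)
            if config.exclusive_service:
                for q in procs:
                    if ps.pid in queues[q]:
                        try_start(q, t)

    # ------------------------------------------------------------------
    # Emit log + ground truth (times floored to whole minutes)
    # ------------------------------------------------------------------
    start = config.start_time

    def to_dt(minutes: float | None) -> datetime | None:
        return None if minutes is None else start + timedelta(minutes=_floor_minute(minutes))

    log = EventLog()
    wait_rows, los_rows = [], []
    truncated: set[str] = set()
    for ps in patients.values():
        if ps.discharge is None:
            truncated.add(ps.pid)
        log.patients[ps.pid] = Patient(
            patient_id=ps.pid,
            arrival_time=to_dt(ps.arrival),
            discharge_time=to_dt(ps.discharge),
            triage=ps.triage,
            arrival_mode=ps.mode,
            age=ps.age,
            gender=ps.gender,
        )
        for rec in ps.records:
            spec = procs[rec["procedure"]]
            ordered, started, completed = rec["ordered"], rec["started"], rec["completed"]
            delayed = (
                spec.is_lab
                and completed is not None
                and rng.random() < config.recording_delay_fraction
            )
            if delayed:
                rec_ordered, rec_started = completed, None
            else:
                rec_ordered, rec_started = ordered, started
            log.events.append(
                Event(
                    patient_id=ps.pid,
                    activity=rec["procedure"],
                    procedure=rec["procedure"],
                    ordered_at=to_dt(rec_ordered),
                    started_at=to_dt(rec_started),
                    completed_at=to_dt(completed),
                    location=spec.location,
                )
            )
            if started is not None:
                wait_rows.append(
                    {
                        "patient_id": ps.pid,
                        "procedure": rec["procedure"],
                        "ordered_at": to_dt(ordered),
                        "started_at": to_dt(started),
                        "wait_minutes": _floor_minute(started) - _floor_minute(ordered),
                    }
                )
        if ps.discharge is not None:
            los_rows.append(
                {
                    "patient_id": ps.pid,
                    "arrival": to_dt(ps.arrival),
                    "discharge": to_dt(ps.discharge),
                    "los_minutes": _floor_minute(ps.discharge) - _floor_minute(ps.arrival),
                }
            )
    log.sort()

    # queue lengths / busy servers on a 5-minute grid, from true times
    grid = np.arange(0.0, horizon + 1e-9, 5.0)
    ql_rows = []
    per_proc: dict[str, list[tuple[float, float | None, float | None]]] = {p: [] for p in procs}
    for ps in patients.values():
        for rec in ps.records:
            per_proc[rec["procedure"]].append(
                (_floor_minute(rec["ordered"]),
                 None if rec["started"] is None else _floor_minute(rec["started"]),
                 None if rec["completed"] is None else _floor_minute(rec["completed"]))
            )
    service_rates = {}
    for proc, recs in per_proc.items():
        o = np.array([r[0] for r in recs], dtype=float)
        s = np.array([math.inf if r[1] is None else r[1] for r in recs], dtype=float)
        c = np.array([math.inf if r[2] is None else r[2] for r in recs], dtype=float)
        for g in grid:
            ql_rows.append(
                {
                    "time": start + timedelta(minutes=float(g)),
                    "procedure": proc,
                    "queue_length": int(np.sum((o <= g) & (s > g))),
                    "busy_servers": int(np.sum((s <= g) & (c > g))),
                }
            )
        n_completed = int(np.sum(np.isfinite(c)))
        service_rates[proc] = n_completed / config.horizon_hours if config.horizon_hours else 0.0

    gt = GroundTruth(
        waits=pd.DataFrame(wait_rows, columns=["patient_id", "procedure", "ordered_at", "started_at", "wait_minutes"]),
        queue_lengths=pd.DataFrame(ql_rows, columns=["time", "procedure", "queue_length", "busy_servers"]),
        service_rates=service_rates,
        los=pd.DataFrame(los_rows, columns=["patient_id", "arrival", "discharge", "los_minutes"]),
        truncated_patients=truncated,
    )
    return log, gt


# ----------------------------------------------------------------------
# Queueing-theory reference
# ----------------------------------------------------------------------

def erlang_c_expected_wait(arrival_rate: float, service_rate: float, servers: int) -> float:
    """Steady-state M/M/c mean waiting time in minutes.

    ``arrival_rate`` and ``service_rate`` are per hour (per server for
    service).  Requires utilization < 1.
    """
    lam, mu, c = float(arrival_rate), float(service_rate), int(servers)
    a = lam / mu
    rho = a / c
    if rho >= 1:
        raise ValueError("unstable queue: utilization >= 1")
    # Erlang-C probability of waiting, computed with a stable recurrence
    inv_b = 1.0  # 1 / Erlang-B
    for k in range(1, c + 1):
        inv_b = 1.0 + inv_b * k / a
    erlang_b = 1.0 / inv_b
    p_wait = erlang_b / (1.0 - rho * (1.0 - erlang_b))
    wq_hours = p_wait / (c * mu - lam)
    return wq_hours * 60.0
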