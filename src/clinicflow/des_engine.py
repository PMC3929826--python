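"""Discrete-event simulation core.

A clinic day is simulated as a chronological event stream over scheduled
multi-server FIFO stations.  Patients receive their full set of random
draws (class, per-station service times, routing coin flips) up front from
per-purpose substreams of one root seed, so paired scenario runs share
common random numbers.

Patients may join a physician queue before that physician's attendance
starts; service begins no earlier than the schedule's start time.  By
default servers work overtime until their queue is empty (``overtime``
flag on the config); with a hard cutoff, patients still queued at the
schedule end are left unserved (NaN timestamps).
"""

from __future__ import annotations

import enum
import heapq
import math
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd

from .clinic_model import ClinicConfig, ConfigError, StationId

__all__ = [
    "Event",
    "EventKind",
    "PatientRecord",
    "ReplicationResult",
    "simulate",
    "decompose_wait",
    "station_waits",
    "write_event_log",
    "read_event_log",
]


class EventKind(enum.IntEnum):
    """Event types; integer value is the tie-break rank at equal times."""

    STATION_OPEN = 0
    SERVICE_START = 1
    ARRIVAL = 2
    SERVICE_END = 3


@dataclass(frozen=True)
class Event:
    time: float
    kind: EventKind
    patient_id: int | None
    station_id: StationId | None


@dataclass
class Visit:
    station: StationId
    queue_join: float
    service_start: float = math.nan
    service_end: float = math.nan

    @property
    def wait(self) -> float:
        return self.service_start - self.queue_join


@dataclass
class PatientRecord:
    patient_id: int
    class_id: str
    arrival_time: float
    route: list[StationId] = field(default_factory=list)
    visits: list[Visit] = field(default_factory=list)

    def visit(self, station: StationId) -> Visit:
        """First visit to ``station``; KeyError if the route skipped it."""
        for v in self.visits:
            if v.station == station:
                return v
        raise KeyError(station)


@dataclass
class ReplicationResult:
    """Output of one simulated clinic day."""

    config: ClinicConfig
    records: list[PatientRecord]
    events: list[Event] | None = None
    _frame: pd.DataFrame | None = field(default=None, repr=False)

    def to_frame(self) -> pd.DataFrame:
        """One row per (patient, station) visit, in route order."""
        if self._frame is None:
            rows = [
                (r.patient_id, r.class_id, str(v.station), v.queue_join, v.service_start, v.service_end)
                for r in self.records
                for v in r.visits
            ]
            self._frame = pd.DataFrame(
                rows,
                columns=["patient_id", "class", "station", "queue_join", "service_start", "service_end"],
            )
        return self._frame

    def station_waits(self, station_id: StationId | str) -> float:
        return station_waits(self, station_id)

    def decomposition(self, station_id: StationId | str) -> tuple[float, float, float]:
        """(mean wait before attendance, after attendance, total) at a
        physician station; NaN triple if no patient was served there."""
        sid = StationId(station_id)
        attendance = self.config.station(sid).schedule.start_time
        before = after = total = 0.0
        n = 0
        for rec in self.records:
            for v in rec.visits:
                if v.station == sid and not math.isnan(v.service_start):
                    b, a = decompose_wait(v.queue_join, v.service_start, attendance)
                    before += b
                    after += a
                    total += v.wait
                    n += 1
        if n == 0:
            return (math.nan, math.nan, math.nan)
        return (before / n, after / n, total / n)


def decompose_wait(
    queue_join: float, service_start: float, attendance_start: float
) -> tuple[float, float]:
    """Split a queue wait at a physician station into the part accrued
    before the physician's attendance start and the part after it.

    ``before + after == service_start - queue_join`` exactly.
    """
    before = max(0.0, min(service_start, attendance_start) - queue_join)
    if service_start > attendance_start:
        after = service_start - max(queue_join, attendance_start)
    else:
        after = 0.0
    return before, after


def station_waits(result: ReplicationResult, station_id: StationId | str) -> float:
    """Mean queue wait (service_start - queue_join) at one station.

    Returns NaN (a flagged empty value, distinct from 0) when no patient
    was served there; raises KeyError for a station not in the config.
    """
    sid = StationId(station_id)
    if sid not in result.config.stations:
        raise KeyError(f"unknown station {sid}")
    waits = [
        v.wait
        for rec in result.records
        for v in rec.visits
        if v.station == sid and not math.isnan(v.service_start)
    ]
    if not waits:
        return math.nan
    return float(np.mean(waits))


# ---- random-number plumbing -------------------------------------------

_STREAM_ARRIVALS = 0
_STREAM_CLASS = 1
_STREAM_CONSULT = 2
_STREAM_PARACLINIC = 3
_STREAM_STATION_BASE = 10  # + index of StationId in enum order

_STATION_ORDER = list(StationId)


def _substream(seed: int, key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _draw_arrivals(config: ClinicConfig, seed: int, n_patients: int | None) -> np.ndarray:
    rng = _substream(seed, _STREAM_ARRIVALS)
    start = config.admission_start
    if n_patients is not None:
        gaps = config.interarrival.sample(rng, n_patients)
        return start + np.cumsum(gaps)
    end = start + config.admission_duration
    times: list[float] = []
    t = start
    mean_gap = max(config.interarrival.truncated_mean, 1e-9)
    block = max(16, int(config.admission_duration / mean_gap * 1.5) + 8)
    while True:
        gaps = config.interarrival.sample(rng, block)
        for g in gaps:
            t += g
            if t > end:
                return np.asarray(times)
            times.append(t)


def _build_routes(
    config: ClinicConfig, class_ids: list, u_consult: np.ndarray, u_para: np.ndarray
) -> list[list[StationId]]:
    routes = []
    for i, cid in enumerate(class_ids):
        pc = config.classes[cid]
        route: list[StationId] = []
        for sid in (StationId.REGISTRATION, StationId.CASH):
            if sid in config.stations:
                route.append(sid)
        fp = pc.first_physician
        if fp is not None and fp in config.stations:
            route.append(fp)
        if (
            StationId.SENIOR_STAFF in config.stations
            and fp is not None
            and fp != StationId.SENIOR_STAFF
            and u_consult[i] < pc.p_consult_senior
        ):
            route.append(StationId.SENIOR_STAFF)
        if StationId.PARACLINIC in config.stations and u_para[i] < pc.p_paraclinic:
            route.append(StationId.PARACLINIC)
            if config.paraclinic_return and fp is not None:
                route.append(fp)
        routes.append(route)
    return routes


class _StationState:
    __slots__ = ("station", "queue", "busy", "is_open")

    def __init__(self, station):
        self.station = station
        self.queue: deque = deque()
        self.busy = 0
        self.is_open = False


def simulate(
    config: ClinicConfig,
    seed: int,
    n_patients: int | None = None,
    record_events: bool = False,
) -> ReplicationResult:
    """Simulate one clinic day; deterministic given ``(config, seed)``.

    Patients arrive from ``admission_start`` for ``admission_duration``
    minutes unless ``n_patients`` forces an exact arrival count (used by
    the synthetic-data generator and the stationary oracle tests).
    """
    arrivals = _draw_arrivals(config, seed, n_patients)
    n = len(arrivals)

    class_list = list(config.classes.values())
    if class_list:
        probs = np.array([c.mix_probability for c in class_list])
        cum = np.cumsum(probs)
        u_class = _substream(seed, _STREAM_CLASS).random(n)
        class_idx = np.searchsorted(cum, u_class, side="right").clip(0, len(class_list) - 1)
        class_ids = [class_list[j].id for j in class_idx]
    else:
        class_ids = []
    u_consult = _substream(seed, _STREAM_CONSULT).random(n)
    u_para = _substream(seed, _STREAM_PARACLINIC).random(n)
    routes = _build_routes(config, class_ids, u_consult, u_para)

    # Per-patient service draws at every station (station-specific streams),
    # drawn whether or not the route visits it: keeps draws aligned across
    # scenarios (common random numbers).  A second draw column covers the
    # optional return visit after paraclinic.
    n_cols = 2 if config.paraclinic_return else 1
    service: dict[StationId, np.ndarray] = {}
    for sid, st in config.stations.items():
        rng = _substream(seed, _STREAM_STATION_BASE + _STATION_ORDER.index(sid))
        service[sid] = st.service.sample(rng, n * n_cols).reshape(n, n_cols)

    records = [
        PatientRecord(patient_id=i, class_id=str(class_ids[i]), arrival_time=float(arrivals[i]), route=list(routes[i]))
        for i in range(n)
    ]
    events: list[Event] | None = [] if record_events else None

    states = {sid: _StationState(st) for sid, st in config.stations.items()}
    # route position per patient
    pos = [0] * n
    visit_count: dict[tuple[int, StationId], int] = {}

    heap: list[tuple[float, int, int, int, StationId | None]] = []
    seq = 0
    for sid, st in config.stations.items():
        heapq.heappush(heap, (st.schedule.start_time, int(EventKind.STATION_OPEN), seq, -1, sid))
        seq += 1
    for i in range(n):
        heapq.heappush(heap, (float(arrivals[i]), int(EventKind.ARRIVAL), seq, i, None))
        seq += 1

    def log(time: float, kind: EventKind, pid: int | None, sid: StationId | None) -> None:
        if events is not None:
            events.append(Event(time, kind, pid, sid))

    def join(pid: int, clock: float) -> None:
        """Advance patient to the next station on its route (or exit)."""
        rec = records[pid]
        if pos[pid] >= len(rec.route):
            return
        sid = rec.route[pos[pid]]
        rec.visits.append(Visit(station=sid, queue_join=clock))
        states[sid].queue.append(pid)
        log(clock, EventKind.ARRIVAL, pid, sid)
        dispatch(sid, clock)

    def dispatch(sid: StationId, clock: float) -> None:
        nonlocal seq
        state = states[sid]
        st = state.station
        if clock < st.schedule.start_time:
            return
        while state.queue and state.busy < st.schedule.n_servers:
            if not config.overtime and clock >= st.schedule.end:
                break
            pid = state.queue.popleft()
            rec = records[pid]
            v = rec.visits[-1] if rec.visits and rec.visits[-1].station == sid and math.isnan(rec.visits[-1].service_start) else None
            if v is None:  # return visit bookkeeping
                for cand in rec.visits:
                    if cand.station == sid and math.isnan(cand.service_start):
                        v = cand
                        break
            assert v is not None
            v.service_start = clock
            k = visit_count.get((pid, sid), 0)
            visit_count[(pid, sid)] = k + 1
            dur = float(service[sid][pid, min(k, service[sid].shape[1] - 1)])
            if not math.isfinite(dur):
                raise ConfigError(f"non-finite service time at {sid}")
            v.service_end = clock + dur
            state.busy += 1
            log(clock, EventKind.SERVICE_START, pid, sid)
            heapq.heappush(heap, (clock + dur, int(EventKind.SERVICE_END), seq, pid, sid))
            seq += 1

    while heap:
        time, kind, _, pid, sid = heapq.heappop(heap)
        kind = EventKind(kind)
        if kind is EventKind.STATION_OPEN:
            states[sid].is_open = True
            log(time, kind, None, sid)
            dispatch(sid, time)
        elif kind is EventKind.ARRIVAL:
            join(pid, time)
        elif kind is EventKind.SERVICE_END:
            states[sid].busy -= 1
            log(time, kind, pid, sid)
            pos[pid] += 1
            join(pid, time)
            dispatch(sid, time)

    return ReplicationResult(config=config, records=records, events=events)


# ---- event-log I/O -----------------------------------------------------

_LOG_COLUMNS = ["patient_id", "class", "station", "queue_join", "service_start", "service_end"]


def write_event_log(result_or_frame: ReplicationResult | pd.DataFrame, path: str | Path) -> None:
    """Write the per-visit log as CSV (times in minutes, 3 decimals)."""
    frame = (
        result_or_frame.to_frame()
        if isinstance(result_or_frame, ReplicationResult)
        else result_or_frame
    )
    frame = frame[_LOG_COLUMNS]
    frame.to_csv(path, index=False, float_format="%.3f")


def read_event_log(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_LOG_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"event log {path} missing columns {sorted(missing)}")
    return frame
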