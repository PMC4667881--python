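"""Data model and I/O for minute-resolution rodent telemetry.

A recording session produces, per animal, two parallel minute-sampled
signals — abdominal temperature (°C) and gross locomotor activity
(arbitrary integer counts) — plus a log of discrete events (handling,
bed change, intraperitoneal injection, light transitions).  This module
defines the in-memory containers (:class:`TelemetrySeries`,
:class:`PhaseRecording`), the CSV interchange reader/writer, the
circadian light/dark phase splitter and the pooling of animal-day-phase
recordings into analysis sets.

Conventions
-----------
* Timestamps are at minute resolution; phase windows are half-open
  ``[start, end)``, so a sample stamped exactly at lights-on belongs to
  the light phase and a complete 12:12 cycle yields 720 samples per
  phase.
* A dark phase is attributed to the calendar day on which it starts
  (the day containing 18:00–24:00 under the default cycle).
* A day is *disturbed* when any non-lights event falls on it; both
  phases of that day inherit the disturbed condition (overridable via
  ``disturb_whole_day=False``, which marks only windows that temporally
  contain an event).
* Missing samples are NaN.  Descriptors downstream operate on
  non-missing samples; recordings with more than ``max_missing_frac``
  missing in either signal are dropped at pooling time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date as Date
from datetime import time as Time
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("control", "substrain")
PHASES = ("light", "dark")
CONDITIONS = ("undisturbed", "disturbed")
EVENT_KINDS = ("handling", "bed_change", "injection", "lights_on", "lights_off")
INTERVENTION_KINDS = ("handling", "bed_change", "injection")

#: fixed sampling interval of the acquisition system
SAMPLING_INTERVAL = pd.Timedelta(minutes=1)

#: physiologically admissible abdominal temperature range, °C
TEMPERATURE_RANGE = (30.0, 42.0)

TELEMETRY_COLUMNS = ("animal_id", "group", "timestamp", "temperature_c", "activity_counts")
EVENT_COLUMNS = ("animal_id", "timestamp", "event_kind")

DEFAULT_LIGHTS_ON = Time(6, 0)
DEFAULT_LIGHTS_OFF = Time(18, 0)


class TelemetryFormatError(ValueError):
    """Raised when an input file violates the documented CSV dialect."""


@dataclass(frozen=True, order=True)
class EventRecord:
    """A timestamped discrete event in an animal's log."""

    time: pd.Timestamp
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}; expected one of {EVENT_KINDS}")
        object.__setattr__(self, "time", pd.Timestamp(self.time).floor("min"))

    @property
    def is_intervention(self) -> bool:
        return self.kind in INTERVENTION_KINDS


@dataclass
class TelemetrySeries:
    """One animal's continuous minute-resolution telemetry record.

    ``temperature`` and ``activity`` are float arrays of equal length
    with NaN marking missing samples; activity values are non-negative
    integers where present.
    """

    animal_id: str
    group: str
    start_time: pd.Timestamp
    temperature: np.ndarray
    activity: np.ndarray
    events: list[EventRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.start_time = pd.Timestamp(self.start_time).floor("min")
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.events = sorted(self.events)
        self.validate()

    # -- structure -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return int(self.temperature.size)

    @property
    def end_time(self) -> pd.Timestamp:
        return self.start_time + (self.n_samples - 1) * SAMPLING_INTERVAL

    def times(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start_time, periods=self.n_samples, freq="min")

    def validate(self) -> None:
        if self.temperature.shape != self.activity.shape or self.temperature.ndim != 1:
            raise ValueError("temperature and activity must be 1-D sequences of equal length")
        t = self.temperature[~np.isnan(self.temperature)]
        lo, hi = TEMPERATURE_RANGE
        if t.size and (t.min() < lo or t.max() > hi):
            raise ValueError(f"temperature outside physiological range {TEMPERATURE_RANGE} °C")
        a = self.activity[~np.isnan(self.activity)]
        if a.size and (np.any(a < 0) or np.any(a != np.round(a))):
            raise ValueError("activity counts must be non-negative integers")
        if self.n_samples:
            for ev in self.events:
                if not (self.start_time <= ev.time <= self.end_time):
                    raise ValueError(f"event {ev} outside the series time span")


@dataclass
class PhaseRecording:
    """One animal-day-phase slice — the unit of descriptor computation.

    720 samples for a complete phase under 1-min sampling and a 12:12
    cycle; ``partial`` flags truncated first/last windows.
    """

    animal_id: str
    group: str
    date: Date
    phase: str
    condition: str
    temperature: np.ndarray
    activity: np.ndarray
    partial: bool = False

    def __post_init__(self) -> None:
        if self.phase not in PHASES:
            raise ValueError(f"phase must be one of {PHASES}")
        if self.condition not in CONDITIONS:
            raise ValueError(f"condition must be one of {CONDITIONS}")
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        if self.temperature.shape != self.activity.shape:
            raise ValueError("temperature and activity must have equal length")

    @property
    def n_samples(self) -> int:
        return int(self.temperature.size)

    def missing_fraction(self, signal: str) -> float:
        arr = getattr(self, signal)
        return float(np.isnan(arr).mean()) if arr.size else 1.0


# ---------------------------------------------------------------------------
# phase splitting & pooling
# ---------------------------------------------------------------------------

def _minutes_of_day(clock: Time) -> int:
    return clock.hour * 60 + clock.minute


def light_mask(minute_of_day: np.ndarray, lights_on: Time, lights_off: Time) -> np.ndarray:
    """Boolean mask: True where the half-open window [on, off) applies."""
    on, off = _minutes_of_day(lights_on), _minutes_of_day(lights_off)
    if on < off:
        return (minute_of_day >= on) & (minute_of_day < off)
    return (minute_of_day >= on) | (minute_of_day < off)


def split_phases(
    series: TelemetrySeries,
    lights_on: Time = DEFAULT_LIGHTS_ON,
    lights_off: Time = DEFAULT_LIGHTS_OFF,
    *,
    disturb_whole_day: bool = True,
) -> list[PhaseRecording]:
    """Cut a continuous series into light/dark :class:`PhaseRecording` windows.

    Windows are half-open ``[lights_on, lights_off)`` (light) and
    ``[lights_off, next lights_on)`` (dark); windows not spanning a full
    nominal phase are flagged ``partial``.
    """
    if lights_on == lights_off:
        raise ValueError("lights_on and lights_off must differ")
    if series.n_samples == 0:
        raise ValueError("cannot split an empty series")

    times = series.times()
    mod = (times.hour * 60 + times.minute).to_numpy()
    on, off = _minutes_of_day(lights_on), _minutes_of_day(lights_off)
    is_light = light_mask(mod, lights_on, lights_off)
    boundary = (mod == on) | (mod == off)

    starts = np.flatnonzero(boundary)
    if starts.size == 0 or starts[0] != 0:
        starts = np.concatenate([[0], starts])
    edges = np.append(starts, series.n_samples)

    light_len = (off - on) % 1440
    dark_len = 1440 - light_len
    disturbed_dates = {ev.time.date() for ev in series.events if ev.is_intervention}

    recordings: list[PhaseRecording] = []
    for i0, i1 in zip(edges[:-1], edges[1:]):
        i0, i1 = int(i0), int(i1)
        phase = "light" if is_light[i0] else "dark"
        nominal = light_len if phase == "light" else dark_len
        partial = (i1 - i0 != nominal) or not bool(boundary[i0])
        day = times[i0].date()
        if disturb_whole_day:
            disturbed = day in disturbed_dates
        else:
            disturbed = any(
                times[i0] <= ev.time <= times[i1 - 1]
                for ev in series.events
                if ev.is_intervention
            )
        recordings.append(
            PhaseRecording(
                animal_id=series.animal_id,
                group=series.group,
                date=day,
                phase=phase,
                condition="disturbed" if disturbed else "undisturbed",
                temperature=series.temperature[i0:i1].copy(),
                activity=series.activity[i0:i1].copy(),
                partial=partial,
            )
        )
    return recordings


def pool_recordings(
    recordings: Sequence[PhaseRecording],
    phase: str | None = None,
    condition: str | None = None,
    *,
    include_partial: bool = False,
    max_missing_frac: float | None = 0.05,
) -> list[PhaseRecording]:
    """Pool animal-day-phase recordings sharing a phase and condition.

    A pure filter: selects the recordings matching ``phase`` and
    ``condition``, drops partial windows and recordings exceeding the
    missingness threshold, and orders the result by (animal_id, date).
    Pooling a pooled set returns it unchanged.
    """
    out: list[PhaseRecording] = []
    for rec in recordings:
        if phase is not None and rec.phase != phase:
            continue
        if condition is not None and rec.condition != condition:
            continue
        if rec.partial and not include_partial:
            continue
        if max_missing_frac is not None and (
            rec.missing_fraction("temperature") > max_missing_frac
            or rec.missing_fraction("activity") > max_missing_frac
        ):
            logger.info(
                "dropping %s %s %s: missingness above %.1f%%",
                rec.animal_id, rec.date, rec.phase, 100 * max_missing_frac,
            )
            continue
        out.append(rec)

    keys = [(r.animal_id, r.date, r.phase) for r in out]
    if len(set(keys)) != len(keys):
        raise ValueError("duplicate (animal, date, phase) recording in pool")
    out.sort(key=lambda r: (r.animal_id, r.date, r.phase))
    if not out:
        logger.info("pooling produced an empty set (phase=%s, condition=%s)", phase, condition)
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_events_csv(path) -> dict[str, list[EventRecord]]:
    """Read an event log CSV (columns animal_id, timestamp, event_kind)."""
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in EVENT_COLUMNS:
        if col not in df.columns:
            raise TelemetryFormatError(f"event file missing required column {col!r}")
    out: dict[str, list[EventRecord]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["animal_id"]), []).append(
            EventRecord(time=pd.Timestamp(row["timestamp"]), kind=str(row["event_kind"]))
        )
    for evs in out.values():
        evs.sort()
    return out


def read_telemetry_csv(path, events_path=None) -> list[TelemetrySeries]:
    """Read a telemetry CSV into one :class:`TelemetrySeries` per animal.

    Rows are sorted by time per animal; gaps in the minute grid become
    missing samples; malformed numeric cells become missing with a
    logged warning count.  Missing required columns or duplicate
    (animal_id, timestamp) rows raise :class:`TelemetryFormatError`.
    """
    df = pd.read_csv(path, comment="#", dtype=str)
    for col in TELEMETRY_COLUMNS:
        if col not in df.columns:
            raise TelemetryFormatError(f"telemetry file missing required column {col!r}")
    if df.empty:
        raise TelemetryFormatError("telemetry file contains no data rows")

    ts = pd.to_datetime(df["timestamp"]).dt.floor("min")
    if df.assign(_ts=ts).duplicated(subset=["animal_id", "_ts"]).any():
        raise TelemetryFormatError("duplicate (animal_id, timestamp) rows")

    parsed = {}
    for col in ("temperature_c", "activity_counts"):
        raw = df[col]
        num = pd.to_numeric(raw, errors="coerce")
        bad = int((num.isna() & raw.notna() & (raw.str.strip() != "")).sum())
        if bad:
            logger.warning("%d malformed %s cells treated as missing", bad, col)
        parsed[col] = num

    event_log = read_events_csv(events_path) if events_path is not None else {}

    series: list[TelemetrySeries] = []
    work = df.assign(_ts=ts, _temp=parsed["temperature_c"], _act=parsed["activity_counts"])
    for animal_id, sub in work.groupby("animal_id", sort=True):
        sub = sub.sort_values("_ts")
        groups = sub["group"].dropna().unique()
        if len(groups) != 1:
            raise TelemetryFormatError(f"animal {animal_id!r} has ambiguous group labels {groups}")
        grid = pd.date_range(sub["_ts"].iloc[0], sub["_ts"].iloc[-1], freq="min")
        temp = pd.Series(sub["_temp"].to_numpy(), index=sub["_ts"]).reindex(grid)
        act = pd.Series(sub["_act"].to_numpy(), index=sub["_ts"]).reindex(grid)
        n_gap = len(grid) - len(sub)
        if n_gap:
            logger.info("animal %s: %d gap minutes filled with missing", animal_id, n_gap)
        series.append(
            TelemetrySeries(
                animal_id=str(animal_id),
                group=str(groups[0]),
                start_time=grid[0],
                temperature=temp.to_numpy(),
                activity=act.to_numpy(),
                events=event_log.get(str(animal_id), []),
            )
        )
    return series


def _version_comment() -> str:
    from thermoloco import __version__

    return f"# thermoloco v{__version__}\n"


def write_telemetry_csv(series_seq: Iterable[TelemetrySeries], path) -> None:
    """Write TelemetrySeries to the interchange CSV (one row per animal-minute)."""
    frames = []
    for s in series_seq:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": s.animal_id,
                    "group": s.group,
                    "timestamp": s.times().strftime("%Y-%m-%dT%H:%M"),
                    "temperature_c": s.temperature,
                    "activity_counts": pd.array(s.activity, dtype="Int64"),
                }
            )
        )
    with open(path, "w") as fh:
        fh.write(_version_comment())
        pd.concat(frames, ignore_index=True).to_csv(fh, index=False)


def write_events_csv(series_seq: Iterable[TelemetrySeries], path) -> None:
    rows = [
        {
            "animal_id": s.animal_id,
            "timestamp": ev.time.strftime("%Y-%m-%dT%H:%M"),
            "event_kind": ev.kind,
        }
        for s in series_seq
        for ev in s.events
    ]
    with open(path, "w") as fh:
        fh.write(_version_comment())
        pd.DataFrame(rows, columns=list(EVENT_COLUMNS)).to_csv(fh, index=False)
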