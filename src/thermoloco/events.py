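"""Baseline-referenced response profiles around events.

For each event (light transition or intervention) the hour before the
event defines a baseline (mean temperature and mean activity rate), and
the period after the event is tiled with 10-min epochs — 6 epochs (1 h)
for light transitions, 12 epochs (2 h) for interventions.  The event
minute itself belongs to the first post-event epoch.  Epoch means minus
the baseline give the response deltas that are averaged (mean ± SEM)
across recordings, with the three intervention kinds poolable under one
label because they evoke the same transient pattern.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .telemetry import EventRecord, TelemetrySeries, SAMPLING_INTERVAL, INTERVENTION_KINDS

#: post-event horizon (min) by event kind
DEFAULT_HORIZONS = {
    "lights_on": 60,
    "lights_off": 60,
    "handling": 120,
    "bed_change": 120,
    "injection": 120,
}

BASELINE_MINUTES = 60
EPOCH_MINUTES = 10


@dataclass
class EventResponseProfile:
    animal_id: str
    group: str
    event: EventRecord
    horizon_minutes: int
    epoch_minutes: int
    baseline_bt: float
    baseline_activity: float
    bt_epoch_means: np.ndarray
    activity_epoch_means: np.ndarray
    complete: bool

    @property
    def n_epochs(self) -> int:
        return self.horizon_minutes // self.epoch_minutes

    @property
    def bt_deltas(self) -> np.ndarray:
        return self.bt_epoch_means - self.baseline_bt

    @property
    def activity_deltas(self) -> np.ndarray:
        return self.activity_epoch_means - self.baseline_activity


@dataclass
class PooledEventResponse:
    """Epoch-wise mean ± SEM of response deltas across profiles."""

    label: str
    n_profiles: int
    epoch_minutes: int
    horizon_minutes: int
    bt_delta_mean: np.ndarray
    bt_delta_sem: np.ndarray
    activity_delta_mean: np.ndarray
    activity_delta_sem: np.ndarray


def _window_mean(arr: np.ndarray, lo: int, hi: int, min_valid_frac: float = 0.0) -> float:
    window = arr[lo:hi]
    valid = ~np.isnan(window)
    if valid.sum() == 0 or valid.mean() < min_valid_frac:
        return math.nan
    return float(np.mean(window[valid]))


def response_profile(
    series: TelemetrySeries,
    event: EventRecord,
    *,
    baseline_minutes: int = BASELINE_MINUTES,
    epoch_minutes: int = EPOCH_MINUTES,
    horizon_minutes: int | None = None,
) -> EventResponseProfile:
    """Profile the response of both signals to one event.

    The profile is flagged incomplete when the series does not cover
    the full [event − baseline, event + horizon) window; the baseline
    is missing when fewer than 50% of its minutes are valid.
    """
    if horizon_minutes is None:
        horizon_minutes = DEFAULT_HORIZONS[event.kind]
    if horizon_minutes % epoch_minutes:
        raise ValueError("horizon must be an integer number of epochs")
    e = int((event.time - series.start_time) / SAMPLING_INTERVAL)
    n = series.n_samples
    complete = (e - baseline_minutes >= 0) and (e + horizon_minutes <= n)

    baseline_bt = math.nan
    baseline_act = math.nan
    if e - baseline_minutes >= 0 and e <= n:
        baseline_bt = _window_mean(series.temperature, e - baseline_minutes, e, 0.5)
        baseline_act = _window_mean(series.activity, e - baseline_minutes, e, 0.5)

    n_epochs = horizon_minutes // epoch_minutes
    bt_means = np.full(n_epochs, math.nan)
    act_means = np.full(n_epochs, math.nan)
    for k in range(n_epochs):
        lo, hi = e + k * epoch_minutes, e + (k + 1) * epoch_minutes
        if 0 <= lo and hi <= n:
            bt_means[k] = _window_mean(series.temperature, lo, hi)
            act_means[k] = _window_mean(series.activity, lo, hi)
    if math.isnan(baseline_bt) or math.isnan(baseline_act):
        complete = False
    return EventResponseProfile(
        animal_id=series.animal_id,
        group=series.group,
        event=event,
        horizon_minutes=horizon_minutes,
        epoch_minutes=epoch_minutes,
        baseline_bt=baseline_bt,
        baseline_activity=baseline_act,
        bt_epoch_means=bt_means,
        activity_epoch_means=act_means,
        complete=complete,
    )


def intervention_profiles(series: TelemetrySeries, **kwargs) -> list[EventResponseProfile]:
    """Profiles for every intervention event in one series."""
    return [
        response_profile(series, ev, **kwargs)
        for ev in series.events
        if ev.kind in INTERVENTION_KINDS
    ]


def pool_event_profiles(
    profiles: list[EventResponseProfile], label: str = "intervention"
) -> PooledEventResponse:
    """Epoch-wise mean and SEM of deltas over complete profiles.

    SEM uses the sample (ddof=1) standard deviation; it is NaN for a
    single profile.
    """
    usable = [p for p in profiles if p.complete]
    if not usable:
        raise ValueError("no complete profiles to pool")
    n_epochs = {p.n_epochs for p in usable}
    if len(n_epochs) != 1:
        raise ValueError("profiles with different horizons cannot be pooled")
    bt = np.vstack([p.bt_deltas for p in usable])
    act = np.vstack([p.activity_deltas for p in usable])
    n = len(usable)

    def sem(mat: np.ndarray) -> np.ndarray:
        if n < 2:
            return np.full(mat.shape[1], math.nan)
        return mat.std(axis=0, ddof=1) / math.sqrt(n)

    return PooledEventResponse(
        label=label,
        n_profiles=n,
        epoch_minutes=usable[0].epoch_minutes,
        horizon_minutes=usable[0].horizon_minutes,
        bt_delta_mean=bt.mean(axis=0),
        bt_delta_sem=sem(bt),
        activity_delta_mean=act.mean(axis=0),
        activity_delta_sem=sem(act),
    )
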