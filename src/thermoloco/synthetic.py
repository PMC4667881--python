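"""Synthetic telemetry cohort simulator with analytically known ground truth.

Emulates a two-group rat telemetry study design: per group, several
animals recorded continuously at 1-min sampling under a 12:12 light
cycle for a run of days, a subset of which carries brief interventions
(handling, bed change, vehicle injection).

Activity model
--------------
Minute-by-minute two-state (active/inactive) Markov chain per phase.
``q_ai`` is the probability an active minute is followed by an inactive
one, ``q_ia`` the reverse, so run lengths are geometric with means
``1/q_ai`` (active) and ``1/q_ia`` (inactive), and the stationary active
fraction is ``q_ia / (q_ia + q_ai)``.  Inactive minutes emit 0; active
minutes emit a geometric count on {1, 2, ...} with mean
``activity_mean`` (right-skewed, integer).  Closed forms:
``MI = 100·q_ia/(q_ia+q_ai)``, ``DA = 1/q_ai``, ``DI = 1/q_ia``,
``RMI = activity_mean``.

Temperature model
-----------------
``BT_t = baseline(phase_t) + coupling_gain · MA_w(activity)_t + X_t``
with a trailing ``w``-minute moving average modelling metabolic heat
lag, and ``X_t = φ·X_{t−1} + ε_t`` an AR(1) noise process.  The
innovation ε is a zero-mean two-sided mixture: with probability
``p_up`` a half-normal draw of scale ``sigma_up``, otherwise the
negative of a half-normal draw of scale ``sigma_down`` — the knob that
injects rise/fall asymmetry into the Poincaré partition.

An *iid-increment mode* bypasses the AR process and draws the 1-min
temperature increments directly from the mixture, making the asymptotic
short-term decrease contribution analytically known:

    C1d → (1−p_up)·σ_down² / (p_up·σ_up² + (1−p_up)·σ_down²),

and under the zero-drift constraint ``p_up·σ_up = (1−p_up)·σ_down``
this simplifies to ``C1d → p_up`` (see :meth:`InnovationMix.from_c1d`).

Interventions superimpose a transient ``amplitude·exp(−t/decay)``
response (after a latency) on temperature, and Poisson counts with the
analogous decaying rate on activity.

Reproducibility: one master seed; per-animal generators are spawned
from ``numpy.random.SeedSequence(seed)`` in (group, animal-index)
order, so cohorts of any size are reproducible bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from datetime import date as Date
from datetime import time as Time
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .telemetry import (
    EventRecord,
    PhaseRecording,
    TelemetrySeries,
    light_mask,
    TEMPERATURE_RANGE,
)

_HALF_NORMAL_MEAN = math.sqrt(2.0 / math.pi)


@dataclass(frozen=True)
class BoutParams:
    """Two-state bout process parameters for one group × phase."""

    q_ai: float  # P(active → inactive) per minute
    q_ia: float  # P(inactive → active) per minute
    activity_mean: float  # mean counts during an active minute (≥ 1)

    def __post_init__(self) -> None:
        for name in ("q_ai", "q_ia"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {q}")
        if self.activity_mean < 1.0:
            raise ValueError("activity_mean must be ≥ 1 (counts are positive integers)")

    @property
    def active_fraction(self) -> float:
        return self.q_ia / (self.q_ia + self.q_ai)

    @property
    def mean_active_run(self) -> float:
        return 1.0 / self.q_ai

    @property
    def mean_inactive_run(self) -> float:
        return 1.0 / self.q_ia


@dataclass(frozen=True)
class InnovationMix:
    """Two-sided half-normal sign mixture for temperature innovations."""

    sigma_down: float
    sigma_up: float
    p_up: float

    def __post_init__(self) -> None:
        if self.sigma_down <= 0 or self.sigma_up <= 0:
            raise ValueError("innovation scales must be positive")
        if not 0.0 < self.p_up < 1.0:
            raise ValueError("p_up must lie in (0, 1)")

    @property
    def mean(self) -> float:
        return _HALF_NORMAL_MEAN * (self.p_up * self.sigma_up - (1 - self.p_up) * self.sigma_down)

    @property
    def second_moment(self) -> float:
        return self.p_up * self.sigma_up**2 + (1 - self.p_up) * self.sigma_down**2

    @property
    def c1d_asymptotic(self) -> float:
        """Limit of C1d when the mixture is used as iid 1-min increments."""
        return (1 - self.p_up) * self.sigma_down**2 / self.second_moment

    @classmethod
    def symmetric(cls, sigma: float) -> "InnovationMix":
        return cls(sigma_down=sigma, sigma_up=sigma, p_up=0.5)

    @classmethod
    def from_c1d(cls, c1d: float, sigma_down: float) -> "InnovationMix":
        """Zero-drift mixture whose iid-increment C1d limit equals ``c1d``.

        Setting ``p_up = c1d`` and ``sigma_up = (1−p)/p · sigma_down``
        makes the mixture mean zero and its asymptotic C1d exactly
        ``p_up``.
        """
        if not 0.0 < c1d < 1.0:
            raise ValueError("c1d must lie in (0, 1)")
        return cls(
            sigma_down=sigma_down,
            sigma_up=(1 - c1d) / c1d * sigma_down,
            p_up=c1d,
        )


@dataclass(frozen=True)
class EventResponseParams:
    """Transient intervention response superimposed on both signals."""

    bt_amplitude: float  # °C at response onset
    activity_amplitude: float  # counts/min at response onset
    latency_min: float
    decay_min: float


@dataclass(frozen=True)
class GroupPhenotype:
    bouts: Mapping[str, BoutParams]  # keys "light", "dark"
    innovations: Mapping[str, InnovationMix]
    bt_baseline_light: float
    bt_baseline_dark: float
    coupling_gain: float  # °C per unit of smoothed activity
    ar_coefficient: float  # φ ∈ [0, 1)
    event_response: EventResponseParams

    def __post_init__(self) -> None:
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")

    def baseline(self, phase: str) -> float:
        return self.bt_baseline_light if phase == "light" else self.bt_baseline_dark


@dataclass(frozen=True)
class EventSpec:
    day: int  # 0-based recording day index
    time: Time
    kind: str


def default_control_phenotype() -> GroupPhenotype:
    """Calibrated healthy-rat phenotype (nocturnal, asymmetric BT noise)."""
    return GroupPhenotype(
        bouts={
            "light": BoutParams(q_ai=0.35, q_ia=0.08, activity_mean=5.0),
            "dark": BoutParams(q_ai=0.15, q_ia=0.25, activity_mean=12.0),
        },
        innovations={
            "light": InnovationMix.from_c1d(0.60, sigma_down=0.045),
            "dark": InnovationMix.from_c1d(0.60, sigma_down=0.060),
        },
        bt_baseline_light=36.6,
        bt_baseline_dark=37.3,
        coupling_gain=0.04,
        ar_coefficient=0.98,
        event_response=EventResponseParams(
            bt_amplitude=0.6, activity_amplitude=30.0, latency_min=0.0, decay_min=30.0
        ),
    )


def default_substrain_phenotype() -> GroupPhenotype:
    """Calibrated dysregulated phenotype: hypoactive, fragmented, hot dark
    phase, noisier temperature with blunted asymmetry and blunted,
    delayed intervention responses."""
    return GroupPhenotype(
        bouts={
            "light": BoutParams(q_ai=0.45, q_ia=0.055, activity_mean=4.0),
            "dark": BoutParams(q_ai=0.30, q_ia=0.30, activity_mean=8.0),
        },
        innovations={
            "light": InnovationMix.from_c1d(0.53, sigma_down=0.055),
            "dark": InnovationMix.from_c1d(0.53, sigma_down=0.075),
        },
        bt_baseline_light=36.6,
        bt_baseline_dark=37.65,
        coupling_gain=0.04,
        ar_coefficient=0.98,
        event_response=EventResponseParams(
            bt_amplitude=0.5, activity_amplitude=12.0, latency_min=15.0, decay_min=40.0
        ),
    )


def default_event_schedule() -> list[EventSpec]:
    """5 intervention days out of 13: 2× handling, 2× bed change, 1 injection
    (morning, 08:30–09:00 window)."""
    return [
        EventSpec(day=2, time=Time(10, 0), kind="handling"),
        EventSpec(day=4, time=Time(11, 0), kind="bed_change"),
        EventSpec(day=6, time=Time(8, 45), kind="injection"),
        EventSpec(day=8, time=Time(10, 0), kind="handling"),
        EventSpec(day=10, time=Time(11, 0), kind="bed_change"),
    ]


@dataclass
class SyntheticConfig:
    """Full parameterization of the cohort simulator."""

    n_animals_per_group: int = 6
    n_days: int = 13
    seed: int = 0
    start_date: Date = Date(2015, 1, 5)
    lights_on: Time = Time(6, 0)
    lights_off: Time = Time(18, 0)
    groups: dict[str, GroupPhenotype] = field(
        default_factory=lambda: {
            "control": default_control_phenotype(),
            "substrain": default_substrain_phenotype(),
        }
    )
    events: list[EventSpec] = field(default_factory=default_event_schedule)
    smoothing_minutes: int = 30
    iid_increments: bool = False

    def __post_init__(self) -> None:
        for name, ph in self.groups.items():
            if ph.bouts["dark"].active_fraction <= ph.bouts["light"].active_fraction:
                raise ValueError(
                    f"group {name!r}: dark active fraction must exceed light (nocturnal design)"
                )
        for ev in self.events:
            if not 0 <= ev.day < self.n_days:
                raise ValueError(f"event day {ev.day} outside the {self.n_days}-day design")

    @property
    def start_time(self) -> pd.Timestamp:
        # recordings start at lights-on so every simulated day is complete
        return pd.Timestamp.combine(self.start_date, self.lights_on)

    @property
    def n_minutes(self) -> int:
        return self.n_days * 1440

    def phase_labels(self) -> np.ndarray:
        """Per-minute 'light'/'dark' labels for the whole design."""
        times = pd.date_range(self.start_time, periods=self.n_minutes, freq="min")
        mod = (times.hour * 60 + times.minute).to_numpy()
        return np.where(light_mask(mod, self.lights_on, self.lights_off), "light", "dark")

    def config_hash(self) -> str:
        """Hash of the design excluding the seed (seed-invariant identity)."""
        payload = asdict(self)
        payload.pop("seed")
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


# ---------------------------------------------------------------------------
# primitive simulators
# ---------------------------------------------------------------------------

def _phase_blocks(phases: np.ndarray):
    """Yield (start, stop, label) for contiguous equal-phase stretches."""
    edges = np.flatnonzero(phases[1:] != phases[:-1]) + 1
    starts = np.concatenate([[0], edges])
    stops = np.concatenate([edges, [phases.size]])
    for i0, i1 in zip(starts, stops):
        yield int(i0), int(i1), str(phases[i0])


def simulate_activity(
    phenotype: GroupPhenotype, phases: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Simulate the minute-resolution activity count sequence.

    Each contiguous phase block runs the two-state chain with that
    phase's parameters, starting from its stationary distribution.
    """
    n = phases.size
    states = np.zeros(n, dtype=bool)
    for i0, i1, label in _phase_blocks(phases):
        bouts = phenotype.bouts[label]
        active = bool(rng.random() < bouts.active_fraction)
        i = i0
        while i < i1:
            q = bouts.q_ai if active else bouts.q_ia
            run = int(rng.geometric(q))
            states[i : min(i + run, i1)] = active
            i += run
            active = not active
    counts = np.zeros(n, dtype=float)
    for i0, i1, label in _phase_blocks(phases):
        bouts = phenotype.bouts[label]
        block = states[i0:i1]
        n_active = int(block.sum())
        if n_active:
            counts[i0:i1][block] = rng.geometric(1.0 / bouts.activity_mean, size=n_active)
    return counts


def _sample_mixture(
    mix: InnovationMix, size: int, rng: np.random.Generator, *, centered: bool
) -> np.ndarray:
    up = rng.random(size) < mix.p_up
    mag = np.abs(rng.normal(0.0, 1.0, size))
    draws = np.where(up, mag * mix.sigma_up, -mag * mix.sigma_down)
    return draws - mix.mean if centered else draws


def _trailing_mean(x: np.ndarray, window: int) -> np.ndarray:
    c = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    idx = np.arange(x.size)
    lo = np.maximum(0, idx - window + 1)
    return (c[idx + 1] - c[lo]) / (idx + 1 - lo)


def simulate_temperature(
    phenotype: GroupPhenotype,
    phases: np.ndarray,
    activity: np.ndarray,
    rng: np.random.Generator,
    *,
    smoothing_minutes: int = 30,
    iid_increments: bool = False,
    bt_start: float = 37.0,
) -> np.ndarray:
    """Simulate the temperature sequence given the activity sequence."""
    n = phases.size
    if iid_increments:
        steps = np.empty(n)
        for i0, i1, label in _phase_blocks(phases):
            steps[i0:i1] = _sample_mixture(
                phenotype.innovations[label], i1 - i0, rng, centered=False
            )
        bt = bt_start + np.cumsum(steps)
        return np.clip(bt, *TEMPERATURE_RANGE)

    eps = np.empty(n)
    for i0, i1, label in _phase_blocks(phases):
        eps[i0:i1] = _sample_mixture(phenotype.innovations[label], i1 - i0, rng, centered=True)
    phi = phenotype.ar_coefficient
    sigma0 = math.sqrt(phenotype.innovations[str(phases[0])].second_moment)
    x0 = rng.normal(0.0, sigma0 / math.sqrt(max(1.0 - phi**2, 1e-12)))
    x, _ = lfilter([1.0], [1.0, -phi], eps, zi=np.array([phi * x0]))

    baseline = np.where(
        phases == "light", phenotype.bt_baseline_light, phenotype.bt_baseline_dark
    )
    coupled = phenotype.coupling_gain * _trailing_mean(activity, smoothing_minutes)
    return np.clip(baseline + coupled + x, *TEMPERATURE_RANGE)


def _apply_event_kernels(
    bt: np.ndarray,
    activity: np.ndarray,
    event_indices: Sequence[int],
    params: EventResponseParams,
    rng: np.random.Generator,
) -> None:
    """Add exponential-decay transients (in place) after each event."""
    n = bt.size
    span = max(1, int(round(8 * params.decay_min)))
    for e in event_indices:
        onset = e + int(round(params.latency_min))
        stop = min(n, onset + span)
        if onset >= n:
            continue
        t_rel = np.arange(stop - onset, dtype=float)
        kernel = np.exp(-t_rel / params.decay_min)
        bt[onset:stop] += params.bt_amplitude * kernel
        if params.activity_amplitude > 0:
            activity[onset:stop] += rng.poisson(params.activity_amplitude * kernel)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

def _animal_rngs(config: SyntheticConfig) -> dict[str, list[np.random.Generator]]:
    root = np.random.SeedSequence(config.seed)
    children = root.spawn(len(config.groups) * config.n_animals_per_group)
    out: dict[str, list[np.random.Generator]] = {}
    k = 0
    for group in sorted(config.groups):
        out[group] = [np.random.default_rng(children[k + i]) for i in range(config.n_animals_per_group)]
        k += config.n_animals_per_group
    return out


def simulate_series(
    config: SyntheticConfig, group: str, animal_id: str, rng: np.random.Generator
) -> TelemetrySeries:
    """Simulate one animal's full multi-day telemetry record with events."""
    phenotype = config.groups[group]
    phases = config.phase_labels()
    activity = simulate_activity(phenotype, phases, rng)

    start = config.start_time
    event_records: list[EventRecord] = []
    event_indices: list[int] = []
    for ev in config.events:
        ts = pd.Timestamp.combine(config.start_date, ev.time) + pd.Timedelta(days=ev.day)
        idx = int((ts - start) / pd.Timedelta(minutes=1))
        if 0 <= idx < config.n_minutes:
            event_records.append(EventRecord(time=ts, kind=ev.kind))
            event_indices.append(idx)

    # temperature rides on the full (baseline + event-induced) activity
    bt_kernel = np.zeros(config.n_minutes)
    _apply_event_kernels(bt_kernel, activity, event_indices, phenotype.event_response, rng)
    bt = simulate_temperature(
        phenotype,
        phases,
        activity,
        rng,
        smoothing_minutes=config.smoothing_minutes,
        iid_increments=config.iid_increments,
    )
    bt = np.clip(bt + bt_kernel, *TEMPERATURE_RANGE)

    # daily light transitions in the log
    for day in range(config.n_days):
        base = pd.Timestamp(config.start_date) + pd.Timedelta(days=day)
        for clock, kind in ((config.lights_on, "lights_on"), (config.lights_off, "lights_off")):
            ts = pd.Timestamp.combine(base.date(), clock)
            if start <= ts <= start + (config.n_minutes - 1) * pd.Timedelta(minutes=1):
                event_records.append(EventRecord(time=ts, kind=kind))

    return TelemetrySeries(
        animal_id=animal_id,
        group=group,
        start_time=start,
        temperature=bt,
        activity=activity,
        events=event_records,
    )


def simulate_cohort(config: SyntheticConfig) -> list[TelemetrySeries]:
    """Simulate the full two-group cohort from one master seed."""
    rngs = _animal_rngs(config)
    cohort: list[TelemetrySeries] = []
    for group in sorted(config.groups):
        for i, rng in enumerate(rngs[group]):
            cohort.append(simulate_series(config, group, f"{group}-{i + 1:02d}", rng))
    return cohort


def simulate_phase_recording(
    config: SyntheticConfig,
    group: str,
    phase: str,
    seed,
    *,
    n_minutes: int = 720,
) -> PhaseRecording:
    """Simulate a single stand-alone phase recording (no events).

    Convenience entry point for calibration and recovery experiments:
    one animal, one phase, ``n_minutes`` of data under that phase's
    parameters.
    """
    rng = np.random.default_rng(seed)
    phenotype = config.groups[group]
    phases = np.full(n_minutes, phase, dtype=object)
    activity = simulate_activity(phenotype, phases, rng)
    bt = simulate_temperature(
        phenotype,
        phases,
        activity,
        rng,
        smoothing_minutes=config.smoothing_minutes,
        iid_increments=config.iid_increments,
    )
    return PhaseRecording(
        animal_id="sim-00",
        group=group,
        date=config.start_date,
        phase=phase,
        condition="undisturbed",
        temperature=bt,
        activity=activity,
    )


def iid_increment_series(
    mix: InnovationMix, n_minutes: int, seed, *, bt_start: float = 37.0
) -> np.ndarray:
    """Temperature series whose 1-min increments are iid mixture draws.

    The asymptotic short-term decrease contribution of this series is
    ``mix.c1d_asymptotic`` (exact ratio of expected squared decrease to
    total squared increment).
    """
    rng = np.random.default_rng(seed)
    steps = _sample_mixture(mix, n_minutes - 1, rng, centered=False)
    return np.concatenate([[bt_start], bt_start + np.cumsum(steps)])
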