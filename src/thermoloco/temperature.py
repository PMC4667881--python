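"""Scalar body-temperature descriptors for one phase recording.

Covers the epoch-mean temperature, the extrema and amplitude, and the
mean magnitudes of consecutive-minute increases and decreases.  The
mean is the mean of per-1-h-epoch means (with complete data this equals
the raw grand mean); consecutive differences are only computed between
adjacent non-missing samples, and zero differences belong to neither
change mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .telemetry import PhaseRecording


@dataclass(frozen=True)
class TemperatureDescriptors:
    bt_mean: float  # mean of hourly means, °C
    bt_min: float
    bt_max: float
    bt_amplitude: float  # bt_max − bt_min
    mean_increase: float  # mean of positive consecutive differences (NaN if none)
    mean_decrease: float  # mean magnitude of negative consecutive differences


def compute_temperature_descriptors(rec, *, epoch_minutes: int = 60) -> TemperatureDescriptors:
    """Compute the temperature descriptor set for one recording.

    Epoch means use whatever valid samples each complete
    ``epoch_minutes`` window contains; when the recording is shorter
    than one epoch the grand mean over valid samples is used.
    """
    bt = rec.temperature if isinstance(rec, PhaseRecording) else np.asarray(rec, dtype=float)
    valid = ~np.isnan(bt)
    if valid.sum() < 2:
        raise ValueError("need at least 2 valid temperature samples")

    epoch_means = []
    for k in range(bt.size // epoch_minutes):
        window = bt[k * epoch_minutes : (k + 1) * epoch_minutes]
        if not np.isnan(window).all():
            epoch_means.append(np.nanmean(window))
    bt_mean = float(np.mean(epoch_means)) if epoch_means else float(np.mean(bt[valid]))

    bt_min = float(np.min(bt[valid]))
    bt_max = float(np.max(bt[valid]))

    adjacent = valid[:-1] & valid[1:]
    diffs = (bt[1:] - bt[:-1])[adjacent]
    ups = diffs[diffs > 0]
    downs = diffs[diffs < 0]
    return TemperatureDescriptors(
        bt_mean=bt_mean,
        bt_min=bt_min,
        bt_max=bt_max,
        bt_amplitude=bt_max - bt_min,
        mean_increase=float(np.mean(ups)) if ups.size else math.nan,
        mean_decrease=float(np.mean(-downs)) if downs.size else math.nan,
    )
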