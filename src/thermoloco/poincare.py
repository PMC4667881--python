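"""Poincaré-plot variability and asymmetry analysis of a temperature series.

The Poincaré plot of a minute-sampled body-temperature series is the
lag-1 return map: each point has coordinates (BT_n, BT_{n+1}).  Points
on the identity line x = y are minutes with no change; points above it
are temperature increases, points below it decreases.

Descriptors
-----------
Rotating the plot by 45° maps the identity line onto the new x-axis.
With Δ_n = BT_{n+1} − BT_n and N valid pairs,

* ``SD1`` (short-term variability) is the dispersion of points
  *across* the identity line: ``SD1² = Σ Δ² / (2(N−1))`` — the second
  moment of the signed perpendicular distance to the line itself.
* ``SD2`` (long-term variability) is the dispersion *along* the line
  about the centroid: ``SD2² = Σ D² / (N−1)`` with
  ``D_n = (BT_n + BT_{n+1} − 2m)/√2`` and ``m`` the mean over all pair
  coordinates.
* ``SDNN² = (SD1² + SD2²)/2`` — the total variability, matching the
  series' overall standard deviation about ``m``.

Asymmetry partition
-------------------
The variance-based descriptors are split by the sign of Δ:

* ``SD1d² = Σ_{Δ<0} Δ² / (2(N−1))``, ``SD1i²`` likewise for Δ>0, so
  ``SD1d² + SD1i² = SD1²`` exactly (on-line points contribute nothing).
* ``SD2d² = [Σ_{Δ<0} D² + ½ Σ_{Δ=0} D²] / (N−1)`` and symmetrically for
  increases, so ``SD2d² + SD2i² = SD2²`` exactly (on-line points split
  equally, preserving the decomposition).
* Relative contributions ``C1d = SD1d²/SD1²`` etc., with
  ``C1d + C1i = C2d + C2i = 1``.

A recording is *short-term asymmetric* when SD1d > SD1i (decreases
dominate the short-term variance) and *long-term asymmetric* when
SD2i > SD2d; exact ties classify as not asymmetric.

Sample (N−1) denominators are used throughout.  The default lag is one
sample (1 min), exposed as a parameter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .telemetry import PhaseRecording

_SQRT2 = math.sqrt(2.0)


class PoincareError(ValueError):
    """Raised when a recording has too few valid pairs for analysis."""


@dataclass(frozen=True)
class PoincareDescriptors:
    """SD1/SD2/SDNN and the decrease/increase partition for one recording."""

    n_pairs: int
    sd1: float
    sd2: float
    sdnn: float
    sd1d: float
    sd1i: float
    sd2d: float
    sd2i: float
    c1d: float
    c1i: float
    c2d: float
    c2i: float


@dataclass(frozen=True)
class AsymmetryClassification:
    short_term_asymmetric: bool  # SD1d > SD1i
    long_term_asymmetric: bool  # SD2i > SD2d


def lagged_pairs(bt: np.ndarray, lag: int = 1) -> tuple[np.ndarray, np.ndarray]:
    """Return the valid (BT_n, BT_{n+lag}) coordinate arrays.

    Pairs spanning a missing sample are dropped; order is preserved.
    """
    bt = np.asarray(bt, dtype=float)
    if lag < 1:
        raise ValueError("lag must be a positive integer")
    if bt.size <= lag:
        raise PoincareError(f"series of length {bt.size} has no lag-{lag} pairs")
    x, y = bt[:-lag], bt[lag:]
    valid = ~(np.isnan(x) | np.isnan(y))
    return x[valid], y[valid]


def sd1_sd2(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Compute (SD1, SD2, SDNN) from the pair coordinate arrays."""
    n = x.size
    if n < 2:
        raise PoincareError("need at least 2 valid pairs")
    delta = y - x
    sd1_sq = float(np.sum(delta**2)) / (2.0 * (n - 1))
    m = float(np.mean(np.concatenate([x, y])))
    d_along = (x + y - 2.0 * m) / _SQRT2
    sd2_sq = float(np.sum(d_along**2)) / (n - 1)
    return math.sqrt(sd1_sq), math.sqrt(sd2_sq), math.sqrt(0.5 * (sd1_sq + sd2_sq))


def asymmetry_partition(
    x: np.ndarray, y: np.ndarray
) -> tuple[float, float, float, float, float, float, float, float]:
    """Partition SD1²/SD2² by temperature decreases and increases.

    Returns ``(sd1d, sd1i, sd2d, sd2i, c1d, c1i, c2d, c2i)``.  The
    contribution ratios are NaN when the corresponding variance is zero.
    """
    n = x.size
    if n < 2:
        raise PoincareError("need at least 2 valid pairs")
    delta = y - x
    dec, inc, flat = delta < 0, delta > 0, delta == 0

    denom1 = 2.0 * (n - 1)
    sd1d_sq = float(np.sum(delta[dec] ** 2)) / denom1
    sd1i_sq = float(np.sum(delta[inc] ** 2)) / denom1

    m = float(np.mean(np.concatenate([x, y])))
    d_sq = ((x + y - 2.0 * m) / _SQRT2) ** 2
    half_flat = 0.5 * float(np.sum(d_sq[flat]))
    sd2d_sq = (float(np.sum(d_sq[dec])) + half_flat) / (n - 1)
    sd2i_sq = (float(np.sum(d_sq[inc])) + half_flat) / (n - 1)

    sd1_sq = sd1d_sq + sd1i_sq
    sd2_sq = sd2d_sq + sd2i_sq
    c1d = sd1d_sq / sd1_sq if sd1_sq > 0 else math.nan
    c1i = sd1i_sq / sd1_sq if sd1_sq > 0 else math.nan
    c2d = sd2d_sq / sd2_sq if sd2_sq > 0 else math.nan
    c2i = sd2i_sq / sd2_sq if sd2_sq > 0 else math.nan
    return (
        math.sqrt(sd1d_sq),
        math.sqrt(sd1i_sq),
        math.sqrt(sd2d_sq),
        math.sqrt(sd2i_sq),
        c1d,
        c1i,
        c2d,
        c2i,
    )


def poincare_descriptors(
    bt_or_recording: np.ndarray | PhaseRecording, lag: int = 1
) -> PoincareDescriptors:
    """Full Poincaré descriptor set for a temperature series or recording."""
    if isinstance(bt_or_recording, PhaseRecording):
        bt = bt_or_recording.temperature
    else:
        bt = np.asarray(bt_or_recording, dtype=float)
    x, y = lagged_pairs(bt, lag=lag)
    sd1, sd2, sdnn = sd1_sd2(x, y)
    sd1d, sd1i, sd2d, sd2i, c1d, c1i, c2d, c2i = asymmetry_partition(x, y)
    return PoincareDescriptors(
        n_pairs=int(x.size),
        sd1=sd1,
        sd2=sd2,
        sdnn=sdnn,
        sd1d=sd1d,
        sd1i=sd1i,
        sd2d=sd2d,
        sd2i=sd2i,
        c1d=c1d,
        c1i=c1i,
        c2d=c2d,
        c2i=c2i,
    )


def classify_asymmetry(desc: PoincareDescriptors) -> AsymmetryClassification:
    """Strict-inequality asymmetry calls; exact ties are not asymmetric."""
    return AsymmetryClassification(
        short_term_asymmetric=desc.sd1d > desc.sd1i,
        long_term_asymmetric=desc.sd2i > desc.sd2d,
    )
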