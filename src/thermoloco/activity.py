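"""Locomotor-activity descriptors for one light/dark phase recording.

The descriptors quantify both the amount of movement and the
fragmentation of the rest–activity pattern:

* ``AL`` — activity level: mean count sum per 1-h epoch,
* ``MI`` — movement index: percentage of minutes with a count above the
  activity threshold (default: count > 0),
* ``RMI`` — relative movement index: mean count over active minutes,
* ``PN`` — phase number: total number of maximal active/inactive runs,
* ``DI`` / ``DA`` — mean duration (min) of uninterrupted immobility /
  activity runs.

Runs are maximal stretches of consecutive minutes sharing the activity
predicate.  Missing minutes break runs by default (a run must be
uninterrupted); ``bridge_single_missing=True`` lets a lone missing
minute flanked by same-state minutes extend the run (the bridged minute
counts toward the run length but not toward MI/RMI).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .telemetry import PhaseRecording

ACTIVE, INACTIVE = "active", "inactive"


@dataclass(frozen=True)
class ActivityDescriptors:
    al: float  # mean counts per 1-h epoch
    mi: float  # % of minutes with count > threshold
    rmi: float  # mean counts over active minutes (NaN if none)
    pn: int  # total number of runs
    di: float  # mean inactive-run length, min (NaN if none)
    da: float  # mean active-run length, min (NaN if none)


def _counts(rec) -> np.ndarray:
    if isinstance(rec, PhaseRecording):
        return rec.activity
    return np.asarray(rec, dtype=float)


def run_segmentation(
    activity,
    threshold: float = 0.0,
    *,
    min_bout: int = 1,
    bridge_single_missing: bool = False,
) -> list[tuple[str, int]]:
    """Segment a count sequence into maximal active/inactive runs.

    Returns (state, length-in-minutes) pairs in temporal order.  Run
    lengths sum to the number of minutes covered (valid minutes, plus
    bridged missing minutes when bridging is enabled).  Runs shorter
    than ``min_bout`` are greedily merged into the preceding run (the
    leading run merges forward) — a smoothing heuristic, default off.
    """
    counts = np.asarray(activity, dtype=float)
    if counts.size == 0:
        return []
    valid = ~np.isnan(counts)
    state = np.where(counts > threshold, 1, 0)  # meaningful only where valid

    if bridge_single_missing:
        v = valid.copy()
        for i in np.flatnonzero(~valid):
            if 0 < i < counts.size - 1 and valid[i - 1] and valid[i + 1]:
                if state[i - 1] == state[i + 1]:
                    v[i] = True
                    state[i] = state[i - 1]
        valid = v

    runs: list[tuple[str, int]] = []
    cur_state, cur_len = None, 0
    for i in range(counts.size):
        if not valid[i]:
            if cur_len:
                runs.append((cur_state, cur_len))
            cur_state, cur_len = None, 0
            continue
        s = ACTIVE if state[i] else INACTIVE
        if s == cur_state:
            cur_len += 1
        else:
            if cur_len:
                runs.append((cur_state, cur_len))
            cur_state, cur_len = s, 1
    if cur_len:
        runs.append((cur_state, cur_len))

    if min_bout > 1:
        runs = _merge_short_runs(runs, min_bout)
    return runs


def _merge_short_runs(runs: list[tuple[str, int]], min_bout: int) -> list[tuple[str, int]]:
    # Greedy forward merge: a run shorter than min_bout is absorbed by the
    # run before it (the first run, by the one after). Iterate to a fixed
    # point; total length is conserved.
    runs = list(runs)
    changed = True
    while changed and len(runs) > 1:
        changed = False
        for i, (state, length) in enumerate(runs):
            if length < min_bout:
                j = i - 1 if i > 0 else i + 1
                absorbed_state = runs[j][0]
                runs[j] = (absorbed_state, runs[j][1] + length)
                del runs[i]
                # re-coalesce neighbours of equal state
                k = min(i, j)
                while k + 1 < len(runs) and runs[k][0] == runs[k + 1][0]:
                    runs[k] = (runs[k][0], runs[k][1] + runs[k + 1][1])
                    del runs[k + 1]
                changed = True
                break
    return runs


def compute_activity_descriptors(
    rec,
    *,
    threshold: float = 0.0,
    epoch_minutes: int = 60,
    min_bout: int = 1,
    bridge_single_missing: bool = False,
) -> ActivityDescriptors:
    """Compute the full activity descriptor set for one recording.

    ``AL`` averages the count sums of complete, fully valid
    ``epoch_minutes`` windows aligned to the recording start (partial or
    gap-containing windows are excluded).  With zero active minutes, RMI
    and DA are NaN rather than zero.
    """
    counts = _counts(rec)
    valid = ~np.isnan(counts)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise ValueError("recording has no valid activity samples")

    active = valid & (counts > threshold)
    mi = 100.0 * active.sum() / n_valid
    rmi = float(np.mean(counts[active])) if active.any() else math.nan

    sums = []
    for k in range(counts.size // epoch_minutes):
        window = counts[k * epoch_minutes : (k + 1) * epoch_minutes]
        if not np.isnan(window).any():
            sums.append(window.sum())
    al = float(np.mean(sums)) if sums else math.nan

    runs = run_segmentation(
        counts, threshold, min_bout=min_bout, bridge_single_missing=bridge_single_missing
    )
    inactive_lens = [length for s, length in runs if s == INACTIVE]
    active_lens = [length for s, length in runs if s == ACTIVE]
    return ActivityDescriptors(
        al=al,
        mi=float(mi),
        rmi=rmi,
        pn=len(runs),
        di=float(np.mean(inactive_lens)) if inactive_lens else math.nan,
        da=float(np.mean(active_lens)) if active_lens else math.nan,
    )
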