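"""Shared fixtures: a session-wide default synthetic cohort and its pools."""

from __future__ import annotations

import numpy as np
import pytest

import thermoloco as tl

#: fixed study seed for the shared cohort
COHORT_SEED = 11


@pytest.fixture(scope="session")
def default_config() -> tl.SyntheticConfig:
    return tl.SyntheticConfig(seed=COHORT_SEED)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    """Full two-group cohort under the default study design."""
    return tl.simulate_cohort(default_config)


@pytest.fixture(scope="session")
def pooled_recordings(default_cohort):
    """dict[(group, phase, condition)] -> pooled PhaseRecording list."""
    recs = [r for s in default_cohort for r in tl.split_phases(s)]
    pools = {}
    for group in ("control", "substrain"):
        sub = [r for r in recs if r.group == group]
        for phase in ("light", "dark"):
            for condition in ("undisturbed", "disturbed"):
                pools[(group, phase, condition)] = tl.pool_recordings(sub, phase, condition)
    return pools


@pytest.fixture(scope="session")
def pooled_descriptors(pooled_recordings):
    """Poincaré + activity + temperature descriptors for undisturbed pools."""
    out = {}
    for (group, phase, condition), recs in pooled_recordings.items():
        if condition != "undisturbed":
            continue
        out[(group, phase)] = {
            "poincare": [tl.poincare_descriptors(r) for r in recs],
            "activity": [tl.compute_activity_descriptors(r) for r in recs],
            "temperature": [tl.compute_temperature_descriptors(r) for r in recs],
        }
    return out


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


def make_series(
    temperature,
    activity=None,
    *,
    animal_id="r01",
    group="control",
    start="2015-01-05 06:00",
    events=(),
) -> tl.TelemetrySeries:
    """Small helper to build a TelemetrySeries from raw arrays."""
    temperature = np.asarray(temperature, dtype=float)
    if activity is None:
        activity = np.zeros_like(temperature)
    return tl.TelemetrySeries(
        animal_id=animal_id,
        group=group,
        start_time=start,
        temperature=temperature,
        activity=np.asarray(activity, dtype=float),
        events=list(events),
    )
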