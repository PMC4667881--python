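"""End-to-end analysis pipeline: series → recordings → descriptors → reports.

Outputs written to the run directory:

* ``recording_descriptors.csv`` — one row per pooled recording with the
  activity, temperature and Poincaré descriptors,
* ``asymmetry_summary.csv`` — asymmetry counts, contributions and
  group-level tests per group × phase × term,
* ``event_responses.csv`` — pooled epoch-wise response deltas
  (mean ± SEM) per group for light transitions and interventions,
* ``manifest.json`` — seed, config hash, recording counts, file list,
* ``config_resolved.yaml`` — the resolved run configuration.

Runs are fully reproducible from (config, input files); descriptor CSVs
are byte-identical across reruns with the same seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from datetime import time as Time
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .activity import compute_activity_descriptors
from .events import intervention_profiles, pool_event_profiles, response_profile
from .groupstats import summaries_to_frame, summarize_asymmetry
from .poincare import PoincareError, poincare_descriptors
from .synthetic import SyntheticConfig, simulate_cohort
from .telemetry import (
    PHASES,
    TelemetrySeries,
    pool_recordings,
    read_telemetry_csv,
    split_phases,
    write_events_csv,
    write_telemetry_csv,
)
from .temperature import compute_temperature_descriptors

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.10g"


@dataclass
class RunConfig:
    output_dir: Path
    seed: int = 0
    simulate: bool = True
    telemetry_csv: Path | None = None
    events_csv: Path | None = None
    synthetic: SyntheticConfig | None = None
    lights_on: Time = Time(6, 0)
    lights_off: Time = Time(18, 0)
    max_missing_frac: float = 0.05
    lag: int = 1
    write_inputs: bool = True  # persist simulated telemetry/event CSVs

    def resolved_synthetic(self) -> SyntheticConfig:
        if self.synthetic is not None:
            return self.synthetic
        return SyntheticConfig(seed=self.seed, lights_on=self.lights_on, lights_off=self.lights_off)


def _load_series(config: RunConfig) -> list[TelemetrySeries]:
    if config.simulate:
        return simulate_cohort(config.resolved_synthetic())
    if config.telemetry_csv is None:
        raise ValueError("analysis run requires telemetry_csv when simulate=False")
    return read_telemetry_csv(config.telemetry_csv, config.events_csv)


def _descriptor_row(rec, lag: int) -> dict:
    row = {
        "animal_id": rec.animal_id,
        "group": rec.group,
        "date": rec.date.isoformat(),
        "phase": rec.phase,
        "condition": rec.condition,
        "n_samples": rec.n_samples,
    }
    act = compute_activity_descriptors(rec)
    temp = compute_temperature_descriptors(rec)
    row.update({f"act_{k}": v for k, v in dataclasses.asdict(act).items()})
    row.update({f"bt_{k}": v for k, v in dataclasses.asdict(temp).items()})
    try:
        poi = poincare_descriptors(rec, lag=lag)
        row.update({f"poincare_{k}": v for k, v in dataclasses.asdict(poi).items()})
    except PoincareError:
        logger.warning("Poincaré analysis failed for %s %s %s", rec.animal_id, rec.date, rec.phase)
    return row


def _pooled_response_rows(series_list: list[TelemetrySeries]) -> list[dict]:
    rows: list[dict] = []
    groups = sorted({s.group for s in series_list})
    for group in groups:
        members = [s for s in series_list if s.group == group]
        pools = {
            "intervention": [p for s in members for p in intervention_profiles(s)],
            "lights_on": [
                response_profile(s, ev)
                for s in members
                for ev in s.events
                if ev.kind == "lights_on"
            ],
            "lights_off": [
                response_profile(s, ev)
                for s in members
                for ev in s.events
                if ev.kind == "lights_off"
            ],
        }
        for label, profiles in pools.items():
            usable = [p for p in profiles if p.complete]
            if not usable:
                continue
            pooled = pool_event_profiles(usable, label=label)
            for k in range(pooled.bt_delta_mean.size):
                rows.append(
                    {
                        "group": group,
                        "label": label,
                        "epoch": k + 1,
                        "epoch_end_min": (k + 1) * pooled.epoch_minutes,
                        "n_profiles": pooled.n_profiles,
                        "bt_delta_mean": pooled.bt_delta_mean[k],
                        "bt_delta_sem": pooled.bt_delta_sem[k],
                        "activity_delta_mean": pooled.activity_delta_mean[k],
                        "activity_delta_sem": pooled.activity_delta_sem[k],
                    }
                )
    return rows


def _write_csv(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# thermoloco v{__version__}\n")
        df.to_csv(fh, index=False, float_format=_FLOAT_FMT)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full pipeline and return the manifest dictionary."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    series_list = _load_series(config)
    if not series_list:
        raise ValueError("no telemetry series to analyze")

    if config.simulate and config.write_inputs:
        write_telemetry_csv(series_list, out / "telemetry.csv")
        write_events_csv(series_list, out / "events.csv")

    recordings = [
        rec
        for s in series_list
        for rec in split_phases(s, config.lights_on, config.lights_off)
    ]
    pooled = pool_recordings(recordings, max_missing_frac=config.max_missing_frac)
    if not pooled:
        raise ValueError("no valid recordings after pooling")

    desc_rows = [_descriptor_row(rec, config.lag) for rec in pooled]
    desc_df = pd.DataFrame(desc_rows)
    _write_csv(desc_df, out / "recording_descriptors.csv")

    # asymmetry analysis on undisturbed recordings only
    undisturbed = [r for r in pooled if r.condition == "undisturbed"]
    labelled = []
    for rec in undisturbed:
        try:
            labelled.append((rec.group, rec.phase, poincare_descriptors(rec, lag=config.lag)))
        except PoincareError:
            continue
    summary_rows = summarize_asymmetry(labelled)
    _write_csv(summaries_to_frame(summary_rows), out / "asymmetry_summary.csv")

    response_rows = _pooled_response_rows(series_list)
    _write_csv(pd.DataFrame(response_rows), out / "event_responses.csv")

    counts = {
        f"{g}/{ph}/{cond}": sum(
            1 for r in pooled if r.group == g and r.phase == ph and r.condition == cond
        )
        for g in sorted({r.group for r in pooled})
        for ph in PHASES
        for cond in ("undisturbed", "disturbed")
    }
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "simulated": config.simulate,
        "config_hash": config.resolved_synthetic().config_hash() if config.simulate else None,
        "n_series": len(series_list),
        "n_recordings_pooled": len(pooled),
        "recording_counts": counts,
        "files": [
            "recording_descriptors.csv",
            "asymmetry_summary.csv",
            "event_responses.csv",
        ],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(_config_to_plain(config), fh, sort_keys=True)
    return manifest


def _config_to_plain(config: RunConfig) -> dict:
    plain = dataclasses.asdict(config)
    if config.simulate:
        plain["synthetic"] = dataclasses.asdict(config.resolved_synthetic())
    return json.loads(json.dumps(plain, default=str))
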