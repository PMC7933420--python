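"""Tabular readers/writers (TSV with header, UTF-8, '.' decimal), YAML
configuration, and the pipeline driver.

Formats
-------
trace TSV:     time_ms, x_deg, y_deg          (uniform grid; rate inferred)
saccade TSV:   onset_ms, offset_ms, start_x_deg, start_y_deg, end_x_deg,
               end_y_deg, amplitude_deg, direction_deg
trial TSV:     trial_id, task, fix_on_ms, fix_off_ms, target_on_ms,
               target_dir_deg, target_ecc_deg
outcome TSV:   trial columns + outcome, rt_ms, dir_err_deg, ecc_err_deg
spike TSV:     trial_id, t_ms (relative to target onset), fix_off_ms,
               saccade_on_ms, in_rf
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .eyekin import EyeTrace, SaccadeEvent
from .synthgen import SpikeDataset, SpikeTrial
from .trials import TrialEvents, TrialRecord

__all__ = [
    "read_trace",
    "write_trace",
    "read_saccades",
    "write_saccades",
    "read_trial_events",
    "write_trial_events",
    "write_outcomes",
    "read_spikes",
    "write_spikes",
    "load_config",
    "config_hash",
    "write_json",
]


class FormatError(ValueError):
    """Malformed input file."""


def read_trace(path: str | Path) -> EyeTrace:
    df = pd.read_csv(path, sep="\t")
    for col in ("time_ms", "x_deg", "y_deg"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    t = df["time_ms"].to_numpy(dtype=float)
    if len(t) < 2:
        raise FormatError(f"{path}: need at least 2 samples")
    dt = np.diff(t)
    step = np.median(dt)
    bad = np.nonzero(np.abs(dt - step) > 1e-6 * step)[0]
    if len(bad):
        row = int(bad[0]) + 2  # +1 for header, +1 for 1-based rows
        raise FormatError(
            f"{path}: non-uniform time grid at data row {row} "
            f"(step {dt[bad[0]]:.6g} ms, expected {step:.6g} ms)"
        )
    rate = 1000.0 / step
    # snap to the two supported rates when within rounding error
    for r in (250.0, 1000.0):
        if abs(rate - r) < 1e-6 * r:
            rate = r
    return EyeTrace(time=t, x=df["x_deg"].to_numpy(float), y=df["y_deg"].to_numpy(float), sampling_rate=rate)


def write_trace(trace: EyeTrace, path: str | Path) -> None:
    pd.DataFrame({"time_ms": trace.time, "x_deg": trace.x, "y_deg": trace.y}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def write_saccades(events: list[SaccadeEvent], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "onset_ms": e.onset_ms,
                "offset_ms": e.offset_ms,
                "start_x_deg": e.start[0],
                "start_y_deg": e.start[1],
                "end_x_deg": e.end[0],
                "end_y_deg": e.end[1],
                "amplitude_deg": e.amplitude_deg,
                "direction_deg": e.direction_deg,
            }
            for e in events
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_saccades(path: str | Path) -> list[SaccadeEvent]:
    df = pd.read_csv(path, sep="\t")
    return [
        SaccadeEvent(
            onset_ms=r.onset_ms,
            offset_ms=r.offset_ms,
            start=(r.start_x_deg, r.start_y_deg),
            end=(r.end_x_deg, r.end_y_deg),
        )
        for r in df.itertuples()
    ]


def write_trial_events(trials: list[TrialEvents], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id,
                "task": t.task,
                "fix_on_ms": t.fix_on_ms,
                "fix_off_ms": t.fix_off_ms,
                "target_on_ms": t.target_on_ms,
                "target_dir_deg": t.target_direction_deg,
                "target_ecc_deg": t.target_eccentricity_deg,
            }
            for t in trials
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_trial_events(path: str | Path) -> list[TrialEvents]:
    df = pd.read_csv(path, sep="\t")
    return [
        TrialEvents(
            task=r.task,
            fix_on_ms=r.fix_on_ms,
            fix_off_ms=r.fix_off_ms,
            target_on_ms=r.target_on_ms,
            target_direction_deg=r.target_dir_deg,
            target_eccentricity_deg=r.target_ecc_deg,
            trial_id=int(r.trial_id),
        )
        for r in df.itertuples()
    ]


def write_outcomes(records: list[TrialRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "trial_id": r.events.trial_id,
                "task": r.events.task,
                "target_dir_deg": r.events.target_direction_deg,
                "target_ecc_deg": r.events.target_eccentricity_deg,
                "outcome": r.outcome.value,
                "rt_ms": r.reaction_time_ms,
                "dir_err_deg": r.direction_error_deg,
                "ecc_err_deg": r.eccentricity_error_deg,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_spikes(dataset: SpikeDataset, path: str | Path) -> None:
    rows = []
    for i, tr in enumerate(dataset.trials):
        for s in tr.spikes_ms:
            rows.append(
                {
                    "trial_id": i,
                    "t_ms": s,
                    "fix_off_ms": tr.fix_off_ms,
                    "saccade_on_ms": tr.saccade_on_ms,
                    "in_rf": int(tr.in_rf),
                }
            )
    pd.DataFrame(rows, columns=["trial_id", "t_ms", "fix_off_ms", "saccade_on_ms", "in_rf"]).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_spikes(path: str | Path) -> SpikeDataset:
    df = pd.read_csv(path, sep="\t")
    trials = []
    for _, g in df.groupby("trial_id", sort=True):
        trials.append(
            SpikeTrial(
                spikes_ms=np.sort(g["t_ms"].to_numpy(float)),
                target_on_ms=0.0,
                fix_off_ms=float(g["fix_off_ms"].iloc[0]),
                saccade_on_ms=float(g["saccade_on_ms"].iloc[0]),
                in_rf=bool(g["in_rf"].iloc[0]),
            )
        )
    return SpikeDataset(trials)


def load_config(path: str | Path) -> dict:
    with open(path, encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a key/value mapping")
    return cfg


def config_hash(cfg: dict) -> str:
    """Stable hash of a resolved configuration, recorded as provenance."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n", encoding="utf-8")
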