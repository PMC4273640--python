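"""Delimited-text readers and writers, configuration, and run manifests.

All artifacts are tab-separated text with a header row:

- period records: one row per triplet-period (column order fixed by
  ``PERIOD_COLUMNS``);
- event markers: one row per on-screen event (``MARKER_COLUMNS``);
- traces: two columns (time_s, conductance_uS), one file per subject,
  named ``<subject>.tsv``;
- SCR ground truth / detected SCR tables / waveform test results:
  self-describing headers.

Session configuration is a flat YAML mapping whose keys match
:class:`~physioecon.simulate.SessionConfig` fields.  A JSON run manifest
(config snapshot, seed, file list, package version, timestamp) is written
next to every output set so any run can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .edasynth import EDATrace, SCRGroundTruth
from .pipeline import SCREvent
from .simulate import EventMarker, PeriodRecord, SessionConfig
from .game import GameParams

__all__ = [
    "PERIOD_COLUMNS",
    "MARKER_COLUMNS",
    "write_period_records",
    "read_period_records",
    "write_markers",
    "read_markers",
    "write_trace",
    "read_trace",
    "write_ground_truth",
    "read_ground_truth",
    "write_scr_events",
    "read_scr_events",
    "load_session_config",
    "dump_session_config",
    "write_manifest",
    "read_manifest",
]

PERIOD_COLUMNS = [
    "triplet", "period", "treatment", "q1", "b1", "q2", "b2", "winner",
    "decision_class", "inspected", "bribe_revealed", "payoff_official",
    "payoff_firm1", "payoff_firm2", "rt_firm1", "rt_firm2", "rt_official",
    "rt_inspection", "t_start",
]

MARKER_COLUMNS = [
    "subject", "event_type", "time_s", "condition", "period", "triplet",
    "event_id",
]


def write_period_records(records: list[PeriodRecord], path) -> None:
    df = pd.DataFrame([vars(r) for r in records], columns=PERIOD_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_period_records(path) -> list[PeriodRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        PeriodRecord(**{k: row[k] for k in PERIOD_COLUMNS})
        for row in df.to_dict("records")
    ]


def write_markers(markers: list[EventMarker], path) -> None:
    df = pd.DataFrame([vars(m) for m in markers], columns=MARKER_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_markers(path) -> list[EventMarker]:
    df = pd.read_csv(path, sep="\t")
    return [
        EventMarker(**{k: row[k] for k in MARKER_COLUMNS})
        for row in df.to_dict("records")
    ]


def write_trace(trace: EDATrace, path) -> None:
    df = pd.DataFrame(
        {"time_s": trace.times, "conductance_uS": trace.values}
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_trace(path, subject: str | None = None) -> EDATrace:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t)))
    return EDATrace(
        subject=subject if subject is not None else path.stem,
        sampling_rate=round(fs, 6),
        values=df["conductance_uS"].to_numpy(),
        start_time=float(t[0]),
    )


def write_ground_truth(truth: list[SCRGroundTruth], path) -> None:
    pd.DataFrame([vars(g) for g in truth]).to_csv(path, sep="\t", index=False)


def read_ground_truth(path) -> list[SCRGroundTruth]:
    df = pd.read_csv(path, sep="\t")
    return [SCRGroundTruth(**row) for row in df.to_dict("records")]


def write_scr_events(scrs: list[SCREvent], path) -> None:
    pd.DataFrame([vars(s) for s in scrs]).to_csv(path, sep="\t", index=False)


def read_scr_events(path) -> list[SCREvent]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.to_dict("records"):
        if pd.isna(row.get("linked_event")):
            row["linked_event"] = None
        if pd.isna(row.get("condition")):
            row["condition"] = None
        out.append(SCREvent(**row))
    return out


def load_session_config(path) -> SessionConfig:
    """Flat YAML key-value mapping -> SessionConfig.

    Keys must match SessionConfig field names; ``params_*`` keys override
    the auction economy constants (e.g. ``params_F: 10``).
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError("config file must be a flat key-value mapping")
    fields = {f.name for f in dataclasses.fields(SessionConfig)}
    kwargs = {}
    game_kwargs = {}
    for key, val in raw.items():
        if key.startswith("params_"):
            game_kwargs[key[len("params_"):]] = val
        elif key in fields:
            if isinstance(val, list):
                val = tuple(val)
            kwargs[key] = val
        else:
            raise ValueError(f"unknown config key {key!r}")
    if game_kwargs:
        kwargs["params"] = GameParams(**game_kwargs)
    return SessionConfig(**kwargs)


def dump_session_config(config: SessionConfig, path) -> None:
    d = dataclasses.asdict(config)
    params = d.pop("params")
    for key, val in params.items():
        d[f"params_{key}"] = val
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=True)


def _config_snapshot(config) -> dict:
    d = dataclasses.asdict(config)
    for key, val in list(d.items()):
        if isinstance(val, tuple):
            d[key] = list(val)
    return d


def write_manifest(
    path,
    config,
    seed: int | None,
    inputs: list[str],
    outputs: list[str],
) -> None:
    manifest = {
        "package": "physioecon",
        "version": __version__,
        "seed": seed,
        "config": _config_snapshot(config) if config is not None else None,
        "inputs": sorted(map(str, inputs)),
        "outputs": sorted(map(str, outputs)),
        "created_unix": int(time.time()),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_manifest(path) -> dict:
    with open(path) as fh:
        return json.load(fh)
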