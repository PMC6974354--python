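"""Columnar text I/O for traces, events, speed, labels and ground truth.

All tables are plain CSV; configuration is YAML or JSON.  Times are seconds,
sample indices 0-based.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BehaviorLabels, Event, EventSeries, SpeedTrace, Trace
from .synthetic import SynthGroundTruth

log = logging.getLogger("cacoupling")

TRACE_COLUMNS = ["time_s", "value", "trace_id", "neuron_id", "compartment",
                 "kind", "fs"]
EVENT_COLUMNS = ["trace_id", "peak_time_s", "peak_index", "amplitude",
                 "norm_amplitude"]


def _require_columns(df: pd.DataFrame, required: list[str], path: Path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def write_traces(traces: list[Trace], path: str | Path) -> Path:
    path = Path(path)
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "time_s": tr.times, "value": tr.values, "trace_id": tr.trace_id,
            "neuron_id": tr.neuron_id, "compartment": tr.compartment,
            "kind": tr.kind.value, "fs": tr.fs,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_traces(path: str | Path) -> list[Trace]:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        log.warning("%s is empty; returning no traces", path)
        return []
    if df.empty:
        log.warning("%s has a header but no rows; returning no traces", path)
        return []
    _require_columns(df, TRACE_COLUMNS, path)
    traces = []
    for trace_id, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("time_s")
        traces.append(Trace(
            values=grp["value"].to_numpy(), fs=float(grp["fs"].iloc[0]),
            t0=float(grp["time_s"].iloc[0]), trace_id=str(trace_id),
            neuron_id=str(grp["neuron_id"].iloc[0]),
            compartment=str(grp["compartment"].iloc[0]),
            kind=str(grp["kind"].iloc[0])))
    return traces


def write_events(series_list: list[EventSeries], path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for s in series_list:
        for e in s.events:
            rows.append({"trace_id": s.trace_id, "peak_time_s": e.peak_time,
                         "peak_index": e.peak_index, "amplitude": e.amplitude,
                         "norm_amplitude": e.norm_amplitude})
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)
    return path


def read_events(path: str | Path) -> list[EventSeries]:
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        return []
    _require_columns(df, EVENT_COLUMNS, path)
    out = []
    for trace_id, grp in df.groupby("trace_id", sort=False):
        grp = grp.sort_values("peak_time_s")
        events = [Event(r.peak_time_s, int(r.peak_index), r.amplitude,
                        r.norm_amplitude) for r in grp.itertuples()]
        out.append(EventSeries(events=events, trace_id=str(trace_id)))
    return out


def write_speed(speed: SpeedTrace, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": speed.times, "speed_cm_s": speed.speed}).to_csv(
        path, index=False)
    return path


def read_speed(path: str | Path) -> SpeedTrace:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, ["time_s", "speed_cm_s"], path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / float(np.median(np.diff(t))) if t.size > 1 else 1.0
    return SpeedTrace(speed=df["speed_cm_s"].to_numpy(), fs=fs, t0=float(t[0]))


def write_labels(labels: BehaviorLabels, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"time_s": labels.times, "state": labels.state_names()}).to_csv(
        path, index=False)
    return path


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None if math.isnan(obj) else ("inf" if obj > 0 else "-inf")
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name))
                for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_ground_truth(truths: list[SynthGroundTruth], path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(truths), indent=1))
    return path


def load_config_file(path: str | Path) -> dict:
    """Load a YAML or JSON configuration mapping."""
    path = Path(path)
    text = path.read_text()
    data = (json.loads(text) if path.suffix == ".json"
            else yaml.safe_load(text))
    if not isinstance(data, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return data


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
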