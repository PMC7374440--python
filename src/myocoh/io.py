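"""Plain-text persistence of signal records: CSV samples + JSON sidecar.

A record ``name`` is stored as ``name.csv`` (a ``time`` column in seconds
plus one column per channel, header row naming channel roles) and
``name.json`` (sampling rate, channel roles, annotations and free-form
metadata). The pair round-trips losslessly up to float text precision.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .records import (
    SignalRecord,
    annotations_from_dicts,
    annotations_to_dicts,
)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj


def write_signal_record(record: SignalRecord, basepath: str | Path) -> tuple[Path, Path]:
    """Write ``basepath.csv`` and ``basepath.json``; returns both paths."""
    base = Path(basepath)
    base.parent.mkdir(parents=True, exist_ok=True)
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")

    header = ["time"] + [
        f"{role}_{i}" if record.channel_roles.count(role) > 1 else role
        for i, role in enumerate(record.channel_roles)
    ]
    frame = pd.DataFrame(
        np.column_stack([record.times, record.samples]), columns=header
    )
    frame.to_csv(csv_path, index=False, float_format="%.10g")

    sidecar = {
        "format": "myocoh.signal_record/1",
        "sampling_rate": record.sampling_rate,
        "channel_roles": list(record.channel_roles),
        "annotations": annotations_to_dicts(record.annotations),
        "meta": _jsonable(record.meta),
    }
    json_path.write_text(json.dumps(sidecar, indent=1))
    return csv_path, json_path


def read_signal_record(basepath: str | Path) -> SignalRecord:
    """Read a record written by :func:`write_signal_record`.

    ``basepath`` may be the bare base name or either of the two file paths.
    A missing sidecar or sample file raises a format error.
    """
    base = Path(basepath)
    if base.suffix in (".csv", ".json"):
        base = base.with_suffix("")
    csv_path = base.with_suffix(".csv")
    json_path = base.with_suffix(".json")
    if not json_path.exists():
        raise FileNotFoundError(f"missing JSON sidecar {json_path}")
    if not csv_path.exists():
        raise FileNotFoundError(f"missing sample file {csv_path}")

    sidecar = json.loads(json_path.read_text())
    if sidecar.get("format") != "myocoh.signal_record/1":
        raise ValueError(f"{json_path} is not a signal-record sidecar")
    frame = pd.read_csv(csv_path)
    samples = frame.iloc[:, 1:].to_numpy(dtype=float)
    return SignalRecord(
        samples=samples,
        sampling_rate=float(sidecar["sampling_rate"]),
        channel_roles=list(sidecar["channel_roles"]),
        annotations=annotations_from_dicts(sidecar["annotations"]),
        meta=sidecar.get("meta", {}),
    )
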