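"""Plain-text record IO: two-column CSV plus JSON sidecar.

A record is stored as ``<stem>.csv`` with columns ``time_s, amplitude``
and a sidecar ``<stem>.json`` holding sampling frequency, subject/source
labels, the optional BP reference series and, for synthetic records, the
ground-truth beat annotations.  Synthetic and real recordings share this
reader path.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import PPGSignal

__all__ = ["write_record", "read_record", "write_feature_table", "read_feature_table"]


def write_record(signal: PPGSignal, stem: str | Path) -> tuple[Path, Path]:
    """Write a PPG record as CSV + JSON sidecar; returns the two paths."""
    stem = Path(stem)
    csv_path = stem.with_suffix(".csv")
    json_path = stem.with_suffix(".json")
    frame = pd.DataFrame({"time_s": signal.time, "amplitude": signal.samples})
    frame.to_csv(csv_path, index=False, float_format="%.10g")
    sidecar = {
        "fs": signal.fs,
        "subject": signal.subject,
        "source": signal.source,
        "record": signal.record,
        "bp_reference": None
        if signal.bp_reference is None
        else np.asarray(signal.bp_reference).tolist(),
        "meta": _jsonable(signal.meta),
    }
    with open(json_path, "w") as fh:
        json.dump(sidecar, fh, indent=1, sort_keys=True)
    return csv_path, json_path


def read_record(stem: str | Path) -> PPGSignal:
    """Read a record written by :func:`write_record` (pass stem or CSV path)."""
    stem = Path(stem)
    csv_path = stem if stem.suffix == ".csv" else stem.with_suffix(".csv")
    json_path = csv_path.with_suffix(".json")
    if not csv_path.exists():
        raise FileNotFoundError(f"record CSV not found: {csv_path}")
    if not json_path.exists():
        raise FileNotFoundError(f"record sidecar not found: {json_path}")
    frame = pd.read_csv(csv_path)
    with open(json_path) as fh:
        sidecar = json.load(fh)
    bp_ref = sidecar.get("bp_reference")
    return PPGSignal(
        samples=frame["amplitude"].to_numpy(dtype=float),
        fs=float(sidecar["fs"]),
        subject=str(sidecar.get("subject", "unknown")),
        source=str(sidecar.get("source", "unknown")),
        record=str(sidecar.get("record", "rec0")),
        bp_reference=None if bp_ref is None else np.asarray(bp_ref, dtype=float),
        meta=sidecar.get("meta", {}),
    )


def write_feature_table(frame: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.12g")
    return path


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def _jsonable(obj):
    """Recursively convert numpy scalars/arrays for JSON serialization."""
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj
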