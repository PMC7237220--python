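"""File formats: tidy performance CSV, raw float signals with JSON sidecars."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

PERFORMANCE_COLUMNS = [
    "subject", "group", "trial", "position", "iki_ms", "kvel", "score",
]


def write_performance_csv(df: pd.DataFrame, path) -> None:
    missing = [c for c in PERFORMANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"performance table missing columns: {missing}")
    df[PERFORMANCE_COLUMNS].to_csv(path, index=False)


def read_performance_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in PERFORMANCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"performance table missing columns: {missing}")
    return df


def write_signal(signal, fs: float, path, markers=None, channels=None) -> None:
    """Raw float32 binary with a JSON sidecar (fs, shape, markers)."""
    path = Path(path)
    arr = np.asarray(signal, dtype=np.float32)
    arr.tofile(path)
    sidecar = {
        "fs": fs,
        "shape": list(arr.shape),
        "dtype": "float32",
        "channels": list(channels) if channels else ["ch0"],
        "markers": markers or {},
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=2)
    )


def read_signal(path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    arr = np.fromfile(path, dtype=np.float32).reshape(sidecar["shape"])
    return arr.astype(float), sidecar


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_jsonify))


def _jsonify(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if hasattr(o, "__dataclass_fields__"):
        return {k: getattr(o, k) for k in o.__dataclass_fields__}
    raise TypeError(f"not JSON serializable: {type(o)}")
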