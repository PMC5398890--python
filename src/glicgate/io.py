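"""Plain-text persistence: trace CSVs with JSON sidecars, manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import StoppedFlowTrace

__all__ = ["write_trace", "read_trace", "write_json", "read_json"]


def write_trace(trace: StoppedFlowTrace, path: str | Path) -> Path:
    """Write time_s,intensity CSV plus a .json metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trace.time, "intensity": trace.intensity}).to_csv(
        path, index=False, float_format="%.9g"
    )
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(trace.meta, indent=1, sort_keys=True, default=str))
    return path


def read_trace(path: str | Path) -> StoppedFlowTrace:
    path = Path(path)
    df = pd.read_csv(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return StoppedFlowTrace(
        time=df["time_s"].to_numpy(dtype=float),
        intensity=df["intensity"].to_numpy(dtype=float),
        meta=meta,
    )


def write_json(obj, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if hasattr(o, "__dict__"):
            return {k: v for k, v in o.__dict__.items() if not k.startswith("_")}
        return str(o)

    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=default))
    return path


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
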