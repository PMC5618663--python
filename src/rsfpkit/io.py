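"""File I/O: tidy trace CSVs, multi-page TIFF stacks, JSON sidecars.

All CSVs are UTF-8, comma-separated, with a header row and '.' decimal.
Trace tables use the tidy dialect shared by the simulator and the extractor:
columns ``object_id, frame, time_s, cycle, half_cycle, illumination,
intensity``.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .experiment import SwitchingExperiment, SwitchingProtocol

__all__ = [
    "write_traces_csv",
    "read_traces_csv",
    "write_stack_tiff",
    "read_stack_tiff",
    "write_json",
    "read_json",
]

TRACE_COLUMNS = ["object_id", "frame", "time_s", "cycle", "half_cycle", "illumination", "intensity"]


def write_traces_csv(experiment: SwitchingExperiment, path: str | Path) -> Path:
    """Write an experiment as a tidy CSV plus a JSON sidecar with protocol/metadata."""
    path = Path(path)
    experiment.to_tidy()[TRACE_COLUMNS].to_csv(path, index=False)
    sidecar = {"protocol": experiment.protocol.to_dict(), "metadata": experiment.metadata}
    write_json(sidecar, path.with_suffix(".json"))
    return path


def read_traces_csv(path: str | Path, protocol: SwitchingProtocol | None = None) -> SwitchingExperiment:
    """Read a tidy trace CSV; the protocol comes from the sidecar unless given."""
    path = Path(path)
    table = pd.read_csv(path)
    missing = set(TRACE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"trace CSV is missing columns: {sorted(missing)}")
    metadata: dict = {}
    if protocol is None:
        sidecar_path = path.with_suffix(".json")
        if sidecar_path.exists():
            sidecar = read_json(sidecar_path)
            protocol = SwitchingProtocol.from_dict(sidecar["protocol"])
            metadata = sidecar.get("metadata", {})
        else:
            protocol = _infer_protocol(table)
    return SwitchingExperiment.from_tidy(table, protocol, metadata=metadata)


def _infer_protocol(table: pd.DataFrame) -> SwitchingProtocol:
    """Reconstruct the schedule from the tidy table itself (single-object view)."""
    one = table[table["object_id"] == table["object_id"].iloc[0]].sort_values("frame")
    n_cycles = int(one["cycle"].max())
    first = one[one["cycle"] == 1]
    on_periods = int((first["half_cycle"] == "on").sum())
    off_periods = int((first["half_cycle"] == "off").sum())
    if n_cycles == 1:
        trailing = 0
    else:
        last = one[one["cycle"] == n_cycles]
        trailing = int((last["half_cycle"] == "on").sum()) - on_periods
    times = one["time_s"].to_numpy()
    period = float(np.median(np.diff(times))) if len(times) > 1 else 1.0
    return SwitchingProtocol(
        n_cycles=n_cycles,
        on_periods=on_periods,
        off_periods=off_periods,
        period_duration=period,
        trailing_on_periods=max(trailing, 0),
    )


def write_stack_tiff(stack: np.ndarray, path: str | Path, dtype: str = "uint16") -> Path:
    """Write an image stack as multi-page grayscale TIFF.

    Float stacks are scaled to the full range of the target integer dtype;
    the scale factor is stored in the TIFF description for round-tripping.
    """
    path = Path(path)
    stack = np.asarray(stack)
    if dtype == "float32":
        tifffile.imwrite(path, stack.astype(np.float32), photometric="minisblack")
        return path
    info = np.iinfo(np.dtype(dtype))
    peak = float(stack.max())
    scale = info.max / peak if peak > 0 else 1.0
    scaled = np.clip(stack * scale, info.min, info.max).astype(dtype)
    tifffile.imwrite(
        path,
        scaled,
        photometric="minisblack",
        description=json.dumps({"intensity_scale": scale}),
    )
    return path


def read_stack_tiff(path: str | Path, rescale: bool = True) -> np.ndarray:
    """Read a multi-page TIFF; undo the write-time intensity scaling if recorded."""
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        stack = tif.asarray().astype(float)
        desc = tif.pages[0].description
    if rescale and desc:
        try:
            scale = json.loads(desc).get("intensity_scale")
            if scale:
                stack = stack / scale
        except (json.JSONDecodeError, AttributeError):
            pass
    if stack.ndim == 2:
        stack = stack[None]
    return stack


def write_json(obj: dict, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")
    return path


def read_json(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
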