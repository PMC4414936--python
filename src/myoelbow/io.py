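"""Delimited-text signal files and JSON manifests.

Signal files are CSV with a header row and columns ``time_s, emg`` plus an
optional ``angle_deg`` ground-truth column, one sample per row.  The
sampling rate is inferred from the time column and validated for
uniformity.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Tuple, Union

import numpy as np
import pandas as pd

from .emg_processing import EMGTrace
from .exceptions import SignalFileError

__all__ = [
    "read_signal_csv",
    "write_signal_csv",
    "write_prediction_csv",
    "read_manifest",
    "write_manifest",
]

#: maximum allowed deviation of sample spacing from uniform (seconds)
TIME_UNIFORMITY_TOL = 1e-6

PathLike = Union[str, Path]


def read_signal_csv(path: PathLike) -> Tuple[EMGTrace, Optional[np.ndarray]]:
    """Read a raw-EMG CSV; returns the trace and the angle column if present."""
    path = Path(path)
    try:
        frame = pd.read_csv(path)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, ValueError) as exc:
        raise SignalFileError(f"{path}: {exc}") from exc
    for col in ("time_s", "emg"):
        if col not in frame.columns:
            raise SignalFileError(f"{path}: missing required column {col!r}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    bad = numeric[["time_s", "emg"]].isna().any(axis=1)
    if bad.any():
        # +2: header row plus 1-based numbering
        line = int(bad.idxmax()) + 2
        raise SignalFileError(f"{path}: non-numeric or missing value at line {line}")
    time = numeric["time_s"].to_numpy()
    if time.size < 2:
        raise SignalFileError(f"{path}: need at least two samples")
    dt = np.diff(time)
    if np.any(np.abs(dt - dt[0]) > TIME_UNIFORMITY_TOL) or dt[0] <= 0:
        raise SignalFileError(f"{path}: time column is not uniformly increasing")
    trace = EMGTrace(numeric["emg"].to_numpy(), 1.0 / dt[0], "raw")
    angles = None
    if "angle_deg" in frame.columns:
        angles = numeric["angle_deg"].to_numpy()
    return trace, angles


def write_signal_csv(
    path: PathLike,
    trace: EMGTrace,
    angles_deg: Optional[np.ndarray] = None,
) -> None:
    """Write a trace (and optional ground-truth angles) as a signal CSV."""
    data = {"time_s": trace.time(), "emg": trace.samples}
    if angles_deg is not None:
        data["angle_deg"] = np.asarray(angles_deg, dtype=float)
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_prediction_csv(
    path: PathLike,
    time_s: np.ndarray,
    angle_deg: np.ndarray,
    states: Optional[np.ndarray] = None,
) -> None:
    """Write a predicted angle series (plus the automaton state per sample)."""
    data = {"time_s": time_s, "angle_deg": angle_deg}
    if states is not None:
        data["state"] = states
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def write_manifest(path: PathLike, manifest: dict) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")


def read_manifest(path: PathLike) -> dict:
    return json.loads(Path(path).read_text())
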