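"""Trajectory serialization: CSV and JSON, loss-free round trips.

Floats are written with 17 significant digits so a write-then-read cycle
reproduces the trajectory bit-exactly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulation import DosingTrajectory

__all__ = ["write_trajectory", "read_trajectory"]

_FLOAT_FMT = "%.17g"


def write_trajectory(
    trajectory: DosingTrajectory, path: str | Path, format: str = "csv"
) -> None:
    """Write a trajectory to ``path`` as CSV (one row per k) or JSON."""
    path = Path(path)
    frame = trajectory.to_frame()
    if format == "csv":
        frame.to_csv(path, index=False, float_format=_FLOAT_FMT)
    elif format == "json":
        payload = {
            col: [None if pd.isna(v) else float(v) for v in frame[col]]
            for col in frame.columns
        }
        path.write_text(json.dumps(payload, indent=1))
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")


def read_trajectory(path: str | Path) -> DosingTrajectory:
    """Read a trajectory written by :func:`write_trajectory`."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = json.loads(path.read_text())
        frame = pd.DataFrame(
            {k: [np.nan if v is None else v for v in vals] for k, vals in payload.items()}
        )
    else:
        frame = pd.read_csv(path, float_precision="round_trip")
    states = frame[["x1", "x2", "x3"]].to_numpy(float)
    return DosingTrajectory(
        times=frame["t_h"].to_numpy(float),
        doses=frame["dose_mg"].to_numpy(float),
        states=states,
        outputs=frame["y"].to_numpy(float),
        fs=frame["fs"].to_numpy(float) if "fs" in frame else None,
        v=frame["v"].to_numpy(float) if "v" in frame else None,
    )
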