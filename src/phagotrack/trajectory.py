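"""Trajectory containers and their delimited-text representation.

The on-disk schema is fixed: tab-separated columns ``frame, time_s,
x_nm, y_nm`` with an optional ``state`` column carrying per-frame motion
labels.  Coordinates are always nanometres; frames are 0-based.  Header
comment lines beginning with ``#`` carry provenance (seed, config hash).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "DIRECTED",
    "DIFFUSIVE",
    "Trajectory",
    "LabeledTrajectory",
    "read_trajectory",
    "write_trajectory",
]

DIRECTED = "directed"
DIFFUSIVE = "diffusive"


@dataclass
class Trajectory:
    """A time-ordered 2-D position track of one tracked bead.

    ``source`` records how the track was obtained: ``tracked`` (from an
    image stack), ``simulated``, or ``file``.
    """

    frames: np.ndarray   # int, 0-based
    times: np.ndarray    # s
    x: np.ndarray        # nm
    y: np.ndarray        # nm
    source: str = "file"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.int64)
        self.times = np.asarray(self.times, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        n = len(self.frames)
        if not (len(self.times) == len(self.x) == len(self.y) == n):
            raise ValueError("frames, times, x, y must have equal length")
        if n == 0:
            raise ValueError("empty trajectory")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(np.diff(self.frames) != 1):
            raise ValueError("frames must be consecutive with no gaps")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    def positions(self) -> np.ndarray:
        """(n, 2) array of observed positions in nm."""
        return np.column_stack([self.x, self.y])


@dataclass
class LabeledTrajectory(Trajectory):
    """Simulated trajectory with noise-free positions and ground truth.

    ``state`` holds the generating per-frame motion label; ``truth``
    records the continuous-time sojourn durations and per-run speeds the
    simulator drew, which downstream recovery tests compare against.
    """

    x_true: np.ndarray = None
    y_true: np.ndarray = None
    state: np.ndarray = None  # per-frame labels in {directed, diffusive}
    truth: dict = field(default_factory=dict)
    source: str = "simulated"

    def __post_init__(self) -> None:
        super().__post_init__()
        self.x_true = np.asarray(self.x_true, dtype=float)
        self.y_true = np.asarray(self.y_true, dtype=float)
        self.state = np.asarray(self.state, dtype=object)
        n = len(self.frames)
        if not (len(self.x_true) == len(self.y_true) == len(self.state) == n):
            raise ValueError("ground-truth arrays must match trajectory length")
        bad = set(self.state) - {DIRECTED, DIFFUSIVE}
        if bad:
            raise ValueError(f"unknown state labels: {sorted(bad)}")


def write_trajectory(traj: Trajectory, path, extra_meta: Optional[dict] = None) -> None:
    path = Path(path)
    meta = dict(traj.meta)
    if extra_meta:
        meta.update(extra_meta)
    cols = {
        "frame": traj.frames,
        "time_s": traj.times,
        "x_nm": traj.x,
        "y_nm": traj.y,
    }
    if isinstance(traj, LabeledTrajectory):
        cols["state"] = traj.state
    df = pd.DataFrame(cols)
    with path.open("w") as fh:
        for k in sorted(meta):
            fh.write(f"# {k}={meta[k]}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6f")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory table; returns a LabeledTrajectory when a
    ``state`` column is present (ground-truth positions then default to
    the observed ones)."""
    path = Path(path)
    meta = {}
    with path.open() as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"frame", "time_s", "x_nm", "y_nm"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    kwargs = dict(
        frames=df["frame"].to_numpy(),
        times=df["time_s"].to_numpy(),
        x=df["x_nm"].to_numpy(),
        y=df["y_nm"].to_numpy(),
        meta=meta,
    )
    if "state" in df.columns:
        return LabeledTrajectory(
            x_true=df["x_nm"].to_numpy(),
            y_true=df["y_nm"].to_numpy(),
            state=df["state"].to_numpy(),
            **kwargs,
        )
    return Trajectory(source="file", **kwargs)
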