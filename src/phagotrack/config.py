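"""Parameter containers for simulation, tracking and analysis.

All physical quantities are in nanometres and seconds.  Each dataclass
validates its fields on construction and raises :class:`ConfigError`
naming the offending field, so that mis-specified configuration files
fail loudly before any computation starts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

__all__ = [
    "ConfigError",
    "SimulationConfig",
    "TrackingConfig",
    "RunCriteria",
    "AnalysisConfig",
    "load_config",
    "save_config",
]


class ConfigError(ValueError):
    """A configuration field failed validation."""


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ConfigError(f"{name}: {msg}")


def _finite(value: float, name: str) -> None:
    if not math.isfinite(value):
        raise ConfigError(f"{name}: must be finite, got {value!r}")


@dataclass(frozen=True)
class SimulationConfig:
    """Conditions for the two-state motor-switching trajectory simulator.

    The motion model alternates between a motor-bound *directed* state,
    in which the cargo advances at a constant per-run speed along a fixed
    axis, and a *diffusive* state with Brownian increments.  Switching is
    a continuous-time two-state Markov process: ``k_off`` is the rate of
    leaving the directed state (the dissociation rate of the cargo from
    the motor-bound state) and ``k_on`` the rate of leaving the diffusive
    state.  Per-run speeds are drawn from a normal distribution truncated
    to the observed 50-1500 nm/s range of bead-phagosome transport.

    Defaults emulate bead-phagosome recordings: 20 frames/s, 150 s
    duration, 27.6 nm/pixel and 9.8 nm localization noise.
    """

    frame_rate: float = 20.0          # frames per second
    duration: float = 150.0           # s
    pixel_size: float = 27.6          # nm per pixel (image rendering only)
    sigma_loc: float = 9.8            # nm, localization noise SD per coordinate
    D_diff: float = 1.0e4             # nm^2/s, diffusive-state diffusion constant
    v_mean: float = 500.0             # nm/s, per-run speed distribution mean
    v_sd: float = 200.0               # nm/s, per-run speed distribution SD
    speed_min: float = 50.0           # nm/s, truncation support
    speed_max: float = 1500.0         # nm/s
    k_off: float = 0.4               # 1/s, rate of leaving the directed state
    k_on: float = 0.4                # 1/s, rate of leaving the diffusive state
    p_reverse: float = 0.5            # probability a new run reverses direction
    forced_state: Optional[str] = None  # None | "directed" | "diffusive"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("frame_rate", "duration", "pixel_size", "sigma_loc",
                     "D_diff", "v_mean", "v_sd", "speed_min", "speed_max",
                     "k_off", "k_on", "p_reverse"):
            _finite(float(getattr(self, name)), name)
        _require(self.frame_rate > 0, "frame_rate", "must be > 0")
        _require(self.duration > 0, "duration", "must be > 0")
        _require(self.pixel_size > 0, "pixel_size", "must be > 0")
        _require(self.sigma_loc >= 0, "sigma_loc", "must be >= 0")
        _require(self.D_diff >= 0, "D_diff", "must be >= 0")
        _require(self.k_off > 0, "k_off", "must be > 0")
        _require(self.k_on > 0, "k_on", "must be > 0")
        _require(0.0 <= self.p_reverse <= 1.0, "p_reverse", "must be in [0, 1]")
        _require(self.v_sd >= 0, "v_sd", "must be >= 0")
        _require(
            50.0 <= self.speed_min <= self.speed_max <= 1500.0,
            "speed_min/speed_max",
            "speed support must lie within [50, 1500] nm/s",
        )
        _require(
            self.forced_state in (None, "directed", "diffusive"),
            "forced_state",
            "must be None, 'directed' or 'diffusive'",
        )
        _require(
            isinstance(self.seed, int) and 0 <= self.seed < 2**63,
            "seed",
            "must be a non-negative integer",
        )

    @property
    def dt(self) -> float:
        """Frame interval in seconds."""
        return 1.0 / self.frame_rate

    @property
    def n_frames(self) -> int:
        return int(round(self.duration * self.frame_rate))


@dataclass(frozen=True)
class TrackingConfig:
    """Settings for centroid localization and frame-to-frame linking."""

    roi_halfwidth: int = 12           # pixels, covers the default rendered spot
    background_method: str = "roi_min"  # "roi_min" | "percentile"
    percentile: float = 0.1           # fraction, used by "percentile"
    max_step: float = 500.0           # nm, linking gate between frames

    def __post_init__(self) -> None:
        _require(self.roi_halfwidth >= 2, "roi_halfwidth", "must be >= 2")
        _require(
            self.background_method in ("roi_min", "percentile"),
            "background_method",
            "must be 'roi_min' or 'percentile'",
        )
        if self.background_method == "percentile":
            _require(0.0 < self.percentile < 0.5, "percentile",
                     "must be in (0, 0.5)")
        _require(self.max_step > 0, "max_step", "must be > 0")


@dataclass(frozen=True)
class RunCriteria:
    """Thresholds a constant-velocity piece must meet to count as a run.

    A piece is a *run* when its net displacement exceeds ``min_run_length``,
    its speed exceeds ``min_speed`` and it lasts at least ``min_duration``;
    a piece slower than ``min_speed`` is a *pause*; anything else (fast but
    short) is *subthreshold*.
    """

    min_run_length: float = 200.0     # nm
    min_speed: float = 50.0           # nm/s
    min_duration: float = 0.25        # s

    def __post_init__(self) -> None:
        _require(self.min_run_length > 0, "min_run_length", "must be > 0")
        _require(self.min_speed > 0, "min_speed", "must be > 0")
        _require(self.min_duration > 0, "min_duration", "must be > 0")


@dataclass(frozen=True)
class AnalysisConfig:
    """End-to-end analysis settings.

    At the default 20 frames/s the 40-frame window spans 2.0 s; fitted
    lags are restricted to one quarter of the window (frames 1..10).
    ``sigma_loc_nm`` is held fixed in every window fit, entering the MSD
    model as the additive ``2*sigma^2`` offset.
    """

    window_frames: int = 40
    stride_frames: int = 1
    sigma_loc_nm: float = 9.8
    max_lag_frames: int = 10
    alpha_min: float = 0.0
    alpha_max: float = 2.2
    min_segment_frames: int = 5       # shorter motion segments are absorbed
    max_gap_frames: int = 5           # diffusive gap tolerated when stitching
    changepoint_penalty_factor: float = 12.0  # multiplies sigma^2 * log(n)
    run_criteria: RunCriteria = field(default_factory=RunCriteria)
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.window_frames >= 8, "window_frames", "must be >= 8")
        _require(self.stride_frames >= 1, "stride_frames", "must be >= 1")
        _require(self.sigma_loc_nm >= 0, "sigma_loc_nm", "must be >= 0")
        _require(4 <= self.max_lag_frames <= self.window_frames // 2,
                 "max_lag_frames",
                 "need >= 4 lags and at most half the window")
        _require(0 <= self.alpha_min < self.alpha_max, "alpha_min/alpha_max",
                 "need 0 <= alpha_min < alpha_max")
        _require(self.min_segment_frames >= 1, "min_segment_frames",
                 "must be >= 1")
        _require(self.max_gap_frames >= 0, "max_gap_frames", "must be >= 0")
        _require(self.changepoint_penalty_factor > 0,
                 "changepoint_penalty_factor", "must be > 0")
        _require(isinstance(self.seed, int) and 0 <= self.seed < 2**63,
                 "seed", "must be a non-negative integer")


_CONFIG_TYPES = {
    "simulation": SimulationConfig,
    "tracking": TrackingConfig,
    "run_criteria": RunCriteria,
    "analysis": AnalysisConfig,
}


def config_to_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    for k, cls in _CONFIG_TYPES.items():
        if isinstance(cfg, cls):
            d["kind"] = k
    return d


def config_hash(cfg) -> str:
    """Stable short hash of a config, recorded in output provenance."""
    payload = json.dumps(config_to_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def save_config(cfg, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path, expected_kind: Optional[str] = None):
    """Load a config written by :func:`save_config`.

    Raises :class:`ConfigError` with the offending field name on invalid
    values; unknown keys are rejected rather than silently dropped.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a key-value mapping")
    kind = raw.pop("kind", expected_kind)
    if kind not in _CONFIG_TYPES:
        raise ConfigError(f"{path}: unknown or missing config kind {kind!r}")
    if expected_kind is not None and kind != expected_kind:
        raise ConfigError(f"{path}: expected a {expected_kind} config, got {kind}")
    cls = _CONFIG_TYPES[kind]
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(raw) - names
    if unknown:
        raise ConfigError(f"{path}: unknown fields {sorted(unknown)}")
    if cls is AnalysisConfig and isinstance(raw.get("run_criteria"), dict):
        raw["run_criteria"] = RunCriteria(**raw["run_criteria"])
    return cls(**raw)
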