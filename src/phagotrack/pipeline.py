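"""End-to-end orchestration: trajectories in, transport report out.

The pipeline pools per-window scaling exponents across all beads of an
analysis (one mixture and one cutoff per condition), labels motion
segments per bead, stitches and parses directed tracks into
constant-velocity pieces, applies the run criteria, and assembles
per-group transport summaries with group comparisons when two groups
are given.  Every report records the configuration hash, seed and
package version, and identical inputs + config give identical reports.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np

from . import __version__
from .config import AnalysisConfig, config_hash
from .msd import (
    MotionSegment,
    TwoGaussianModel,
    fit_alpha_distribution,
    fit_windows,
    label_segments,
    per_frame_alpha,
)
from .runs import RunSegment, classify_runs, parse_constant_velocity, stitch_directed
from .summary import TransportSummary, compare_groups, summarize_group
from .trajectory import Trajectory, read_trajectory

__all__ = ["BeadAnalysis", "PipelineReport", "analyze_cohort", "run_pipeline"]


@dataclass
class BeadAnalysis:
    """Per-bead intermediate results of the pipeline."""

    trajectory: Trajectory
    alphas: np.ndarray                  # per-frame scaling exponent
    segments: List[MotionSegment]
    runs: List[RunSegment]


@dataclass
class PipelineReport:
    """Full result bundle of one pipeline execution."""

    groups: Dict[str, List[BeadAnalysis]]
    mixture: TwoGaussianModel
    summaries: Dict[str, TransportSummary]
    comparisons: Optional[dict]
    provenance: dict

    def to_dict(self) -> dict:
        def msdict(m):
            return {"mean": m.mean, "sem": m.sem, "n": m.n}

        out = {
            "provenance": self.provenance,
            "mixture": {
                "weights": self.mixture.weights.tolist(),
                "means": self.mixture.means.tolist(),
                "sds": self.mixture.sds.tolist(),
                "cutoff": self.mixture.cutoff,
            },
            "summaries": {},
        }
        for g, s in self.summaries.items():
            out["summaries"][g] = {
                "n_beads": s.n_beads,
                "n_runs": s.n_runs,
                "pct_directed": msdict(s.pct_directed),
                "pct_diffusive": msdict(s.pct_diffusive),
                "run_length_nm": msdict(s.run_length),
                "velocity_nm_s": msdict(s.velocity),
                "dissociation_rate_per_s": msdict(s.dissociation_rate),
                "flags": s.flags,
            }
        if self.comparisons is not None:
            out["comparisons"] = {
                name: dataclasses.asdict(c) for name, c in self.comparisons.items()
            }
        return out

    def to_json(self, path=None, indent: int = 2) -> str:
        text = json.dumps(self.to_dict(), indent=indent, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def analyze_cohort(
    groups: Dict[str, Sequence[Trajectory]],
    config: Optional[AnalysisConfig] = None,
    cutoff: Optional[float] = None,
) -> PipelineReport:
    """Analyze one or two groups of trajectories end to end.

    Window fits are pooled across every bead of every group to fit one
    two-Gaussian mixture and derive one cutoff (pass ``cutoff`` to skip
    the mixture and impose a threshold).  Beads too short for a single
    window are skipped with a recorded warning, never silently.
    """
    if config is None:
        config = AnalysisConfig()
    if not groups or all(len(v) == 0 for v in groups.values()):
        raise ValueError("no inputs: every group is empty")

    fits_per_bead: Dict[str, list] = {g: [] for g in groups}
    kept: Dict[str, list] = {g: [] for g in groups}
    skipped: List[str] = []
    for g, trajs in groups.items():
        for i, traj in enumerate(trajs):
            if len(traj) < config.window_frames:
                skipped.append(f"{g}[{i}]: {len(traj)} frames < one window")
                continue
            fits_per_bead[g].append(fit_windows(traj, config))
            kept[g].append(traj)

    pooled = np.concatenate(
        [
            [f.alpha for f in fits if f.fit_ok]
            for g in groups
            for fits in fits_per_bead[g]
        ]
        or [[]]
    )
    if cutoff is None:
        mixture = fit_alpha_distribution(pooled, seed=config.seed)
        cut = mixture.cutoff
    else:
        cut = float(cutoff)
        mixture = TwoGaussianModel(
            weights=np.array([np.nan, np.nan]),
            means=np.array([np.nan, np.nan]),
            sds=np.array([np.nan, np.nan]),
            cutoff=cut,
        )

    analyses: Dict[str, List[BeadAnalysis]] = {}
    summaries: Dict[str, TransportSummary] = {}
    for g in groups:
        beads = []
        for traj, fits in zip(kept[g], fits_per_bead[g]):
            segments = label_segments(
                traj, fits, cut, min_segment_frames=config.min_segment_frames
            )
            tracks = stitch_directed(segments, traj, config.max_gap_frames)
            runs: List[RunSegment] = []
            for tr in tracks:
                runs.extend(parse_constant_velocity(tr, config))
            classify_runs(runs, config.run_criteria)
            beads.append(
                BeadAnalysis(
                    trajectory=traj,
                    alphas=per_frame_alpha(fits, len(traj)),
                    segments=segments,
                    runs=runs,
                )
            )
        analyses[g] = beads
        summaries[g] = summarize_group(
            g,
            [b.segments for b in beads],
            [b.runs for b in beads],
            criteria=config.run_criteria,
        )

    comparisons = None
    names = list(groups)
    if len(names) == 2:
        comparisons = compare_groups(summaries[names[0]], summaries[names[1]])

    provenance = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config_hash(config),
        "cutoff": cut,
        "n_alpha_pooled": int(len(pooled)),
        "skipped": skipped,
    }
    return PipelineReport(
        groups=analyses,
        mixture=mixture,
        summaries=summaries,
        comparisons=comparisons,
        provenance=provenance,
    )


def run_pipeline(
    inputs: Dict[str, Sequence],
    config: Optional[AnalysisConfig] = None,
    cutoff: Optional[float] = None,
) -> PipelineReport:
    """Run the pipeline on trajectory file paths grouped by condition."""
    groups = {
        g: [read_trajectory(p) if not isinstance(p, Trajectory) else p for p in paths]
        for g, paths in inputs.items()
    }
    return analyze_cohort(groups, config=config, cutoff=cutoff)
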