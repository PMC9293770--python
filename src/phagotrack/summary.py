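"""Per-group transport statistics and group comparisons.

The headline quantities of cargo-transport phenotyping: percent time in
directed versus diffusive motion (per bead, time-weighted), run length
and velocity (across runs surviving the run criteria), and the
dissociation rate — run terminations per unit motor-bound time, the
maximum-likelihood rate when run durations are exponential.  Each is
reported mean ± SEM with the unit of aggregation matching common
practice: beads for percentages and dissociation rate, runs for run
length and velocity.  Groups are compared with Welch two-sample t-tests
annotated with the usual significance stars.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .config import RunCriteria
from .msd import MotionSegment
from .runs import RUN, RunSegment
from .trajectory import DIRECTED

__all__ = [
    "MeanSEM",
    "TransportSummary",
    "GroupComparison",
    "percent_motion",
    "run_length_stats",
    "velocity_stats",
    "dissociation_rate",
    "summarize_group",
    "compare_groups",
    "significance_stars",
]


@dataclass
class MeanSEM:
    """Mean ± standard error with sample size; SEM is NaN at n < 2."""

    mean: float
    sem: float
    n: int

    @classmethod
    def from_values(cls, values: Sequence[float]) -> "MeanSEM":
        v = np.asarray(values, dtype=float)
        v = v[np.isfinite(v)]
        if len(v) == 0:
            return cls(float("nan"), float("nan"), 0)
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else float("nan")
        return cls(float(np.mean(v)), sem, len(v))


@dataclass
class TransportSummary:
    """Transport statistics of one group of beads."""

    group: str
    pct_directed: MeanSEM
    pct_diffusive: MeanSEM
    run_length: MeanSEM        # nm, across runs
    velocity: MeanSEM          # nm/s, across runs
    dissociation_rate: MeanSEM  # 1/s, across beads
    n_beads: int
    n_runs: int
    per_bead: dict = field(default_factory=dict)  # raw per-unit values
    flags: List[str] = field(default_factory=list)


@dataclass
class GroupComparison:
    """Welch two-sample t-test between two groups for one statistic."""

    statistic: str
    mean_a: float
    mean_b: float
    t: float
    p: float
    stars: str
    n_a: int
    n_b: int
    skipped: bool = False


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return "ns"
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def percent_motion(
    segments_per_bead: Sequence[Sequence[MotionSegment]],
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-bead percent of classified frames in each motion state.

    Returns ``(pct_directed, pct_diffusive)`` arrays, one entry per bead
    with any classified frames; beads with none are excluded with a
    warning.  The two percentages sum to 100 per bead exactly.
    """
    pct_dir = []
    for i, segs in enumerate(segments_per_bead):
        total = sum(s.n_frames for s in segs)
        if total == 0:
            warnings.warn(f"bead {i} has no classified frames; excluded",
                          stacklevel=2)
            continue
        ndir = sum(s.n_frames for s in segs if s.state == DIRECTED)
        pct_dir.append(100.0 * ndir / total)
    pct_dir = np.asarray(pct_dir)
    return pct_dir, 100.0 - pct_dir


def _runs_only(runs: Sequence[RunSegment]) -> List[RunSegment]:
    return [r for r in runs if r.kind == RUN]


def run_length_stats(runs: Sequence[RunSegment]) -> MeanSEM:
    """Mean ± SEM of net run displacement (nm) over run-kind segments."""
    lengths = [r.net_displacement for r in _runs_only(runs)]
    if not lengths:
        warnings.warn("no run segments; run-length stats undefined", stacklevel=2)
    return MeanSEM.from_values(lengths)


def velocity_stats(runs: Sequence[RunSegment]) -> MeanSEM:
    """Mean ± SEM of run speed (nm/s) over run-kind segments."""
    speeds = [r.speed for r in _runs_only(runs)]
    if not speeds:
        warnings.warn("no run segments; velocity stats undefined", stacklevel=2)
    return MeanSEM.from_values(speeds)


def _observability_threshold(run: RunSegment, criteria: RunCriteria) -> float:
    """Shortest duration at which this run would still meet the criteria."""
    if run.speed <= 0:
        return criteria.min_duration
    return max(criteria.min_duration, criteria.min_run_length / run.speed)


def dissociation_rate(
    runs_per_bead: Sequence[Sequence[RunSegment]],
    criteria: Optional[RunCriteria] = None,
    min_terminations: int = 10,
    truncation_adjusted: bool = True,
) -> Tuple[MeanSEM, dict]:
    """Run terminations per unit motor-bound time, per bead, then mean ± SEM.

    A run terminates when it ends in a pause, a diffusive interval, or
    another parsed piece — anything but the end of the recording.  Runs
    censored by the recording end are excluded from the numerator but
    their time stays in the denominator.

    With ``truncation_adjusted`` (default) the denominator subtracts each
    run's observability threshold ``max(min_duration, min_run_length /
    speed)``: the run criteria left-truncate the duration distribution,
    and for memoryless (exponential) run durations the maximum-likelihood
    rate uses only the time survived *beyond* the threshold.  The raw
    terminations-per-total-time ratio (biased low under truncation) is
    available with ``truncation_adjusted=False``.

    Returns the group statistic and a diagnostics dict; fewer than
    ``min_terminations`` total terminations in the group raises a flag
    rather than an error.
    """
    if criteria is None:
        criteria = RunCriteria()
    rates = []
    total_terms = 0
    for runs in runs_per_bead:
        rr = _runs_only(runs)
        if truncation_adjusted:
            time_in_runs = sum(
                max(r.duration - _observability_threshold(r, criteria), 0.0)
                for r in rr
            )
        else:
            time_in_runs = sum(r.duration for r in rr)
        terms = sum(1 for r in rr if not r.censored)
        total_terms += terms
        if time_in_runs > 0:
            rates.append(terms / time_in_runs)
    diag = {
        "total_terminations": total_terms,
        "insufficient": total_terms < min_terminations,
    }
    return MeanSEM.from_values(rates), diag


def summarize_group(
    group: str,
    segments_per_bead: Sequence[Sequence[MotionSegment]],
    runs_per_bead: Sequence[Sequence[RunSegment]],
    criteria: Optional[RunCriteria] = None,
) -> TransportSummary:
    """Assemble the full transport summary of one group."""
    pct_dir, pct_diff = percent_motion(segments_per_bead)
    all_runs = [r for runs in runs_per_bead for r in runs]
    run_kind = _runs_only(all_runs)
    rate, diag = dissociation_rate(runs_per_bead, criteria=criteria)
    flags = []
    if diag["insufficient"]:
        flags.append(
            f"only {diag['total_terminations']} run terminations; "
            "dissociation rate unreliable"
        )
    if not run_kind:
        flags.append("no segments met the run criteria")
    return TransportSummary(
        group=group,
        pct_directed=MeanSEM.from_values(pct_dir),
        pct_diffusive=MeanSEM.from_values(pct_diff),
        run_length=run_length_stats(all_runs) if run_kind else MeanSEM(np.nan, np.nan, 0),
        velocity=velocity_stats(all_runs) if run_kind else MeanSEM(np.nan, np.nan, 0),
        dissociation_rate=rate,
        n_beads=len(segments_per_bead),
        n_runs=len(run_kind),
        per_bead={
            "pct_directed": pct_dir.tolist(),
            "pct_diffusive": pct_diff.tolist(),
            "run_lengths": [r.net_displacement for r in run_kind],
            "velocities": [r.speed for r in run_kind],
            "dissociation_rates": _per_bead_rates(runs_per_bead, criteria),
        },
        flags=flags,
    )


def _per_bead_rates(runs_per_bead, criteria: Optional[RunCriteria] = None) -> List[float]:
    if criteria is None:
        criteria = RunCriteria()
    out = []
    for runs in runs_per_bead:
        rr = _runs_only(runs)
        t = sum(
            max(r.duration - _observability_threshold(r, criteria), 0.0) for r in rr
        )
        if t > 0:
            out.append(sum(1 for r in rr if not r.censored) / t)
    return out


def _welch(a: np.ndarray, b: np.ndarray, name: str) -> GroupComparison:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a, b = a[np.isfinite(a)], b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        return GroupComparison(name, float(np.mean(a)) if len(a) else np.nan,
                               float(np.mean(b)) if len(b) else np.nan,
                               np.nan, np.nan, "ns", len(a), len(b), skipped=True)
    if np.var(a) == 0 and np.var(b) == 0:
        # degenerate but well-defined: identical constants are not different
        equal = np.isclose(a.mean(), b.mean())
        t, p = (0.0, 1.0) if equal else (np.inf, 0.0)
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    return GroupComparison(
        statistic=name,
        mean_a=float(np.mean(a)),
        mean_b=float(np.mean(b)),
        t=float(t),
        p=float(p),
        stars=significance_stars(float(p)),
        n_a=len(a),
        n_b=len(b),
    )


def compare_groups(
    summary_a: TransportSummary, summary_b: TransportSummary
) -> Dict[str, GroupComparison]:
    """Welch t-tests between two groups on all transport statistics.

    Percentages and dissociation rates are compared across beads; run
    lengths and velocities across runs, matching each statistic's unit
    of aggregation.
    """
    pairs = {
        "pct_directed": ("pct_directed", "pct_directed"),
        "pct_diffusive": ("pct_diffusive", "pct_diffusive"),
        "run_length": ("run_lengths", "run_lengths"),
        "velocity": ("velocities", "velocities"),
        "dissociation_rate": ("dissociation_rates", "dissociation_rates"),
    }
    out = {}
    for name, (ka, kb) in pairs.items():
        out[name] = _welch(
            np.asarray(summary_a.per_bead[ka]),
            np.asarray(summary_b.per_bead[kb]),
            name,
        )
    return out
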