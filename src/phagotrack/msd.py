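"""Sliding-window MSD analysis and motion-state classification.

The analysis scans each position track with a sliding window (default
40 frames = 2.0 s at 20 frames/s), computes the time-averaged MSD per
window, and fits

    MSD(t) = 4 D * t**alpha + 2 * sigma**2

with the localization error ``sigma`` held fixed (default 9.8 nm).  The
scaling exponent ``alpha`` is ~1 for pure diffusion and ~2 for directed
(ballistic) motion; its per-window distribution over a heterogeneous
track is bimodal.  A two-component Gaussian mixture fitted to the pooled
alpha distribution provides the cutoff separating the two modes (the
point between the component means where the weighted densities are
equal), and frames are labeled directed or diffusive accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import optimize
from sklearn.mixture import GaussianMixture

from .config import AnalysisConfig
from .trajectory import DIFFUSIVE, DIRECTED, Trajectory

__all__ = [
    "MSDCurve",
    "WindowFit",
    "TwoGaussianModel",
    "MotionSegment",
    "windowed_msd",
    "fit_msd",
    "fit_windows",
    "alpha_profile",
    "fit_alpha_distribution",
    "label_segments",
    "validate_separation",
    "alpha_peak",
    "DegenerateMixtureError",
]


@dataclass
class MSDCurve:
    """Time-averaged MSD of one sliding window."""

    lags: np.ndarray      # s, positive increasing
    msd: np.ndarray       # nm^2
    n_pairs: np.ndarray   # displacement pairs per lag
    window: Tuple[int, int]  # (start_frame, end_frame) inclusive


@dataclass
class WindowFit:
    """Result of fitting the anomalous-diffusion model to one window."""

    alpha: float          # scaling exponent
    D: float              # generalized diffusion coefficient, nm^2/s^alpha
    sigma: float          # fixed localization error, nm
    center_frame: int
    fit_ok: bool
    residual: float       # sum of squared residuals, nm^4
    window: Tuple[int, int] = (0, 0)
    reason: str = ""


class DegenerateMixtureError(RuntimeError):
    """The two-Gaussian fit collapsed to a degenerate solution."""


@dataclass
class TwoGaussianModel:
    """Two-Gaussian mixture over the alpha distribution, plus cutoff.

    Components are ordered so that ``means[0] < means[1]`` (diffusive
    mode first).  ``cutoff`` is the alpha value strictly between the two
    means where the weighted component densities are equal; windows with
    alpha >= cutoff are called directed.
    """

    weights: np.ndarray
    means: np.ndarray
    sds: np.ndarray
    cutoff: float

    def component_density(self, x: np.ndarray, k: int) -> np.ndarray:
        w, m, s = self.weights[k], self.means[k], self.sds[k]
        return w * np.exp(-0.5 * ((x - m) / s) ** 2) / (s * np.sqrt(2 * np.pi))


@dataclass
class MotionSegment:
    """Maximal same-state interval of a classified trajectory."""

    start_frame: int   # inclusive
    end_frame: int     # inclusive
    state: str         # DIRECTED or DIFFUSIVE
    mean_alpha: float

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame + 1


# ---------------------------------------------------------------------------
# Windowed MSD


def _msd_matrix(
    x: np.ndarray,
    y: np.ndarray,
    window: int,
    stride: int,
    max_lag: int,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Time-averaged MSD for every window, vectorized.

    Returns ``(starts, lags_frames, msd)`` with ``msd`` of shape
    (n_windows, n_lags).  Within a window of W frames the MSD at lag k
    averages the W-k squared displacements between frames i and i+k.
    """
    n = len(x)
    starts = np.arange(0, n - window + 1, stride)
    lags = np.arange(1, max_lag + 1)
    out = np.empty((len(starts), len(lags)))
    for li, k in enumerate(lags):
        sq = (x[k:] - x[:-k]) ** 2 + (y[k:] - y[:-k]) ** 2
        csum = np.concatenate([[0.0], np.cumsum(sq)])
        npairs = window - k
        out[:, li] = (csum[starts + npairs] - csum[starts]) / npairs
    return starts, lags, out


def windowed_msd(
    traj: Trajectory,
    window_frames: int = 40,
    stride_frames: int = 1,
    max_lag_frames: Optional[int] = None,
) -> List[MSDCurve]:
    """Sliding-window time-averaged MSD curves of a trajectory.

    Lags are restricted to one quarter of the window span by default,
    the usual bias-variance compromise for time-averaged MSDs.
    """
    if len(traj) < window_frames:
        raise ValueError(
            f"trajectory has {len(traj)} frames, shorter than one "
            f"window of {window_frames}"
        )
    if max_lag_frames is None:
        max_lag_frames = window_frames // 4
    dt = traj.dt
    starts, lags, msd = _msd_matrix(
        traj.x, traj.y, window_frames, stride_frames, max_lag_frames
    )
    return [
        MSDCurve(
            lags=lags * dt,
            msd=msd[i],
            n_pairs=window_frames - lags,
            window=(int(s), int(s + window_frames - 1)),
        )
        for i, s in enumerate(starts)
    ]


# ---------------------------------------------------------------------------
# Model fitting: MSD = 4D t^alpha + 2 sigma^2, sigma fixed


def _profile_rss(
    Y: np.ndarray, lags_s: np.ndarray, alphas: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares amplitude and RSS for each (window, alpha) pair.

    For fixed alpha the model is linear in the amplitude A = 4D, so the
    optimum is closed-form: A* = max(0, <y, t^a> / <t^a, t^a>).
    """
    Phi = lags_s[:, None] ** alphas[None, :]          # (L, G)
    denom = np.sum(Phi * Phi, axis=0)                 # (G,)
    num = Y @ Phi                                     # (W, G)
    A = np.clip(num / denom, 0.0, None)
    yy = np.sum(Y * Y, axis=1)
    rss = yy[:, None] - 2.0 * A * num + A * A * denom
    return A, rss


def fit_msd(
    curve: MSDCurve,
    sigma: float = 9.8,
    alpha_bounds: Tuple[float, float] = (0.0, 2.2),
    center_frame: Optional[int] = None,
) -> WindowFit:
    """Fit the anomalous-diffusion model to one MSD curve.

    ``sigma`` is held fixed; ``alpha`` is constrained to
    ``alpha_bounds`` and ``D >= 0``.  Never raises on a failed fit:
    ``fit_ok`` is False with a reason instead.
    """
    if center_frame is None:
        center_frame = (curve.window[0] + curve.window[1] + 1) // 2
    lags = np.asarray(curve.lags, dtype=float)
    if len(lags) < 4:
        return WindowFit(np.nan, np.nan, sigma, center_frame, False,
                         np.nan, curve.window, "fewer than 4 lags")
    y = np.asarray(curve.msd, dtype=float) - 2.0 * sigma**2
    if not np.all(np.isfinite(y)):
        return WindowFit(np.nan, np.nan, sigma, center_frame, False,
                         np.nan, curve.window, "non-finite MSD values")

    lo, hi = alpha_bounds
    grid = np.linspace(lo, hi, 441)
    _, rss = _profile_rss(y[None, :], lags, grid)
    g = int(np.argmin(rss[0]))
    a, b = grid[max(g - 1, 0)], grid[min(g + 1, len(grid) - 1)]

    def objective(alpha: float) -> float:
        _, r = _profile_rss(y[None, :], lags, np.array([alpha]))
        return float(r[0, 0])

    res = optimize.minimize_scalar(
        objective, bounds=(a, b), method="bounded",
        options={"xatol": 1e-9},
    )
    alpha = float(res.x) if res.success else float(grid[g])
    A, rss_best = _profile_rss(y[None, :], lags, np.array([alpha]))
    return WindowFit(
        alpha=alpha,
        D=float(A[0, 0]) / 4.0,
        sigma=sigma,
        center_frame=center_frame,
        fit_ok=bool(np.isfinite(rss_best[0, 0])),
        residual=float(rss_best[0, 0]),
        window=curve.window,
    )


def fit_windows(
    traj: Trajectory, config: Optional[AnalysisConfig] = None
) -> List[WindowFit]:
    """Sliding-window MSD fits for a whole trajectory (vectorized).

    Equivalent to mapping :func:`fit_msd` over :func:`windowed_msd`, but
    fits all windows at once on an alpha grid with parabolic refinement
    (grid step 5e-3; refined well below the alpha scales that matter for
    classification).
    """
    if config is None:
        config = AnalysisConfig()
    if len(traj) < config.window_frames:
        raise ValueError(
            f"trajectory has {len(traj)} frames, shorter than one "
            f"window of {config.window_frames}"
        )
    dt = traj.dt
    starts, lags_f, msd = _msd_matrix(
        traj.x, traj.y, config.window_frames, config.stride_frames,
        config.max_lag_frames,
    )
    lags_s = lags_f * dt
    Y = msd - 2.0 * config.sigma_loc_nm**2
    grid = np.arange(config.alpha_min, config.alpha_max + 1e-12, 0.005)
    A, rss = _profile_rss(Y, lags_s, grid)
    g = np.argmin(rss, axis=1)

    # Parabolic refinement through the three grid points around each min.
    gi = np.clip(g, 1, len(grid) - 2)
    r0 = rss[np.arange(len(g)), gi - 1]
    r1 = rss[np.arange(len(g)), gi]
    r2 = rss[np.arange(len(g)), gi + 1]
    denom = r0 - 2 * r1 + r2
    shift = np.where(denom > 0, 0.5 * (r0 - r2) / np.maximum(denom, 1e-300), 0.0)
    alpha = grid[gi] + np.clip(shift, -1.0, 1.0) * 0.005
    alpha = np.clip(alpha, config.alpha_min, config.alpha_max)
    A_ref, rss_ref = _refit_amplitude(Y, lags_s, alpha)

    half = config.window_frames // 2
    fits = []
    for i, s in enumerate(starts):
        fits.append(
            WindowFit(
                alpha=float(alpha[i]),
                D=float(A_ref[i]) / 4.0,
                sigma=config.sigma_loc_nm,
                center_frame=int(s + half),
                fit_ok=bool(np.isfinite(rss_ref[i])),
                residual=float(rss_ref[i]),
                window=(int(s), int(s + config.window_frames - 1)),
            )
        )
    return fits


def _refit_amplitude(
    Y: np.ndarray, lags_s: np.ndarray, alpha: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Closed-form amplitude and RSS at one alpha per window."""
    Phi = lags_s[None, :] ** alpha[:, None]           # (W, L)
    denom = np.sum(Phi * Phi, axis=1)
    num = np.sum(Y * Phi, axis=1)
    A = np.clip(num / denom, 0.0, None)
    rss = np.sum(Y * Y, axis=1) - 2.0 * A * num + A * A * denom
    return A, rss


def alpha_profile(
    traj: Trajectory, config: Optional[AnalysisConfig] = None
) -> np.ndarray:
    """Per-frame alpha: each frame takes the alpha of the window centred
    on it; edge frames take the nearest window."""
    if config is None:
        config = AnalysisConfig()
    fits = fit_windows(traj, config)
    return per_frame_alpha(fits, len(traj))


def per_frame_alpha(fits: Sequence[WindowFit], n_frames: int) -> np.ndarray:
    ok = [f for f in fits if f.fit_ok]
    if not ok:
        raise ValueError("no valid window fits")
    centers = np.array([f.center_frame for f in ok])
    alphas = np.array([f.alpha for f in ok])
    order = np.argsort(centers)
    centers, alphas = centers[order], alphas[order]
    idx = np.clip(
        np.searchsorted(centers, np.arange(n_frames)), 0, len(centers) - 1
    )
    # searchsorted gives the right neighbour; pick the nearer of the two.
    left = np.clip(idx - 1, 0, len(centers) - 1)
    use_left = np.abs(centers[left] - np.arange(n_frames)) <= np.abs(
        centers[idx] - np.arange(n_frames)
    )
    return alphas[np.where(use_left, left, idx)]


# ---------------------------------------------------------------------------
# Two-Gaussian mixture over alpha and the classification cutoff


def _equal_density_cutoff(w, m, s) -> float:
    """Alpha where the weighted component densities cross, within
    (m[0], m[1]); smaller root if two roots fall between the means,
    midpoint fallback if none does (near-degenerate overlap)."""
    a = 0.5 / s[0] ** 2 - 0.5 / s[1] ** 2
    b = m[1] / s[1] ** 2 - m[0] / s[0] ** 2
    c = (
        0.5 * (m[0] ** 2 / s[0] ** 2 - m[1] ** 2 / s[1] ** 2)
        + np.log(w[1] / s[1])
        - np.log(w[0] / s[0])
    )
    if abs(a) < 1e-12:
        roots = np.array([-c / b]) if abs(b) > 1e-300 else np.array([])
    else:
        disc = b * b - 4 * a * c
        if disc < 0:
            roots = np.array([])
        else:
            sq = np.sqrt(disc)
            roots = np.array([(-b - sq) / (2 * a), (-b + sq) / (2 * a)])
    inside = np.sort(roots[(roots > m[0]) & (roots < m[1])])
    if len(inside):
        return float(inside[0])
    return float(0.5 * (m[0] + m[1]))


def fit_alpha_distribution(
    alphas: Sequence[float],
    seed: int = 0,
    n_init: int = 10,
    min_weight: float = 0.02,
    min_sd: float = 1e-3,
    resolution_sd: float = 0.05,
) -> TwoGaussianModel:
    """Fit a two-component Gaussian mixture to pooled alpha values.

    Maximum likelihood with ``n_init`` random restarts; deterministic
    given ``seed``.  Components are reported diffusive-mode first.

    Alpha estimates from finite windows carry sampling error of order
    ``resolution_sd`` or more, so a fitted component narrower than that
    is not an interpretable motion mode — it is typically a pile-up of
    purely ballistic windows at the alpha ceiling capturing a sliver of
    the distribution.  When the unconstrained fit produces one, the
    mixture is refit with a shared (tied) variance, which restores the
    two-mode decomposition.  Truly degenerate solutions (a vanishing
    weight or collapsed SD) raise :class:`DegenerateMixtureError` with
    a diagnostic.
    """
    a = np.asarray(alphas, dtype=float)
    a = a[np.isfinite(a)]
    if len(a) < 50:
        raise ValueError(f"need at least 50 alpha values, got {len(a)}")
    gm = GaussianMixture(
        n_components=2, covariance_type="full", n_init=n_init,
        random_state=seed, reg_covar=1e-6,
    ).fit(a[:, None])
    w = gm.weights_.ravel()
    m = gm.means_.ravel()
    s = np.sqrt(gm.covariances_.ravel())
    if s.min() < resolution_sd:
        gm = GaussianMixture(
            n_components=2, covariance_type="tied", n_init=n_init,
            random_state=seed, reg_covar=1e-6,
        ).fit(a[:, None])
        w = gm.weights_.ravel()
        m = gm.means_.ravel()
        s = np.full(2, float(np.sqrt(gm.covariances_.ravel()[0])))
    order = np.argsort(m)
    w, m, s = w[order], m[order], s[order]
    if w.min() < min_weight:
        raise DegenerateMixtureError(
            f"component weight {w.min():.4f} below {min_weight}; the alpha "
            "distribution does not support two modes"
        )
    if s.min() < min_sd:
        raise DegenerateMixtureError(
            f"component sd {s.min():.2e} collapsed below {min_sd}"
        )
    cutoff = _equal_density_cutoff(w, m, s)
    return TwoGaussianModel(weights=w, means=m, sds=s, cutoff=cutoff)


def alpha_peak(alphas: Sequence[float], bandwidth: Optional[float] = None) -> float:
    """Location of the dominant mode of an alpha distribution.

    Gaussian kernel density estimate (Silverman bandwidth unless given)
    evaluated on a fine grid over the data range; returns the argmax.
    """
    from scipy.stats import gaussian_kde

    a = np.asarray(alphas, dtype=float)
    a = a[np.isfinite(a)]
    kde = gaussian_kde(a, bw_method=bandwidth)
    grid = np.linspace(a.min(), a.max(), 2048)
    return float(grid[np.argmax(kde(grid))])


# ---------------------------------------------------------------------------
# Segment labeling


def label_segments(
    traj: Trajectory,
    fits: Sequence[WindowFit],
    cutoff: float,
    min_segment_frames: int = 5,
) -> List[MotionSegment]:
    """Label maximal directed/diffusive segments of a trajectory.

    Frames with per-frame alpha >= cutoff are directed.  Segments
    shorter than ``min_segment_frames`` are absorbed into the longer
    neighbour (shortest first), suppressing single-window flicker; the
    result tiles the track with alternating states.
    """
    alpha = per_frame_alpha(fits, len(traj))
    labels = np.where(alpha >= cutoff, DIRECTED, DIFFUSIVE)

    segs = _runs_to_segments(labels, alpha)
    segs = _absorb_short(segs, alpha, min_segment_frames)
    return segs


def _runs_to_segments(labels: np.ndarray, alpha: np.ndarray) -> List[MotionSegment]:
    change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
    bounds = np.concatenate([[0], change, [len(labels)]])
    return [
        MotionSegment(
            start_frame=int(s),
            end_frame=int(e - 1),
            state=str(labels[s]),
            mean_alpha=float(np.mean(alpha[s:e])),
        )
        for s, e in zip(bounds[:-1], bounds[1:])
    ]


def _absorb_short(
    segs: List[MotionSegment], alpha: np.ndarray, min_frames: int
) -> List[MotionSegment]:
    segs = list(segs)
    while len(segs) > 1:
        lengths = [s.n_frames for s in segs]
        i = int(np.argmin(lengths))
        if lengths[i] >= min_frames:
            break
        # merge into the longer neighbour (ties: earlier neighbour)
        if i == 0:
            j = 1
        elif i == len(segs) - 1:
            j = i - 1
        else:
            j = i - 1 if segs[i - 1].n_frames >= segs[i + 1].n_frames else i + 1
        lo, hi = min(i, j), max(i, j)
        merged = MotionSegment(
            start_frame=segs[lo].start_frame,
            end_frame=segs[hi].end_frame,
            state=segs[j].state,
            mean_alpha=float(
                np.mean(alpha[segs[lo].start_frame : segs[hi].end_frame + 1])
            ),
        )
        segs[lo : hi + 1] = [merged]
        # coalesce equal-state neighbours created by the merge
        out: List[MotionSegment] = []
        for s in segs:
            if out and out[-1].state == s.state:
                prev = out.pop()
                out.append(
                    MotionSegment(
                        start_frame=prev.start_frame,
                        end_frame=s.end_frame,
                        state=s.state,
                        mean_alpha=float(
                            np.mean(alpha[prev.start_frame : s.end_frame + 1])
                        ),
                    )
                )
            else:
                out.append(s)
        segs = out
    return segs


# ---------------------------------------------------------------------------
# Separation-quality diagnostic


def validate_separation(
    labeled: Sequence[Tuple[Trajectory, Sequence[MotionSegment]]],
    n_sample: int = 1500,
    sigma: float = 9.8,
    min_segments: int = 100,
    min_segment_frames: int = 16,
    seed: int = 0,
) -> dict:
    """Average the MSDs of sampled segments per class and refit.

    Randomly samples up to ``n_sample`` segments per class (at least
    ``min_segment_frames`` frames long so the fit has >= 4 lags),
    computes each segment's time-averaged MSD at lags up to a quarter of
    its span, averages per class at common lags, and fits the
    anomalous-diffusion model to each class average.  The per-class
    average alpha is a diagnostic of how cleanly diffusive and directed
    motion were separated.
    """
    rng = np.random.default_rng(seed)
    pools = {DIFFUSIVE: [], DIRECTED: []}
    for traj, segs in labeled:
        for seg in segs:
            if seg.n_frames >= min_segment_frames:
                pools[seg.state].append((traj, seg))

    out = {}
    for state, pool in pools.items():
        flag = len(pool) < min_segments
        if not pool:
            out[state] = {"alpha": np.nan, "D": np.nan, "n_segments": 0,
                          "too_few": True}
            continue
        take = min(n_sample, len(pool))
        idx = rng.choice(len(pool), size=take, replace=False)
        # average per-segment MSDs at the common lag grid 1..4 frames
        # (every sampled segment supports them); longer lags would drop
        # short segments from the average unevenly.
        lag_frames = np.arange(1, min_segment_frames // 4 + 1)
        acc = np.zeros(len(lag_frames))
        dt = None
        for i in idx:
            traj, seg = pool[i]
            dt = traj.dt
            xs = traj.x[seg.start_frame : seg.end_frame + 1]
            ys = traj.y[seg.start_frame : seg.end_frame + 1]
            for li, k in enumerate(lag_frames):
                d = (xs[k:] - xs[:-k]) ** 2 + (ys[k:] - ys[:-k]) ** 2
                acc[li] += d.mean()
        msd = acc / take
        curve = MSDCurve(
            lags=lag_frames * dt, msd=msd,
            n_pairs=np.full(len(lag_frames), take), window=(0, 0),
        )
        fit = fit_msd(curve, sigma=sigma)
        out[state] = {
            "alpha": fit.alpha,
            "D": fit.D,
            "n_segments": take,
            "too_few": flag,
        }
    return out
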