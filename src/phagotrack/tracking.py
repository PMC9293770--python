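"""Sub-pixel single-particle localization and frame-to-frame tracking.

Positions are recovered by the centroid position method: within a square
region of interest around a guess, the background (ROI minimum or a low
percentile) is subtracted, negative intensities are clamped to zero, and
the intensity-weighted centroid gives the sub-pixel position, converted
to nanometres via the pixel size.  Tracking walks the stack frame by
frame using the previous position as the next guess, gated by a maximum
step so a lost particle terminates the track instead of jumping to
background structure.
"""

from __future__ import annotations

import warnings
from typing import Optional, Tuple

import numpy as np

from .config import TrackingConfig
from .trajectory import Trajectory

__all__ = ["LocalizationError", "localize_centroid", "track_stack"]


class LocalizationError(RuntimeError):
    """Localization failed on a specific frame."""


def localize_centroid(
    frame: np.ndarray,
    guess: Tuple[float, float],
    cfg: Optional[TrackingConfig] = None,
    pixel_size: float = 27.6,
    frame_index: int = 0,
) -> Tuple[float, float]:
    """Background-subtracted intensity-weighted centroid near ``guess``.

    ``guess`` is (x, y) in pixels; the return value is (x, y) in nm with
    pixel (i, j) centred at ``(j * pixel_size, i * pixel_size)``.

    Raises :class:`LocalizationError` naming the frame if the ROI
    touches the image border or carries no intensity above background.
    """
    if cfg is None:
        cfg = TrackingConfig()
    hw = cfg.roi_halfwidth
    cx, cy = int(round(guess[0])), int(round(guess[1]))
    ny, nx = frame.shape
    if cx - hw < 0 or cy - hw < 0 or cx + hw > nx - 1 or cy + hw > ny - 1:
        raise LocalizationError(
            f"frame {frame_index}: ROI around ({guess[0]:.1f}, {guess[1]:.1f}) "
            "touches the image border"
        )
    roi = np.asarray(frame[cy - hw : cy + hw + 1, cx - hw : cx + hw + 1], dtype=float)
    if cfg.background_method == "roi_min":
        bg = roi.min()
    else:
        bg = np.percentile(roi, 100.0 * cfg.percentile)
    w = np.clip(roi - bg, 0.0, None)
    total = w.sum()
    if total <= 0:
        raise LocalizationError(
            f"frame {frame_index}: no intensity above background in ROI"
        )
    jj = np.arange(cx - hw, cx + hw + 1, dtype=float)
    ii = np.arange(cy - hw, cy + hw + 1, dtype=float)
    x_px = float((w.sum(axis=0) @ jj) / total)
    y_px = float((w.sum(axis=1) @ ii) / total)
    return x_px * pixel_size, y_px * pixel_size


def track_stack(
    stack: np.ndarray,
    start: Tuple[float, float],
    cfg: Optional[TrackingConfig] = None,
    pixel_size: float = 27.6,
    frame_rate: float = 20.0,
) -> Trajectory:
    """Track one particle through a stack starting from ``start`` (pixels).

    Each frame is localized with the previous position as the guess.  A
    step larger than ``cfg.max_step`` nm, or a localization failure after
    frame 0, terminates the track at the last good frame with a warning;
    the track is never silently interpolated.
    """
    if cfg is None:
        cfg = TrackingConfig()
    xs, ys = [], []
    guess = (float(start[0]), float(start[1]))
    for f in range(stack.shape[0]):
        try:
            x_nm, y_nm = localize_centroid(
                stack[f], guess, cfg, pixel_size=pixel_size, frame_index=f
            )
        except LocalizationError:
            if f == 0:
                raise
            warnings.warn(
                f"particle lost at frame {f}; track terminated at frame {f - 1}",
                stacklevel=2,
            )
            break
        if xs:
            step = np.hypot(x_nm - xs[-1], y_nm - ys[-1])
            if step > cfg.max_step:
                warnings.warn(
                    f"step of {step:.0f} nm at frame {f} exceeds max_step "
                    f"{cfg.max_step:.0f} nm; track terminated at frame {f - 1}",
                    stacklevel=2,
                )
                break
        xs.append(x_nm)
        ys.append(y_nm)
        guess = (x_nm / pixel_size, y_nm / pixel_size)
    n = len(xs)
    return Trajectory(
        frames=np.arange(n),
        times=np.arange(n) / frame_rate,
        x=np.array(xs),
        y=np.array(ys),
        source="tracked",
        meta={"pixel_size_nm": pixel_size, "frame_rate": frame_rate},
    )
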