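"""Per-pixel speckle contrast estimation (K = σ/⟨I⟩).

Two estimators are provided: the standard spatial estimator (sliding-window
standard deviation over mean, computed per frame and averaged over an analysis
bin) and a temporal estimator (per-pixel statistics across frames) used as an
internal cross-check.  Contrast is invariant to global intensity scaling by
construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

from .stack import SpeckleStack

__all__ = ["ContrastMap", "spatial_contrast", "temporal_contrast"]


@dataclass
class ContrastMap:
    """Per-pixel speckle contrast for one analysis time bin.

    ``K`` is NaN wherever ``valid`` is False: the window border of width
    ``(window − 1) / 2`` and any pixel whose window mean is nonpositive.
    """

    K: np.ndarray
    valid: np.ndarray
    window: int
    n_frames_averaged: int
    bin_time_min: float | None = None
    pixel_pitch_mm: float | None = None
    exposure_s: float | None = None


def _frame_contrast(frame: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    mean = uniform_filter(frame, size=window, mode="reflect")
    sqmean = uniform_filter(frame * frame, size=window, mode="reflect")
    var = np.maximum(sqmean - mean * mean, 0.0)
    valid = mean > 0
    K = np.full(frame.shape, np.nan)
    K[valid] = np.sqrt(var[valid]) / mean[valid]
    return K, valid


def _border_mask(shape: tuple[int, int], window: int) -> np.ndarray:
    half = (window - 1) // 2
    interior = np.zeros(shape, dtype=bool)
    interior[half : shape[0] - half, half : shape[1] - half] = True
    return interior


def spatial_contrast(
    stack: SpeckleStack,
    window: int = 7,
    frame_range: tuple[int, int] | None = None,
    bin_time_min: float | None = None,
) -> ContrastMap:
    """Sliding-window contrast, averaged over the frames of one bin.

    Parameters
    ----------
    window:
        Odd window side length in pixels (default 7, the common choice for
        640² speckle imaging: large enough for a stable variance estimate,
        small enough to resolve the occlusion boundary).
    frame_range:
        Half-open ``(start, stop)`` frame indices; defaults to the whole stack.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    start, stop = frame_range if frame_range is not None else (0, len(stack))
    if stop <= start:
        raise ValueError("frame bin must be nonempty")
    frames = stack.frames[start:stop]

    acc = np.zeros(stack.shape)
    valid = np.ones(stack.shape, dtype=bool)
    for frame in frames:
        if not np.any(frame > 0):
            warnings.warn("all-zero frame: contrast undefined everywhere", RuntimeWarning)
            valid &= False
            continue
        K, v = _frame_contrast(frame, window)
        acc += np.where(v, K, 0.0)
        valid &= v
    valid &= _border_mask(stack.shape, window)
    K = np.full(stack.shape, np.nan)
    if np.any(valid):
        K[valid] = acc[valid] / len(frames)
    return ContrastMap(
        K=K,
        valid=valid,
        window=window,
        n_frames_averaged=len(frames),
        bin_time_min=bin_time_min,
        pixel_pitch_mm=stack.pixel_pitch_mm,
        exposure_s=stack.exposure_s,
    )


def temporal_contrast(
    stack: SpeckleStack, n_frames: int, bin_time_min: float | None = None
) -> ContrastMap:
    """Per-pixel sd/mean across ``n_frames`` consecutive frames.

    Independent of any spatial window, so it serves as a cross-check of the
    spatial estimator on statistically uniform regions.
    """
    if n_frames < 8:
        raise ValueError("temporal contrast needs at least 8 frames")
    if n_frames > len(stack):
        raise ValueError("n_frames exceeds stack length")
    frames = stack.frames[:n_frames]
    mean = frames.mean(axis=0)
    sd = frames.std(axis=0, ddof=1)
    valid = mean > 0
    K = np.full(stack.shape, np.nan)
    K[valid] = sd[valid] / mean[valid]
    return ContrastMap(
        K=K,
        valid=valid,
        window=1,
        n_frames_averaged=n_frames,
        bin_time_min=bin_time_min,
        pixel_pitch_mm=stack.pixel_pitch_mm,
        exposure_s=stack.exposure_s,
    )
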