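"""Rigid translational motion correction for speckle frame stacks.

Awake-animal recordings through a skull-mounted chamber are dominated by
in-plane translation, so registration is restricted to a rigid shift:
frequency-domain cross-correlation of mean-removed frames, with the integer
peak refined to subpixel precision by a separable quadratic fit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import fourier_shift, gaussian_filter

from .errors import DegenerateInputError
from .stack import SpeckleStack

__all__ = ["ShiftEstimate", "estimate_shift", "align_stack", "translate_frame"]


@dataclass
class ShiftEstimate:
    """Estimated (dy, dx) such that ``moving ≈ translate(reference, (dy, dx))``.

    ``confidence`` is the ratio of the correlation peak to the strongest
    secondary peak outside a 5-px exclusion zone (≈1 means ambiguous).
    """

    dy: float
    dx: float
    confidence: float


def translate_frame(frame: np.ndarray, shift: tuple[float, float]) -> np.ndarray:
    """Subpixel translation by Fourier interpolation (periodic boundaries)."""
    if shift[0] == 0 and shift[1] == 0:
        return frame.copy()
    return np.fft.ifft2(fourier_shift(np.fft.fft2(frame), shift)).real


def _wrap(idx: int, n: int) -> int:
    return idx - n if idx > n // 2 else idx


def _quadratic_offset(cm1: float, c0: float, cp1: float) -> float:
    denom = cm1 - 2.0 * c0 + cp1
    if denom >= 0:  # not a local max; keep the integer estimate
        return 0.0
    return float(np.clip(0.5 * (cm1 - cp1) / denom, -0.5, 0.5))


def estimate_shift(
    reference: np.ndarray, moving: np.ndarray, presmooth_px: float = 0.0
) -> ShiftEstimate:
    """Translation of ``moving`` relative to ``reference``.

    Cross-correlation is computed in the Fourier domain on mean-removed,
    variance-normalized images; the correlation peak is refined per axis by a
    quadratic fit through its two wrapped neighbours.  ``presmooth_px``
    applies a Gaussian low-pass to both inputs first: on speckle data this
    suppresses the frame-to-frame decorrelating component so the correlation
    is carried by the persistent anatomy.
    """
    if reference.shape != moving.shape:
        raise ValueError("frames must share a shape")
    a = np.asarray(reference, dtype=np.float64)
    b = np.asarray(moving, dtype=np.float64)
    if presmooth_px > 0:
        a = gaussian_filter(a, presmooth_px)
        b = gaussian_filter(b, presmooth_px)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        raise DegenerateInputError("degenerate-input: constant image cannot be registered")
    a = (a - a.mean()) / sa
    b = (b - b.mean()) / sb
    C = np.fft.ifft2(np.fft.fft2(b) * np.conj(np.fft.fft2(a))).real
    h, w = C.shape
    iy, ix = np.unravel_index(np.argmax(C), C.shape)
    dy = _wrap(int(iy), h)
    dx = _wrap(int(ix), w)
    dy += _quadratic_offset(C[(iy - 1) % h, ix], C[iy, ix], C[(iy + 1) % h, ix])
    dx += _quadratic_offset(C[iy, (ix - 1) % w], C[iy, ix], C[iy, (ix + 1) % w])

    yy = (np.arange(h)[:, None] - iy + h // 2) % h - h // 2
    xx = (np.arange(w)[None, :] - ix + w // 2) % w - w // 2
    outside = yy * yy + xx * xx > 25
    secondary = float(C[outside].max()) if np.any(outside) else 0.0
    confidence = float(C[iy, ix] / secondary) if secondary > 0 else float("inf")
    return ShiftEstimate(dy=float(dy), dx=float(dx), confidence=confidence)


def align_stack(
    stack: SpeckleStack,
    reference_index: int = 0,
    reference: np.ndarray | None = None,
    presmooth_px: float = 2.0,
) -> tuple[SpeckleStack, list[ShiftEstimate]]:
    """Register every frame to the reference and undo its shift.

    The reference defaults to the frame at ``reference_index``; an explicit
    reference image — ideally the temporal mean of a pre-ischemic baseline
    interval, which averages away the fluctuating speckle — may be supplied
    instead.  Registration inputs are pre-smoothed (σ = ``presmooth_px``);
    the output frames themselves are shifted originals.  Returns the aligned
    stack and the shift log.
    """
    if reference is None:
        if not 0 <= reference_index < len(stack):
            raise ValueError("reference_index out of range")
        reference = stack.frames[reference_index]
    shifts: list[ShiftEstimate] = []
    out = np.empty_like(stack.frames)
    for k, frame in enumerate(stack.frames):
        est = estimate_shift(reference, frame, presmooth_px=presmooth_px)
        shifts.append(est)
        out[k] = np.maximum(translate_frame(frame, (-est.dy, -est.dx)), 0.0)
    return stack.replace_frames(out, motion_schedule_px=None), shifts
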