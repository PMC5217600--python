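"""The raw speckle frame-stack container.

A :class:`SpeckleStack` holds an ordered sequence of time-integrated speckle
intensity frames plus the acquisition metadata every downstream stage needs:
the camera exposure time ``T`` (which enters the contrast-to-correlation-time
model), the frame rate, and the pixel pitch used to convert pixel counts to
mm².
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class SpeckleStack:
    """Ordered speckle frames with acquisition metadata.

    Parameters
    ----------
    frames:
        Array of shape ``(n_frames, h, w)``, nonnegative intensities.
    exposure_s:
        Camera exposure time ``T`` in seconds. Must not exceed the frame
        interval ``1 / frame_rate_hz``.
    frame_rate_hz:
        Acquisition rate in frames per second.
    pixel_pitch_mm:
        Physical size of one pixel in mm.
    timestamps_s:
        Frame-start times in seconds; defaults to ``k / frame_rate_hz``.
    motion_schedule_px:
        Optional per-frame ``(dy, dx)`` ground-truth translations, recorded by
        the simulator when jitter is injected so registration can be scored.
    """

    frames: np.ndarray
    exposure_s: float
    frame_rate_hz: float
    pixel_pitch_mm: float
    timestamps_s: np.ndarray | None = None
    motion_schedule_px: np.ndarray | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=np.float64)
        if self.frames.ndim != 3:
            raise ValueError("frames must have shape (n_frames, h, w)")
        if np.any(self.frames < 0):
            raise ValueError("speckle intensities must be nonnegative")
        if self.exposure_s <= 0 or self.frame_rate_hz <= 0:
            raise ValueError("exposure and frame rate must be positive")
        if self.exposure_s > 1.0 / self.frame_rate_hz + 1e-12:
            raise ValueError("exposure_s may not exceed the frame interval")
        if self.timestamps_s is None:
            self.timestamps_s = np.arange(len(self.frames)) / self.frame_rate_hz
        else:
            self.timestamps_s = np.asarray(self.timestamps_s, dtype=np.float64)
            if len(self.timestamps_s) != len(self.frames):
                raise ValueError("one timestamp per frame required")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def replace_frames(self, frames: np.ndarray, **extra) -> "SpeckleStack":
        """Copy of this stack with new pixel data, metadata preserved."""
        kwargs = dict(
            exposure_s=self.exposure_s,
            frame_rate_hz=self.frame_rate_hz,
            pixel_pitch_mm=self.pixel_pitch_mm,
            timestamps_s=self.timestamps_s.copy(),
            motion_schedule_px=self.motion_schedule_px,
            seed=self.seed,
        )
        kwargs.update(extra)
        return SpeckleStack(np.asarray(frames), **kwargs)
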