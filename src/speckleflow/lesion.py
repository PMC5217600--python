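"""Lesion and infarct volumetry by threshold planimetry.

Slice stacks (T2-like MRI, 1-mm slices; TTC-like, 3-mm slices) are quantified
per slice: 3 × 3 Gaussian smoothing, a threshold at 75% of each slice's
maximum intensity, pixel count × pitch² per slice, and total volume as the sum
of slice areas times the slice thickness.  The lesion (T2 hyperintensity) and
the infarct (TTC pallor) are both treated as the bright class of the analyzed
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import convolve

__all__ = [
    "VolumeImage",
    "LesionResult",
    "smooth_slice",
    "threshold_75max",
    "lesion_volume",
    "infarct_volume",
]

# 3 x 3 Gaussian, sigma = 1 px, normalized to unit sum.
_g = np.exp(-0.5 * np.arange(-1, 2) ** 2)
GAUSSIAN_3X3 = np.outer(_g, _g) / np.outer(_g, _g).sum()

THRESHOLD_FRACTION = 0.75


@dataclass
class VolumeImage:
    """A slice stack with voxel geometry.

    ``slices`` has shape ``(n_slices, h, w)``; ``modality`` is "MRI-like" or
    "TTC-like".  When produced by the simulator, ``truth_mask`` holds the
    planted lesion voxels and ``true_volume_mm3`` their exact volume.
    """

    slices: np.ndarray
    slice_thickness_mm: float
    in_plane_pitch_mm: float
    modality: str = "MRI-like"
    truth_mask: np.ndarray | None = None
    true_volume_mm3: float | None = None

    def __post_init__(self) -> None:
        self.slices = np.asarray(self.slices, dtype=np.float64)
        if self.slices.ndim != 3:
            raise ValueError("slices must have shape (n_slices, h, w)")
        if self.slice_thickness_mm <= 0 or self.in_plane_pitch_mm <= 0:
            raise ValueError("voxel geometry must be positive")

    @property
    def voxel_volume_mm3(self) -> float:
        return self.in_plane_pitch_mm**2 * self.slice_thickness_mm


@dataclass
class LesionResult:
    per_slice_area_mm2: list[float]
    total_volume_mm3: float
    threshold_used: list[float] = field(default_factory=list)
    masks: np.ndarray | None = None


def smooth_slice(slice_img: np.ndarray) -> np.ndarray:
    """3 × 3 Gaussian smoothing (σ = 1 px, reflective borders)."""
    slice_img = np.asarray(slice_img, dtype=np.float64)
    if slice_img.shape[0] < 3 or slice_img.shape[1] < 3:
        raise ValueError("slice must be at least 3 x 3")
    return convolve(slice_img, GAUSSIAN_3X3, mode="reflect")


def threshold_75max(slice_img: np.ndarray) -> np.ndarray:
    """Select pixels at or above 75% of the slice's own maximum.

    A slice whose maximum is nonpositive carries no lesion signal and yields
    an empty mask rather than an exception.
    """
    m = float(np.max(slice_img))
    if m <= 0:
        return np.zeros(slice_img.shape, dtype=bool)
    return slice_img >= THRESHOLD_FRACTION * m


def _planimetry(vol: VolumeImage) -> LesionResult:
    """Per-slice smooth → 75%-max threshold → area; Σ area × thickness.

    The per-image threshold presupposes that the image contains lesion: on a
    lesion-free slice, 75% of the (background) maximum would select the whole
    background.  Slices are therefore screened against the volume-wide
    maximum first — a slice participates only if its own smoothed maximum
    reaches 75% of the brightest slice's, i.e. if it plausibly contains the
    hyperintense class at all.
    """
    smoothed = [smooth_slice(sl) for sl in vol.slices]
    vol_max = max(float(np.max(sm)) for sm in smoothed) if smoothed else 0.0
    areas: list[float] = []
    thresholds: list[float] = []
    masks = np.zeros(vol.slices.shape, dtype=bool)
    px_area = vol.in_plane_pitch_mm**2
    for i, sm in enumerate(smoothed):
        if float(np.max(sm)) < THRESHOLD_FRACTION * vol_max:
            thresholds.append(float("nan"))
            areas.append(0.0)
            continue
        mask = threshold_75max(sm)
        masks[i] = mask
        thresholds.append(THRESHOLD_FRACTION * float(np.max(sm)))
        areas.append(float(mask.sum()) * px_area)
    total = float(np.sum(areas)) * vol.slice_thickness_mm
    return LesionResult(
        per_slice_area_mm2=areas, total_volume_mm3=total, threshold_used=thresholds, masks=masks
    )


def lesion_volume(vol: VolumeImage) -> LesionResult:
    """T2-like lesion volumetry: smooth → 75%-max threshold → Σ area × thickness."""
    return _planimetry(vol)


def infarct_volume(vol: VolumeImage) -> LesionResult:
    """TTC-like infarct volumetry.

    Expects the pallor channel as a single intensity image per slice (pale
    infarct bright); applies the same per-slice smoothing and 75%-max
    threshold, with the stack's slice thickness (3 mm for standard brain
    matrices) in the volume sum.
    """
    if vol.modality != "TTC-like":
        raise ValueError("infarct_volume expects a TTC-like stack")
    return _planimetry(vol)
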