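"""Baseline normalization and hypo-/hyperperfusion area statistics.

Relative flow maps are normalized pixel-by-pixel to the pre-stroke baseline,
N(t) = CBF(t)/CBF(0).  The hypoperfused territory CBF_50(t) is the area of
ipsilateral pixels with a strictly greater than 50% flow reduction (N < 0.5);
CBF_+(t) is the area with flow enhanced above baseline by a configurable
margin; occlusion of the targeted vessel is declared successful when the
regional mean over the illumination-focus ROI has dropped by strictly more
than 85%.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .flow import FlowMap

__all__ = [
    "NormalizedFlowMap",
    "PerfusionMask",
    "AreaSeries",
    "normalize_to_baseline",
    "reduction_mask",
    "enhancement_mask",
    "mask_area",
    "occlusion_success",
    "area_time_series",
]

REDUCTION_THRESHOLD = 0.5
DEFAULT_ENHANCEMENT_THRESHOLD = 1.2
DEFAULT_OCCLUSION_CRITERION = 0.85
PRIMARY_ENDPOINT_MIN = 15.0


@dataclass
class NormalizedFlowMap:
    """Per-pixel flow relative to the pre-stroke baseline (1 = baseline)."""

    N: np.ndarray
    valid: np.ndarray
    bin_time_min: float | None = None
    pixel_pitch_mm: float | None = None


@dataclass
class PerfusionMask:
    B: np.ndarray
    threshold_kind: str  # "reduction" | "enhancement"
    threshold: float
    bin_time_min: float | None = None


@dataclass
class AreaSeries:
    times_min: np.ndarray
    areas_mm2: np.ndarray
    kind: str  # "CBF_50" | "CBF_plus"
    pixel_pitch_mm: float
    primary_endpoint_min: float = PRIMARY_ENDPOINT_MIN

    @property
    def primary_endpoint_mm2(self) -> float:
        """Area at the primary analysis time (15 min after onset)."""
        idx = int(np.argmin(np.abs(np.asarray(self.times_min) - self.primary_endpoint_min)))
        return float(self.areas_mm2[idx])


def normalize_to_baseline(
    series: list[FlowMap] | FlowMap, baseline: FlowMap
) -> list[NormalizedFlowMap] | NormalizedFlowMap:
    """N = cbf(t) / cbf(0) pixelwise.

    Pixels whose baseline flow falls below 1% of the baseline median are
    excluded (division guard); an entirely invalid baseline is an error.
    """
    single = isinstance(series, FlowMap)
    maps = [series] if single else list(series)
    base_vals = baseline.cbf[baseline.valid & (baseline.cbf > 0)]
    if base_vals.size == 0:
        raise ValueError("baseline flow map has no valid positive pixels")
    floor = 0.01 * float(np.median(base_vals))
    base_ok = baseline.valid & (baseline.cbf > floor)
    out = []
    for fmap in maps:
        if fmap.cbf.shape != baseline.cbf.shape:
            raise ValueError("flow map shapes must match the baseline")
        valid = fmap.valid & base_ok
        N = np.full(fmap.cbf.shape, np.nan)
        N[valid] = fmap.cbf[valid] / baseline.cbf[valid]
        out.append(
            NormalizedFlowMap(
                N=N,
                valid=valid,
                bin_time_min=fmap.bin_time_min,
                pixel_pitch_mm=fmap.pixel_pitch_mm or baseline.pixel_pitch_mm,
            )
        )
    return out[0] if single else out


def reduction_mask(nmap: NormalizedFlowMap, hemisphere: np.ndarray) -> PerfusionMask:
    """Pixels with over 50% flow reduction (strictly N < 0.5) in the
    ipsilateral hemisphere."""
    with np.errstate(invalid="ignore"):
        B = (nmap.N < REDUCTION_THRESHOLD) & hemisphere & nmap.valid
    return PerfusionMask(
        B=B, threshold_kind="reduction", threshold=REDUCTION_THRESHOLD, bin_time_min=nmap.bin_time_min
    )


def enhancement_mask(
    nmap: NormalizedFlowMap,
    hemisphere: np.ndarray,
    threshold: float = DEFAULT_ENHANCEMENT_THRESHOLD,
) -> PerfusionMask:
    """Pixels with flow enhanced above baseline (strictly N > threshold)."""
    if threshold <= 1:
        raise ValueError("enhancement threshold must exceed 1")
    with np.errstate(invalid="ignore"):
        B = (nmap.N > threshold) & hemisphere & nmap.valid
    return PerfusionMask(
        B=B, threshold_kind="enhancement", threshold=threshold, bin_time_min=nmap.bin_time_min
    )


def mask_area(mask: PerfusionMask, pixel_pitch_mm: float) -> float:
    """Pixel sum converted to mm² (count × pitch²)."""
    if pixel_pitch_mm <= 0:
        raise ValueError("pixel pitch must be positive")
    return float(mask.B.sum()) * pixel_pitch_mm**2


def occlusion_success(
    nmap: NormalizedFlowMap,
    mca_roi: np.ndarray,
    criterion: float = DEFAULT_OCCLUSION_CRITERION,
) -> bool:
    """True iff regional flow over the vessel-focus ROI dropped by strictly
    more than ``criterion`` (default 85%) relative to baseline."""
    roi = mca_roi & nmap.valid
    if not np.any(roi):
        raise ValueError("MCA ROI contains no valid pixels")
    # strict inequality; the epsilon guards against float representation of
    # 1 - criterion so that a mean of exactly (1 - criterion) fails the test
    threshold = 1.0 - criterion
    return bool(np.mean(nmap.N[roi]) < threshold - 1e-9 * max(threshold, 1.0))


def area_time_series(
    flow_maps: list[FlowMap],
    baseline: FlowMap | None,
    hemisphere: np.ndarray,
    pixel_pitch_mm: float | None = None,
    enhancement_threshold: float = DEFAULT_ENHANCEMENT_THRESHOLD,
) -> tuple[AreaSeries, AreaSeries]:
    """CBF_50(t) and CBF_+(t) area time series for one animal.

    Every flow map must carry its analysis-bin time; maps are processed in
    time order.  The baseline map (pre-illumination) is mandatory.
    """
    if baseline is None:
        raise ValueError("a pre-illumination baseline flow map is required")
    if any(f.bin_time_min is None for f in flow_maps):
        raise ValueError("every flow map needs a bin time")
    order = np.argsort([f.bin_time_min for f in flow_maps], kind="stable")
    maps = [flow_maps[i] for i in order]
    pitch = pixel_pitch_mm or maps[0].pixel_pitch_mm or baseline.pixel_pitch_mm
    if pitch is None:
        raise ValueError("pixel pitch unknown")
    nmaps = normalize_to_baseline(maps, baseline)
    times, red, enh = [], [], []
    for nmap in nmaps:
        times.append(nmap.bin_time_min)
        red.append(mask_area(reduction_mask(nmap, hemisphere), pitch))
        enh.append(mask_area(enhancement_mask(nmap, hemisphere, enhancement_threshold), pitch))
    times = np.asarray(times)
    return (
        AreaSeries(times_min=times, areas_mm2=np.asarray(red), kind="CBF_50", pixel_pitch_mm=pitch),
        AreaSeries(times_min=times, areas_mm2=np.asarray(enh), kind="CBF_plus", pixel_pitch_mm=pitch),
    )
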