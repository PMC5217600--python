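"""Synthetic data with known ground truth for every pipeline stage.

This module is the test bed for the whole analysis: it renders time-integrated
dynamic speckle whose local contrast follows the single-exposure
contrast-decorrelation model for a prescribed per-pixel correlation-time map,
grows a focal occlusion territory to a target hypoperfused area, injects rigid
translational jitter, plants ellipsoidal lesions in T2-like and TTC-like slice
stacks, and draws per-rat, per-examiner neurological-score cohorts.

Speckle synthesis follows standard fully-developed-speckle statistics: a
spatially band-limited complex circular Gaussian field (Fourier-domain
low-pass, cutoff set by the speckle grain size) evolves between sub-exposure
steps as an AR(1) process with per-pixel coefficient exp(−Δt/τ_c), and the
camera frame is the mean of |field|² over the exposure.  With M sub-steps the
frame contrast reproduces K²(τ_c/T) by construction, up to O(1/M)
discretization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable

import numpy as np
from scipy.ndimage import fourier_shift

from .errors import EmptyIntervalError, ScenarioOverflowError, UndersampledIntegrationError
from .lesion import VolumeImage
from .stack import SpeckleStack
from .stats import NSS_CATEGORY_MAXIMA, NSS_MAX_TOTAL, NSSRecord

__all__ = [
    "ScenarioConfig",
    "FlowPhantom",
    "make_flow_phantom",
    "render_speckle_frame",
    "render_sequence",
    "inject_motion",
    "make_lesion_volume",
    "make_nss_cohort",
]


def linear_growth(target_area_mm2: float, t_plateau_min: float = 15.0) -> Callable[[float], float]:
    """Monotone territory growth: linear ramp reaching the target at 15 min."""

    def curve(t_min: float) -> float:
        return target_area_mm2 * min(max(t_min, 0.0) / t_plateau_min, 1.0)

    return curve


@dataclass
class ScenarioConfig:
    """Everything that defines one simulated occlusion experiment.

    Defaults emulate the acquisition geometry of a 640-px cranial-window
    recording at 50 fps: pixel pitch 0.0109 mm/px (640 px across the 7-mm
    window dimension), 5-ms exposure, β = 1 for the simulated detector, grain
    size 2 px (Nyquist-sampled speckle).  The occlusion is a disc whose flow
    drops to ``occlusion_flow_fraction`` of baseline, with an inner core
    (the illuminated vessel focus) at ``core_flow_fraction`` so that both the
    >50%-reduction territory and the >85% regional-decrease occlusion check
    are realizable in one scenario.

    ``anatomy_contrast`` > 0 multiplies every frame by a static structured
    reflectance pattern (see :func:`make_anatomy_pattern`).  It is off by
    default: quantitative scenarios model a homogeneous-albedo cortex where
    the contrast-decorrelation theory holds exactly.  Enable it (0.4 is
    realistic) when simulating motion, since frame-to-frame registration
    needs persistent structure; note that sharp static structure inflates
    windowed contrast and biases area statistics by several percent, as it
    does over vasculature in real recordings.
    """

    target_area_15min_mm2: float = 19.5
    baseline_tau_s: float = 1e-3
    occlusion_flow_fraction: float = 0.3
    core_flow_fraction: float = 0.03
    core_radius_fraction: float = 0.5
    growth_curve: Callable[[float], float] | None = None
    image_shape: tuple[int, int] = (640, 640)
    pixel_pitch_mm: float = 0.0109
    exposure_s: float = 5e-3
    frame_rate_hz: float = 50.0
    beta: float = 1.0
    speckle_size_px: float = 2.0
    n_substeps: int = 64
    anatomy_contrast: float = 0.0
    anatomy_corr_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.occlusion_flow_fraction < 0.5:
            raise ValueError("occlusion_flow_fraction must lie in (0, 0.5)")
        if not 0 < self.core_flow_fraction <= self.occlusion_flow_fraction:
            raise ValueError("core flow must not exceed territory flow")
        if not 0 < self.beta <= 1:
            raise ValueError("beta must lie in (0, 1]")
        if self.exposure_s > 1.0 / self.frame_rate_hz + 1e-12:
            raise ValueError("exposure must not exceed the frame interval")
        if self.baseline_tau_s <= 0 or self.pixel_pitch_mm <= 0:
            raise ValueError("baseline tau and pixel pitch must be positive")
        if self.n_substeps < 32:
            raise ValueError("at least 32 sub-integration steps are required")
        hemi_area = self.hemisphere_mask().sum() * self.pixel_pitch_mm**2
        if self.target_area_15min_mm2 > hemi_area:
            raise ScenarioOverflowError(
                f"scenario-overflow: target area {self.target_area_15min_mm2} mm² exceeds "
                f"hemisphere area {hemi_area:.1f} mm²"
            )
        if self.growth_curve is None:
            self.growth_curve = linear_growth(self.target_area_15min_mm2)

    def hemisphere_mask(self) -> np.ndarray:
        """Ipsilateral (left) hemisphere: columns left of the image midline."""
        h, w = self.image_shape
        mask = np.zeros((h, w), dtype=bool)
        mask[:, : w // 2] = True
        return mask

    @property
    def occlusion_center_px(self) -> tuple[float, float]:
        # fractional offsets break pixel-distance ties so the rasterized disc
        # can match any requested pixel count exactly
        h, w = self.image_shape
        return (h / 2.0 + 0.2929, w / 4.0 + 0.4114)


@dataclass
class FlowPhantom:
    """Ground-truth flow state of the scenario at one instant."""

    tau_map: np.ndarray
    relative_flow_map: np.ndarray
    occlusion_center_px: tuple[float, float]
    occlusion_radius_px: float
    hemisphere_mask: np.ndarray
    mca_core_mask: np.ndarray
    pixel_pitch_mm: float
    scenario_time_min: float
    true_reduction_area_mm2: float


def _disc_mask(shape: tuple[int, int], center: tuple[float, float], radius: float) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - center[0]) ** 2 + (xx - center[1]) ** 2 <= radius * radius


def make_flow_phantom(config: ScenarioConfig, t_min: float) -> FlowPhantom:
    """Phantom whose true >50%-reduction area equals ``growth_curve(t)``.

    The territory is a disc rasterized to the pixel count nearest the
    requested area (always within one perimeter-pixel ring); flow is
    ``occlusion_flow_fraction`` inside it, ``core_flow_fraction`` in the inner
    core, and 1 elsewhere, with τ_c = baseline_tau / flow pixelwise.
    """
    if t_min < 0:
        raise ValueError("scenario time must be nonnegative")
    h, w = config.image_shape
    hemi = config.hemisphere_mask()
    area_mm2 = float(config.growth_curve(t_min))
    px_area = config.pixel_pitch_mm**2
    hemi_area = hemi.sum() * px_area
    if area_mm2 > hemi_area:
        raise ScenarioOverflowError(
            f"scenario-overflow: requested area {area_mm2:.2f} mm² exceeds hemisphere "
            f"area {hemi_area:.2f} mm²"
        )
    n_req = int(round(area_mm2 / px_area))
    center = config.occlusion_center_px
    flow = np.ones((h, w))
    radius = 0.0
    disc = np.zeros((h, w), dtype=bool)
    if n_req > 0:
        # rasterize to exactly the requested pixel count: take the n_req
        # pixels nearest the territory center (ties broken by the fractional
        # center offset)
        yy, xx = np.ogrid[:h, :w]
        d2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
        r2_star = np.partition(d2.ravel(), n_req - 1)[n_req - 1]
        radius = math.sqrt(r2_star)
        disc = d2 <= r2_star
        if np.any(disc & ~hemi):
            raise ScenarioOverflowError(
                "scenario-overflow: occlusion territory extends beyond the hemisphere mask"
            )
        flow[disc] = config.occlusion_flow_fraction
        core = _disc_mask((h, w), center, radius * config.core_radius_fraction)
        flow[core] = config.core_flow_fraction
    core_roi = _disc_mask(
        (h, w), center, max(radius * config.core_radius_fraction, min(h, w) / 32.0)
    )
    tau = config.baseline_tau_s / flow
    return FlowPhantom(
        tau_map=tau,
        relative_flow_map=flow,
        occlusion_center_px=center,
        occlusion_radius_px=radius,
        hemisphere_mask=hemi,
        mca_core_mask=core_roi,
        pixel_pitch_mm=config.pixel_pitch_mm,
        scenario_time_min=t_min,
        true_reduction_area_mm2=float(disc.sum()) * px_area,
    )


def make_anatomy_pattern(config: ScenarioConfig) -> np.ndarray:
    """Static multiplicative structure shared by all frames of a scenario.

    Real raw speckle frames carry persistent anatomical reflectance
    (vasculature, tissue albedo) on top of the fluctuating speckle; this is
    what image registration locks onto.  A smooth unit-mean random field with
    correlation length ``anatomy_corr_px`` emulates it.  Because the field is
    smooth at the contrast-window scale and sd/mean is invariant to local
    intensity scaling, it leaves speckle-contrast statistics essentially
    unchanged.  Derived from ``config.seed`` only, so every frame of a
    scenario shares the same pattern.
    """
    if config.anatomy_contrast <= 0:
        return np.ones(config.image_shape)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 777]))
    h, w = config.image_shape
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f0 = 1.0 / (2.0 * math.pi * config.anatomy_corr_px)
    kernel = np.exp(-(fy * fy + fx * fx) / (2.0 * f0 * f0))
    field = np.fft.ifft2(np.fft.fft2(rng.standard_normal((h, w))) * kernel).real
    field *= config.anatomy_contrast / field.std()
    return np.clip(1.0 + field - field.mean(), 0.2, None)


class _FieldSynth:
    """Band-limited complex Gaussian field generator for one image shape."""

    def __init__(self, shape: tuple[int, int], speckle_size_px: float):
        fy = np.fft.fftfreq(shape[0])[:, None]
        fx = np.fft.fftfreq(shape[1])[None, :]
        cutoff = 1.0 / (2.0 * speckle_size_px)  # cycles/px
        self.mask = fy * fy + fx * fx <= cutoff * cutoff
        self.n_keep = int(self.mask.sum())
        self.shape = shape
        # normalization so that E|field|² = 1 per pixel
        self.scale = shape[0] * shape[1] / math.sqrt(2.0 * self.n_keep)

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        F = np.zeros(self.shape, dtype=np.complex128)
        F[self.mask] = rng.standard_normal(self.n_keep) + 1j * rng.standard_normal(self.n_keep)
        return np.fft.ifft2(F) * self.scale


def render_speckle_frame(
    phantom: FlowPhantom, config: ScenarioConfig, seed: int | tuple
) -> np.ndarray:
    """One time-integrated dynamic speckle frame for the phantom's τ_c map.

    The field evolves through ``n_substeps`` AR(1) steps spanning the exposure
    with per-pixel coefficient exp(−Δt/τ_c); the frame is the mean intensity.
    Exposures longer than ``n_substeps/4`` correlation times are rejected as
    undersampled.
    """
    M = config.n_substeps
    T = config.exposure_s
    if T / float(phantom.tau_map.min()) > M / 4.0:
        raise UndersampledIntegrationError(
            "undersampled-integration: T/tau_c exceeds n_substeps/4; raise n_substeps"
        )
    rng = np.random.default_rng(seed)
    synth = _FieldSynth(config.image_shape, config.speckle_size_px)
    dt = T / M
    rho = np.exp(-dt / phantom.tau_map)
    innov = np.sqrt(1.0 - rho * rho)
    E = synth.draw(rng)
    acc = np.abs(E) ** 2
    for _ in range(M - 1):
        E = rho * E + innov * synth.draw(rng)
        acc += np.abs(E) ** 2
    frame = acc / M
    if config.anatomy_contrast > 0:
        frame = frame * make_anatomy_pattern(config)
    if config.beta < 1.0:
        # β < 1 models loss of correlation at the detector: blend the dynamic
        # intensity with a constant pedestal so that K² = β·K²_dyn exactly
        # (sd scales by √β at unit mean).
        rb = math.sqrt(config.beta)
        frame = rb * frame + (1.0 - rb)
    return frame


def render_sequence(
    config: ScenarioConfig, t_start_min: float, t_end_min: float
) -> SpeckleStack:
    """Frames at ``frame_rate`` over [t_start, t_end) with the phantom updated
    per frame along the growth curve.

    Frame k is seeded by (config.seed, k), so rendering the same interval — or
    any interval with an identical phantom — with the same seed is
    bit-reproducible.
    """
    if not t_start_min < t_end_min:
        raise EmptyIntervalError("empty-interval: t_start must precede t_end")
    n = int(round((t_end_min - t_start_min) * 60.0 * config.frame_rate_hz))
    if n == 0:
        raise EmptyIntervalError("empty-interval: no frame fits the requested interval")
    frames = np.empty((n, *config.image_shape))
    times = np.empty(n)
    phantom = None
    last_t = None
    for k in range(n):
        t = t_start_min + k / (config.frame_rate_hz * 60.0)
        t_eff = max(t, 0.0)
        if phantom is None or config.growth_curve(t_eff) != config.growth_curve(last_t):
            phantom = make_flow_phantom(config, t_eff)
            last_t = t_eff
        frames[k] = render_speckle_frame(phantom, config, seed=(config.seed, k))
        times[k] = t * 60.0
    return SpeckleStack(
        frames=frames,
        exposure_s=config.exposure_s,
        frame_rate_hz=config.frame_rate_hz,
        pixel_pitch_mm=config.pixel_pitch_mm,
        timestamps_s=times,
        seed=config.seed,
    )


def inject_motion(stack: SpeckleStack, drift_schedule_px: np.ndarray) -> SpeckleStack:
    """Translate each frame by its scheduled (dy, dx), subpixel via Fourier
    interpolation; the schedule is stored on the stack as registration ground
    truth."""
    sched = np.asarray(drift_schedule_px, dtype=np.float64)
    if sched.shape != (len(stack), 2):
        raise ValueError("drift schedule must be (n_frames, 2)")
    h, w = stack.shape
    if np.any(np.abs(sched[:, 0]) >= 0.1 * h) or np.any(np.abs(sched[:, 1]) >= 0.1 * w):
        raise ValueError("drift exceeds 10% of the image size")
    out = np.empty_like(stack.frames)
    for k, (dy, dx) in enumerate(sched):
        if dy == 0 and dx == 0:
            out[k] = stack.frames[k]
        else:
            out[k] = np.fft.ifft2(fourier_shift(np.fft.fft2(stack.frames[k]), (dy, dx))).real
    out = np.maximum(out, 0.0)
    return stack.replace_frames(out, motion_schedule_px=sched)


def make_lesion_volume(
    true_volume_mm3: float,
    n_slices: int,
    thickness_mm: float,
    in_plane_pitch_mm: float,
    lesion_intensity: float = 100.0,
    background_intensity: float = 60.0,
    noise_sd: float = 5.0,
    seed: int = 0,
    slice_shape: tuple[int, int] = (128, 128),
    modality: str = "MRI-like",
    axis_ratios: tuple[float, float, float] = (0.9, 1.0, 1.2),
) -> VolumeImage:
    """Slice stack with a planted hyperintense ellipsoidal lesion.

    The lesion is rasterized to exactly the voxel count nearest
    ``true_volume / voxel_volume`` (radius chosen by order statistics of the
    normalized ellipsoidal distance), so the planted volume is correct to
    within one voxel.  Background must stay below 75% of the lesion intensity
    for the downstream threshold to be able to separate the classes.
    """
    if background_intensity >= 0.75 * lesion_intensity:
        raise ValueError("background must stay below 75% of the lesion intensity")
    if noise_sd > 0.05 * lesion_intensity:
        raise ValueError("noise sd must not exceed 5% of the lesion intensity")
    if true_volume_mm3 < 0:
        raise ValueError("volume must be nonnegative")
    h, w = slice_shape
    voxel = in_plane_pitch_mm**2 * thickness_mm
    capacity = n_slices * h * w * voxel
    if true_volume_mm3 > 0.5 * capacity:
        raise ValueError(
            f"planted volume {true_volume_mm3} mm³ exceeds half the stack capacity {capacity:.0f} mm³"
        )
    rng = np.random.default_rng(seed)
    data = np.full((n_slices, h, w), background_intensity, dtype=np.float64)
    truth = np.zeros((n_slices, h, w), dtype=bool)
    if true_volume_mm3 > 0:
        n_target = max(int(round(true_volume_mm3 / voxel)), 1)
        zc = (np.arange(n_slices) + 0.5) * thickness_mm
        yc = (np.arange(h) + 0.5) * in_plane_pitch_mm
        xc = (np.arange(w) + 0.5) * in_plane_pitch_mm
        # fractional offsets break voxel-distance ties so the rasterized count
        # can match the request exactly
        center = (
            (n_slices / 2.0 + 0.131) * thickness_mm,
            (h / 2.0 + 0.317) * in_plane_pitch_mm,
            (w / 2.0 + 0.473) * in_plane_pitch_mm,
        )
        az, ay, ax = axis_ratios
        R = np.sqrt(
            ((zc - center[0]) / az)[:, None, None] ** 2
            + ((yc - center[1]) / ay)[None, :, None] ** 2
            + ((xc - center[2]) / ax)[None, None, :] ** 2
        )
        r_star = np.partition(R.ravel(), n_target - 1)[n_target - 1]
        truth = R <= r_star
        data[truth] = lesion_intensity
    if noise_sd > 0:
        data = data + rng.normal(0.0, noise_sd, size=data.shape)
    return VolumeImage(
        slices=data,
        slice_thickness_mm=thickness_mm,
        in_plane_pitch_mm=in_plane_pitch_mm,
        modality=modality,
        truth_mask=truth,
        true_volume_mm3=float(truth.sum()) * voxel,
    )


def _decompose_total(total: int) -> dict[str, int]:
    """Split an integer NSS total across categories, respecting the maxima
    (6/2/6/4) and allocating proportionally with deterministic tie-breaks."""
    names = list(NSS_CATEGORY_MAXIMA)
    maxima = np.array([NSS_CATEGORY_MAXIMA[n] for n in names], dtype=float)
    ideal = total * maxima / NSS_MAX_TOTAL
    scores = np.floor(ideal).astype(int)
    remainder = total - scores.sum()
    order = np.argsort(-(ideal - scores), kind="stable")
    for idx in order:
        if remainder == 0:
            break
        if scores[idx] < maxima[idx]:
            scores[idx] += 1
            remainder -= 1
    # spill any residue into categories with headroom (extreme totals)
    while remainder > 0:
        for idx in range(len(scores)):
            if remainder > 0 and scores[idx] < maxima[idx]:
                scores[idx] += 1
                remainder -= 1
    return dict(zip(names, scores.tolist()))


def make_nss_cohort(
    group_mean: float,
    group_sd: float,
    n_rats: int,
    n_examiners: int = 3,
    n_trials: int = 3,
    examiner_sd: float = 0.5,
    seed: int = 0,
    id_prefix: str = "rat",
) -> list[NSSRecord]:
    """Per-rat, per-examiner, per-trial NSS records.

    Each rat carries a latent severity drawn from N(group_mean, group_sd²);
    each record adds examiner/trial noise, rounds to the integer scoring grid,
    clips to [0, 18], and decomposes into category scores respecting the
    motor/sensory/beam/reflex maxima.
    """
    if not 0 <= group_mean <= NSS_MAX_TOTAL:
        raise ValueError("group mean must lie within the 0-18 scale")
    if n_examiners < 1 or n_trials < 1 or n_rats < 1:
        raise ValueError("cohort dimensions must be positive")
    rng = np.random.default_rng(seed)
    records: list[NSSRecord] = []
    for r in range(n_rats):
        latent = rng.normal(group_mean, group_sd) if group_sd > 0 else group_mean
        for e in range(n_examiners):
            for tr in range(n_trials):
                value = latent + (rng.normal(0.0, examiner_sd) if examiner_sd > 0 else 0.0)
                total = int(np.clip(round(value), 0, NSS_MAX_TOTAL))
                cats = _decompose_total(total)
                records.append(
                    NSSRecord(
                        rat_id=f"{id_prefix}{r:02d}",
                        examiner_id=f"ex{e}",
                        trial_index=tr,
                        **cats,
                    )
                )
    return records
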